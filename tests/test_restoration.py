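"""Restoration routes, the Wald-triple back-calculation, and the fix loop."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from sumstatfix.dbsnp import DbSnpIndex, VariantRecord
from sumstatfix.errors import PlanningError
from sumstatfix.evaluation import mask_column
from sumstatfix.restoration import (FixResult, fix, restore_allele,
                                    restore_chr_bp, restore_eaf, restore_rsid,
                                    restore_stat)
from sumstatfix.table import STANDARD_FIELDS, SumStatsTable
from sumstatfix.validation import Resources, validate_table


def _row(**kw):
    base = {"chr": "1", "bp": "100", "rsid": "rs1", "ea": "A", "oa": "G",
            "eaf": "0.2", "beta": "0.1", "se": "0.05", "pval": "0.5"}
    base.update(kw)
    return base


@pytest.fixture(scope="module")
def mini_index():
    records = sorted([
        VariantRecord(100, "2", 500, "A", ("G",), {"S": (0.7, 0.3)}),
        VariantRecord(7, "1", 100, "C", ("T",), {"S": (0.9, 0.1)}),
        VariantRecord(20, "3", 700, "G", ("A",), {"S": (0.6, 0.4)}),
        VariantRecord(21, "3", 700, "G", ("C",), {"S": (0.5, 0.5)}),
    ], key=lambda r: (r.chr, r.bp, r.rsid_num))
    return DbSnpIndex(records, build=38)


class TestRestoreChrBp:
    def test_restores_both_from_rsid(self, mini_index):
        row = restore_chr_bp(_row(rsid="rs100", bp="NA"), mini_index)
        assert (row["chr"], row["bp"]) == ("2", "500")

    def test_pair_rule_overwrites_valid_chr(self, mini_index):
        # chr "1" is syntactically valid but disagrees with the record: the
        # pair rule rewrites both coordinates from the rsID
        row = restore_chr_bp(_row(rsid="rs100", chr="1", bp="NA"), mini_index)
        assert (row["chr"], row["bp"]) == ("2", "500")

    def test_absent_rsid_unchanged(self, mini_index):
        row = _row(rsid="rs999999", bp="NA")
        assert restore_chr_bp(row, mini_index) == row


class TestRestoreRsid:
    def test_single_record_at_site(self, mini_index):
        row = restore_rsid(_row(chr="2", bp="500", rsid="esv1"), mini_index)
        assert row["rsid"] == "rs100"

    def test_allele_disambiguation(self, mini_index):
        # two records at 3:700 (G/A and G/C); EA=C matches only rs21
        row = restore_rsid(_row(chr="3", bp="700", rsid="bad", ea="C", oa="G"),
                           mini_index)
        assert row["rsid"] == "rs21"

    def test_ambiguous_site_lowest_rsid(self, mini_index):
        row = restore_rsid(_row(chr="3", bp="700", rsid="bad", ea="G", oa="-"),
                           mini_index)
        assert row["rsid"] == "rs20"

    def test_empty_position_unchanged(self, mini_index):
        row = _row(chr="9", bp="12345", rsid="bad")
        assert restore_rsid(row, mini_index) == row


class TestRestoreAllele:
    def test_most_likely_partner(self, mini_index):
        row = restore_allele(_row(rsid="rs100", ea="G", oa="NA"), mini_index)
        assert row["oa"] == "A"

    def test_both_invalid_untouched(self, mini_index):
        row = _row(rsid="rs100", ea="NA", oa="NA")
        assert restore_allele(row, mini_index) == row

    def test_unknown_allele_unchanged(self, mini_index):
        row = _row(rsid="rs7", ea="G", oa="NA")    # site is C/T; G not present
        assert restore_allele(row, mini_index) == row

    def test_chrbp_fallback_when_rsid_invalid(self, mini_index):
        row = restore_allele(_row(rsid="bad", chr="2", bp="500", ea="G", oa="NA"),
                             mini_index)
        assert row["oa"] == "A"


class TestRestoreEaf:
    def test_frequency_of_effect_allele(self, mini_index):
        row = restore_eaf(_row(rsid="rs100", ea="G", eaf="NA"), mini_index)
        assert float(row["eaf"]) == 0.3

    def test_allele_not_at_site_unchanged(self, mini_index):
        row = _row(rsid="rs7", ea="G", eaf="NA")
        assert restore_eaf(row, mini_index) == row

    def test_missing_annotation_unchanged(self):
        idx = DbSnpIndex([VariantRecord(1, "1", 10, "A", ("C",), {})])
        row = _row(rsid="rs1", chr="1", bp="10", ea="C", eaf="NA")
        assert restore_eaf(row, idx) == row


class TestRestoreStat:
    """Oracle: z = Φ⁻¹(1 − p/2) with Φ the standard normal CDF."""

    def test_se_from_beta_and_pval(self):
        p = 2 * (1 - norm.cdf(2.0))                 # z = 2 -> p ≈ 0.04550
        row = restore_stat(_row(beta="0.1", pval=repr(float(p)), se="NA"))
        assert float(row["se"]) == pytest.approx(0.05, rel=1e-9)

    def test_pval_from_beta_and_se(self):
        row = restore_stat(_row(beta="0.1", se="0.05", pval="NA"))
        assert float(row["pval"]) == pytest.approx(2 * (1 - norm.cdf(2.0)), rel=1e-9)

    def test_beta_is_unsigned(self):
        p = 2 * (1 - norm.cdf(2.0))
        row = restore_stat(_row(se="0.05", pval=repr(float(p)), beta="NA"))
        assert float(row["beta"]) == pytest.approx(0.1, rel=1e-9)

    @pytest.mark.parametrize("kw", [
        dict(beta="0.1", pval="1", se="NA"),        # z = 0
        dict(beta="0.1", pval="0", se="NA"),        # z = inf
        dict(beta="0.1", se="0", pval="NA"),        # division by zero
        dict(beta="0.1", pval="1e-310", se="NA"),   # quantile overflow guard
    ])
    def test_degenerate_cases_unchanged(self, kw):
        row = _row(**kw)
        assert restore_stat(row) == row

    def test_two_invalid_members_skipped(self):
        row = _row(beta="NA", se="NA", pval="0.5")
        assert restore_stat(row) == row

    @given(beta=st.floats(-2, 2).filter(lambda b: abs(b) > 1e-6),
           se=st.floats(1e-3, 1.0))
    def test_triple_round_trip(self, beta, se):
        """p from (β, se), then se back from (β, p), reproduces se."""
        z = abs(beta) / se
        if not 1e-3 <= z <= 8:
            return
        row1 = restore_stat(_row(beta=repr(beta), se=repr(se), pval="NA"))
        row2 = restore_stat({**row1, "se": "NA"})
        assert float(row2["se"]) == pytest.approx(se, rel=1e-6)


class TestFixLoop:
    def test_clean_table_single_pass(self, clean_table, index, spec):
        res = fix(clean_table, Resources(dbsnp=index, target_build=spec.build))
        assert res.passes == 1
        assert all(v == 0 for v in res.restored_counts.values())

    @pytest.mark.parametrize("column", STANDARD_FIELDS)
    def test_closed_world_recovery(self, clean_table, index, spec, column):
        """Masking any single column of a fixture-consistent table and running
        fix recovers every entry (beta up to sign)."""
        masked = mask_column(clean_table, column)
        res = fix(masked, Resources(dbsnp=index, target_build=spec.build))
        assert res.table.n_rows == clean_table.n_rows
        assert res.unresolved_counts[column] == 0
        assert res.passes <= 3
        orig = clean_table.numeric(column) if column in ("eaf", "beta", "se", "pval") \
            else clean_table.data[column]
        if column in ("chr", "bp", "rsid", "ea", "oa"):
            assert list(res.table.data[column]) == list(orig)
        elif column == "eaf":
            np.testing.assert_allclose(res.table.numeric(column), orig, atol=1e-9)
        elif column == "beta":
            np.testing.assert_allclose(res.table.numeric(column), np.abs(orig),
                                       rtol=1e-6)
        else:
            np.testing.assert_allclose(res.table.numeric(column), orig, rtol=1e-6)

    def test_unknown_rsid_row_retained(self, clean_table, index, spec):
        t = clean_table.copy()
        t.data.at[0, "rsid"] = "rs99999999"
        t.data.at[0, "bp"] = "NA"
        res = fix(t, Resources(dbsnp=index, target_build=spec.build))
        assert res.table.n_rows == clean_table.n_rows
        assert res.unresolved_counts["bp"] == 1

    def test_minimal_mutation(self, clean_table, index, spec):
        """Fields valid on input and outside the chr/bp pair rule are
        bit-identical on output."""
        from sumstatfix.fixtures import FixtureSpec, corrupt_table
        cspec = FixtureSpec(n_variants=spec.n_variants, seed=13,
                            corruption={"rsid": 0.2, "eaf": 0.2, "se": 0.2})
        corrupted, truth = corrupt_table(clean_table, cspec)
        before = corrupted.data.copy()
        report = validate_table(corrupted)
        res = fix(corrupted, Resources(dbsnp=index, target_build=spec.build))
        for f in STANDARD_FIELDS:
            ok = report.valid_mask[f].to_numpy()
            unchanged = before[f][ok].equals(res.table.data[f][ok])
            assert unchanged, f"valid {f} entries were mutated"

    def test_build_mismatch_without_chain_errors_before_mutation(self, clean_table):
        t = clean_table.copy()
        t.input_build = 37
        with pytest.raises(PlanningError, match="chain"):
            fix(t, Resources(dbsnp=None, chain=None, target_build=38))

    def test_liftover_then_lookup(self, clean_table, index, spec, bundle):
        """A table on the shifted build lifts back and then restores."""
        from sumstatfix.liftover import lift_table, parse_chain
        man = bundle["chain_manifest"]
        fwd = parse_chain(man["chain"])
        shifted, _ = lift_table(clean_table, fwd)     # now on build "input+10"
        shifted.input_build = 37
        shifted.data["rsid"] = None                   # force chrbp-keyed lookups
        inv = parse_chain(man["inverse_chain"])
        res = fix(shifted, Resources(dbsnp=index, chain=inv, target_build=38))
        assert res.table.n_rows == clean_table.n_rows
        assert res.unresolved_counts["rsid"] == 0
        assert list(res.table.data["rsid"]) == list(clean_table.data["rsid"])

    def test_zero_loss_and_termination_fuzz(self, clean_table, index, spec):
        """Randomly corrupted tables terminate within fields+1 passes with
        monotone non-increasing invalid totals and zero row loss."""
        from sumstatfix.fixtures import FixtureSpec, corrupt_table
        rng = np.random.default_rng(5)
        for trial in range(10):
            fields = rng.choice(STANDARD_FIELDS,
                                size=rng.integers(1, 5), replace=False)
            corruption = {str(f): float(rng.uniform(0, 0.4)) for f in fields}
            cspec = FixtureSpec(n_variants=spec.n_variants,
                                seed=int(rng.integers(1, 2**20)),
                                corruption=corruption)
            corrupted, _ = corrupt_table(clean_table, cspec)
            res = fix(corrupted, Resources(dbsnp=index, target_build=spec.build))
            assert res.table.n_rows == clean_table.n_rows
            assert res.passes <= len(STANDARD_FIELDS) + 1
            totals = res.pass_invalid_totals
            assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_restored_plus_unresolved_is_initial(self, clean_table, index, spec):
        from sumstatfix.fixtures import FixtureSpec, corrupt_table
        cspec = FixtureSpec(n_variants=spec.n_variants, seed=29,
                            corruption={"bp": 0.3, "pval": 0.3})
        corrupted, _ = corrupt_table(clean_table, cspec)
        initial = validate_table(corrupted).per_field_invalid
        res = fix(corrupted, Resources(dbsnp=index, target_build=spec.build))
        for f in STANDARD_FIELDS:
            assert res.restored_counts[f] + res.unresolved_counts[f] == initial[f]
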