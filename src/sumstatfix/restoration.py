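"""Restoration routes and the outer validate→restore loop.

Only entries flagged invalid are ever modified, with a single exception:
when either the chromosome or the position is invalid, *both* are rewritten
from the rsID lookup, because a half-trusted coordinate pair is worthless.
No route ever drops a row — unresolved entries stay flagged in the output.

The statistical route uses the Wald identity between effect size β, its
standard error s and the two-tailed p-value:

    z = Φ⁻¹(1 − p/2),   s = |β| / z,   p = 2·(1 − Φ(|β| / s))

Only |β| is recoverable from (s, p): a two-tailed p carries no sign, so a
restored β is always reported non-negative.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .dbsnp import (DbSnpIndex, allele_frequency, lookup_by_chrbp,
                    lookup_by_rsid, most_likely_allele)
from .errors import PlanningError
from .liftover import lift_table
from .table import STANDARD_FIELDS, SumStatsTable, fmt_float
from .validation import (FIELD_VALIDATORS, Resources, plan_restoration,
                         validate_table)

log = logging.getLogger(__name__)

#: guard against Φ⁻¹ overflow: p below this is unrestorable for se/beta.
MIN_PVAL = 1e-300

Row = dict[str, str | None]


def _valid(row: Row, fieldname: str) -> bool:
    return FIELD_VALIDATORS[fieldname](row[fieldname])[0]


def _site_records(row: Row, index: DbSnpIndex, prefer: str = "rsid"):
    """Records for a row's site, looked up by the preferred key with fallback."""
    order = ("rsid", "chrbp") if prefer == "rsid" else ("chrbp", "rsid")
    for key in order:
        if key == "rsid" and _valid(row, "rsid"):
            rec = lookup_by_rsid(index, int(row["rsid"].strip()[2:]))
            return [rec] if rec is not None else []
        if key == "chrbp" and _valid(row, "chr") and _valid(row, "bp"):
            return lookup_by_chrbp(index, row["chr"], int(row["bp"]))
    return []


# -- single-row routes -----------------------------------------------------

def restore_chr_bp(row: Row, index: DbSnpIndex) -> Row:
    """Rewrite BOTH chr and bp from the rsID lookup (pair rule)."""
    if not _valid(row, "rsid"):
        return row
    rec = lookup_by_rsid(index, int(row["rsid"].strip()[2:]))
    if rec is None:
        return row
    return {**row, "chr": rec.chr, "bp": str(rec.bp)}


def restore_rsid(row: Row, index: DbSnpIndex) -> Row:
    """Set rsID from the (chr, bp) lookup, disambiguating by allele match."""
    if not (_valid(row, "chr") and _valid(row, "bp")):
        return row
    records = lookup_by_chrbp(index, row["chr"], int(row["bp"]))
    if not records:
        return row
    if len(records) > 1:
        known = [row[f].strip().upper() for f in ("ea", "oa") if _valid(row, f)
                 and row[f].strip() != "-"]
        matching = [r for r in records if all(a in r.alleles for a in known)]
        if len(matching) == 1:
            records = matching
        else:
            log.info("ambiguous site %s:%s; choosing lowest rsID",
                     row["chr"], row["bp"])
    rec = min(records, key=lambda r: r.rsid_num)
    return {**row, "rsid": f"rs{rec.rsid_num}"}


def restore_allele(row: Row, index: DbSnpIndex, prefer: str = "rsid") -> Row:
    """Fill the single invalid allele with the most likely partner of the other."""
    ea_ok, oa_ok = _valid(row, "ea"), _valid(row, "oa")
    if ea_ok == oa_ok:          # zero or two invalid: route does not apply
        return row
    known_field, bad_field = ("ea", "oa") if ea_ok else ("oa", "ea")
    known = row[known_field].strip().upper()
    if known == "-":
        return row
    records = _site_records(row, index, prefer)
    partner = most_likely_allele(records, known)
    if partner is None:
        log.info("no partner allele found for %s at %s", known, row["rsid"])
        return row
    return {**row, bad_field: partner}


def restore_eaf(row: Row, index: DbSnpIndex, prefer: str = "rsid") -> Row:
    """Set EAF to the reference-database frequency of the effect allele."""
    if not _valid(row, "ea") or row["ea"].strip() == "-":
        return row
    records = _site_records(row, index, prefer)
    freq = allele_frequency(records, row["ea"].strip().upper())
    if freq is None:
        return row
    return {**row, "eaf": fmt_float(freq)}


def restore_stat(row: Row) -> Row:
    """Restore the single invalid member of (beta, se, pval) from the other two.

    Degenerate inputs (p = 0, p = 1 where it divides, s = 0, |z| overflow)
    leave the row unchanged and still flagged.
    """
    ok = {f: _valid(row, f) for f in ("beta", "se", "pval")}
    if sum(ok.values()) != 2:
        return row
    bad = next(f for f, v in ok.items() if not v)
    if bad == "se":
        beta, p = float(row["beta"]), float(row["pval"])
        if p < MIN_PVAL or p >= 1.0:
            return row
        z = float(norm.isf(p / 2.0))
        if not np.isfinite(z) or z <= 0.0:
            return row
        return {**row, "se": fmt_float(abs(beta) / z)}
    if bad == "beta":
        se, p = float(row["se"]), float(row["pval"])
        if p < MIN_PVAL:
            return row
        z = float(norm.isf(p / 2.0))
        if not np.isfinite(z) or z < 0.0:
            return row
        return {**row, "beta": fmt_float(abs(se) * z)}
    beta, se = float(row["beta"]), float(row["se"])
    if se == 0.0:
        return row
    return {**row, "pval": fmt_float(2.0 * float(norm.sf(abs(beta / se))))}


# -- the outer loop --------------------------------------------------------

@dataclass
class FixResult:
    """Outcome of the validate→restore loop: zero rows lost, by construction."""

    table: SumStatsTable
    passes: int
    restored_counts: dict[str, int]
    unresolved_counts: dict[str, int]
    n_unmapped_liftover: int = 0
    pass_invalid_totals: list[int] = field(default_factory=list)


def _apply_routes(table: SumStatsTable, plan, index: DbSnpIndex | None) -> int:
    """Run the planned routes over the table in place; return entries restored."""
    from .validation import _route_row_masks, validate_table as _vt

    report = _vt(table)
    masks = _route_row_masks(report)
    df = table.data
    n_restored = 0
    prefer = "rsid" if plan.sort_key == "rsid" else "chrbp"

    def apply(route: str, fn) -> None:
        nonlocal n_restored
        for i in np.flatnonzero(masks[route]):
            row: Row = {f: df.at[i, f] for f in STANDARD_FIELDS}
            new = fn(row)
            changed = {f for f in STANDARD_FIELDS if new[f] != row[f]}
            for f in changed:
                df.at[i, f] = new[f]
            n_restored += len(changed)

    for route in plan.routes:
        if route == "chr_bp" and index is not None:
            apply("chr_bp", lambda r: restore_chr_bp(r, index))
        elif route == "rsid" and index is not None:
            apply("rsid", lambda r: restore_rsid(r, index))
        elif route == "allele" and index is not None:
            apply("allele", lambda r: restore_allele(r, index, prefer))
        elif route == "eaf" and index is not None:
            apply("eaf", lambda r: restore_eaf(r, index, prefer))
        elif route == "stat":
            apply("stat", restore_stat)
    return n_restored


def fix(table: SumStatsTable, resources: Resources,
        target_build: int | None = None) -> FixResult:
    """Validate, lift over once if needed, and restore until a fixed point.

    The loop re-validates after every restoration pass and stops when a pass
    restores nothing further or no resolvable issue remains; it is bounded by
    ``len(fields) + 1`` passes. Output row order and count equal the input's.
    """
    target = target_build if target_build is not None else resources.target_build
    resources = Resources(dbsnp=resources.dbsnp, chain=resources.chain,
                          target_build=target)
    if table.input_build != target and resources.chain is None:
        raise PlanningError(
            f"input build {table.input_build} differs from target build "
            f"{target} but no chain file was supplied")

    work = table.copy()
    n_rows_in = work.n_rows
    n_unmapped = 0
    lifted = False
    initial_invalid: dict[str, int] | None = None
    passes = 0
    pass_totals: list[int] = []
    max_passes = len(STANDARD_FIELDS) + 1

    while passes < max_passes:
        passes += 1
        report = validate_table(work)
        plan = plan_restoration(report, resources, input_build=work.input_build)
        if plan.needs_liftover and not lifted:
            work, n_unmapped = lift_table(work, resources.chain)
            work.input_build = target
            lifted = True
            report = validate_table(work)
            plan = plan_restoration(report, resources, input_build=work.input_build)
        if initial_invalid is None:
            initial_invalid = dict(report.per_field_invalid)
        pass_totals.append(sum(report.per_field_invalid.values()))
        if not plan.routes:
            break
        if _apply_routes(work, plan, resources.dbsnp) == 0:
            break

    final = validate_table(work)
    assert work.n_rows == n_rows_in, "zero-loss invariant violated"
    restored = {f: initial_invalid[f] - final.per_field_invalid[f]
                for f in STANDARD_FIELDS}
    return FixResult(table=work, passes=passes, restored_counts=restored,
                     unresolved_counts=dict(final.per_field_invalid),
                     n_unmapped_liftover=n_unmapped,
                     pass_invalid_totals=pass_totals)
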