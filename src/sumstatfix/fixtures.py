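"""Synthetic, internally consistent fixture data at desk scale.

One generator family produces a mini reference-variant VCF, summary
statistics derived from it, a constant-offset chain file with a deliberate
coverage gap, and per-entry corruption with a truth record. Everything is a
deterministic function of the spec and its seed, and the closed-world
property holds: every variant in the generated summary statistics exists in
the generated VCF, so lookup restoration is exactly recoverable.

The generated statistics use the standard single-SNP association model for a
standardized quantitative trait: se ≈ 1 / sqrt(2·N·f·(1−f)) for allele
frequency f and sample size N, β ~ Normal(0, effect_sd), and the two-tailed
p-value from the Wald z = |β|/se — so every (β, se, p) triple is consistent
by construction.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .errors import ParameterError
from .table import STANDARD_FIELDS, SumStatsTable, fmt_float

#: source-coordinate extent covered by generated chain files (0-based)
CHAIN_COVERED = (1_000, 10_400_000)
#: deliberate per-chromosome gap in source coordinates (0-based half-open)
CHAIN_GAP = (5_000_000, 5_001_000)
_SRC_LEN = 10_500_000
_DST_LEN = 10_600_000
#: positions are sampled strictly inside the covered chain interval
_POS_RANGE = (10_001, 9_999_999)

#: invalid-token palette per field, mimicking failure modes seen in the wild
CORRUPTION_TOKENS: dict[str, tuple[str, ...]] = {
    "chr": ("25", "NA", "0", "chrUn"),
    "bp": ("NA", "-5", "1.2e6", "?"),
    "rsid": ("esv3584976", "NA", "rs", "id_123"),
    "ea": ("N", "B", "NA", "-9"),
    "oa": ("N", "B", "NA", "-9"),
    "eaf": ("NA", "1.5", "-0.1", "freq?"),
    "beta": ("NA", "inf", "none", "#"),
    "se": ("NA", "inf", "none", "#"),
    "pval": ("NA", "2.0", "-1e-4", "p"),
}


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic data set."""

    n_variants: int = 1000
    chromosomes: tuple[str, ...] = ("1", "2", "X")
    build: int = 38
    seed: int = 7
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_sd: float = 0.05
    n_samples: int = 10_000
    corruption: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ParameterError("n_variants must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range must lie within (0, 0.5]")
        if self.effect_sd <= 0 or self.n_samples < 1:
            raise ParameterError("effect_sd must be > 0 and n_samples >= 1")
        for f, frac in self.corruption.items():
            if f not in STANDARD_FIELDS:
                raise ParameterError(f"unknown corruption field {f!r}")
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(f"corruption fraction for {f!r} not in [0,1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _unique_positions(rng: np.random.Generator, n: int) -> np.ndarray:
    # sampled positions steer clear of the deliberate chain gap (with margin
    # for offsets) so that gap behaviour is exercised only where intended
    lo, hi = _POS_RANGE
    g0, g1 = CHAIN_GAP[0] - 1_000, CHAIN_GAP[1] + 1_000
    seen: set[int] = set()
    while len(seen) < n:
        for p in rng.integers(lo, hi, size=n - len(seen)):
            if not g0 < p <= g1:
                seen.add(int(p))
    return np.array(sorted(seen), dtype=np.int64)


def generate_dbsnp_fixture(spec: FixtureSpec, out_path: str | Path) -> Path:
    """Write a sorted biallelic-SNP VCF with per-allele frequencies.

    rsID numbers 1..n are assigned in shuffled order so that rsID order and
    position order differ (both index sort orders get exercised).
    """
    out_path = Path(out_path)
    rng = spec.rng(0)
    n_chr = len(spec.chromosomes)
    counts = [spec.n_variants // n_chr + (1 if i < spec.n_variants % n_chr else 0)
              for i in range(n_chr)]
    rsids = rng.permutation(spec.n_variants) + 1

    bases = np.array(list("ACGT"))
    lines: list[str] = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=FREQ,Number=.,Type=String,Description='
        '"Per-source allele frequencies in REF,ALT order">',
    ]
    lines += [f"##contig=<ID={c},length={_SRC_LEN}>" for c in spec.chromosomes]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    k = 0
    for chrom, n in zip(spec.chromosomes, counts):
        positions = _unique_positions(rng, n)
        for pos in positions:
            ref, alt = rng.choice(bases, size=2, replace=False)
            af = float(rng.uniform(*spec.maf_range))
            freq = f"FREQ=SYNTH:{format(1 - af, '.10g')},{format(af, '.10g')}"
            lines.append(f"{chrom}\t{pos}\trs{rsids[k]}\t{ref}\t{alt}\t.\t.\t{freq}")
            k += 1
    out_path.write_text("\n".join(lines) + "\n")
    return out_path


def generate_sumstats(spec: FixtureSpec, dbsnp_path: str | Path,
                      out_path: str | Path) -> tuple[Path, Path]:
    """Write summary statistics matching the fixture VCF, plus a JSON config.

    One row per VCF variant, in VCF order: identifiers, alleles (effect
    allele = ALT) and the effect-allele frequency are copied verbatim from
    the VCF; (β, se, p) are simulated consistently. Column names and the
    ``chr`` prefix are deliberately non-standard so the reader's config
    machinery is exercised. Returns (sumstats path, config path).
    """
    dbsnp_path, out_path = Path(dbsnp_path), Path(out_path)
    if not dbsnp_path.exists():
        raise OSError(f"fixture VCF not found: {dbsnp_path}")
    rng = spec.rng(1)

    rows: list[str] = ["chromosome\tposition\tsnp_id\tA1\tA2\tfreq1\teffect\tstderr\tp"]
    with dbsnp_path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, rsid, ref, alt, _, _, info = line.rstrip("\n").split("\t")
            af_token = info.split(":", 1)[1].split(",")[1]
            af = float(af_token)
            beta = float(rng.normal(0.0, spec.effect_sd))
            se = float(np.sqrt(1.0 / (2.0 * spec.n_samples * af * (1.0 - af))))
            pval = 2.0 * float(norm.sf(abs(beta) / se))
            rows.append("\t".join([
                f"chr{chrom}", pos, rsid, alt, ref, af_token,
                fmt_float(beta), fmt_float(se), fmt_float(pval),
            ]))
    out_path.write_text("\n".join(rows) + "\n")

    config = {
        "chr": "chromosome", "bp": "position", "rsid": "snp_id",
        "ea": "A1", "oa": "A2", "eaf": "freq1",
        "beta": "effect", "se": "stderr", "pval": "p",
        "input_build": spec.build,
    }
    config_path = out_path.with_suffix(out_path.suffix + ".json")
    config_path.write_text(json.dumps(config, indent=2) + "\n")
    return out_path, config_path


def corrupt_table(table: SumStatsTable,
                  spec: FixtureSpec) -> tuple[SumStatsTable, dict[str, dict[int, str | None]]]:
    """Replace a per-field fraction of entries with invalid tokens.

    Returns the corrupted copy and a truth record
    ``{field: {row index: original token}}`` for later evaluation.
    """
    rng = spec.rng(2)
    out = table.copy()
    truth: dict[str, dict[int, str | None]] = {}
    n = table.n_rows
    for fieldname in STANDARD_FIELDS:
        frac = spec.corruption.get(fieldname, 0.0)
        k = int(round(frac * n))
        if k == 0:
            continue
        rows = rng.choice(n, size=k, replace=False)
        palette = CORRUPTION_TOKENS[fieldname]
        truth[fieldname] = {}
        for i in sorted(int(r) for r in rows):
            truth[fieldname][i] = out.data.at[i, fieldname]
            out.data.at[i, fieldname] = str(rng.choice(palette))
    return out, truth


def uncorrupt(table: SumStatsTable,
              truth: dict[str, dict[int, str | None]]) -> SumStatsTable:
    """Apply a truth record inversely, restoring the original tokens exactly."""
    out = table.copy()
    for fieldname, entries in truth.items():
        for i, tok in entries.items():
            out.data.at[i, fieldname] = tok
    return out


def _write_chain(path: Path, chromosomes: tuple[str, ...], offset: int,
                 src_start: int, src_end: int, gap: tuple[int, int]) -> None:
    g0, g1 = gap
    b1, gap_len, b2 = g0 - src_start, g1 - g0, src_end - g1
    lines: list[str] = []
    for cid, chrom in enumerate(chromosomes, start=1):
        header = (f"chain 1000 chr{chrom} {_SRC_LEN} + {src_start} {src_end} "
                  f"chr{chrom} {_DST_LEN} + {src_start + offset} "
                  f"{src_end + offset} {cid}")
        lines += [header, f"{b1} {gap_len} {gap_len}", f"{b2}", ""]
    path.write_text("\n".join(lines))


def generate_chain_fixture(spec: FixtureSpec, offset: int,
                           out_path: str | Path) -> dict:
    """Write a constant-offset chain file and its inverse.

    Every fixture chromosome is shifted by ``offset`` base pairs, except for
    one deliberate 1 kb gap per chromosome (:data:`CHAIN_GAP`, source
    0-based) that stays unmappable. The inverse chain (offset −K) is written
    next to the forward one. Returns a manifest with both paths, the covered
    interval, and the 1-based gap interval per chromosome.
    """
    out_path = Path(out_path)
    inv_path = out_path.with_name(out_path.stem + ".inv" + out_path.suffix)
    s0, s1 = CHAIN_COVERED
    g0, g1 = CHAIN_GAP
    _write_chain(out_path, spec.chromosomes, offset, s0, s1, (g0, g1))
    # the inverse chain lives on the shifted assembly: both its covered
    # interval and its gap move by the forward offset, so forward ∘ inverse
    # is the identity on every forward-mappable position
    _write_chain(inv_path, spec.chromosomes, -offset,
                 s0 + offset, s1 + offset, (g0 + offset, g1 + offset))
    return {
        "chain": out_path,
        "inverse_chain": inv_path,
        "offset": offset,
        "covered_1based": (CHAIN_COVERED[0] + 1, CHAIN_COVERED[1]),
        "gap_1based": {c: (g0 + 1, g1) for c in spec.chromosomes},
    }


def generate_fixture_set(spec: FixtureSpec, out_dir: str | Path,
                         chain_offset: int | None = None) -> dict:
    """Generate the full bundle: VCF, dbSNP index, sumstats + config, chains.

    Convenience wrapper used by the CLI ``simulate`` command and the test
    harness. Returns a manifest of paths.
    """
    from .dbsnp import preprocess_dbsnp

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf = generate_dbsnp_fixture(spec, out_dir / "dbsnp.vcf")
    index = preprocess_dbsnp(vcf, out_dir / "dbsnp_index", build=spec.build)
    sumstats, config = generate_sumstats(spec, vcf, out_dir / "sumstats.tsv")
    manifest: dict = {
        "vcf": vcf, "index_dir": out_dir / "dbsnp_index", "index": index,
        "sumstats": sumstats, "config": config,
    }
    if chain_offset is not None:
        manifest["chain_manifest"] = generate_chain_fixture(
            spec, chain_offset, out_dir / "lift.chain")
    return manifest
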