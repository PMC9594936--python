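"""Per-field validators, the whole-file correctness report, and restoration
planning.

Validators are pure predicates on string tokens. Invalid data is a *result*
(a flag plus an issue code), never an exception. An entry is either
``missing`` (no token at all) or ``invalid`` (a token that fails the field's
predicate); both make the field ineligible for downstream use until restored.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import PlanningError
from .table import STANDARD_FIELDS, SumStatsTable

#: Conventional genome-wide significance threshold.
GW_SIGNIFICANCE = 5e-8

_RSID_RE = re.compile(r"^rs\d+$")
_BP_RE = re.compile(r"^\d+$")
_ALLELE_RE = re.compile(r"^[ACGT]+$", re.IGNORECASE)
_CHR_TOKENS = frozenset({str(i) for i in range(1, 24)} | {"X", "Y", "M"})


def _code(fieldname: str, token: str | None) -> str:
    return f"{fieldname}:missing" if token is None else f"{fieldname}:invalid"


def validate_chromosome(token: str | None) -> tuple[bool, str | None]:
    """Valid iff an integer 1..23 or one of X, Y, M (case-insensitive)."""
    if token is not None and token.strip().upper().lstrip("0") in _CHR_TOKENS:
        return True, None
    return False, _code("chr", token)


def validate_bp(token: str | None) -> tuple[bool, str | None]:
    """Valid iff a non-negative integer literal."""
    if token is not None and _BP_RE.match(token.strip()):
        return True, None
    return False, _code("bp", token)


def validate_rsid(token: str | None) -> tuple[bool, str | None]:
    """Valid iff ``rs`` followed by one or more digits."""
    if token is not None and _RSID_RE.match(token.strip()):
        return True, None
    return False, _code("rsid", token)


def validate_allele(token: str | None, fieldname: str = "ea") -> tuple[bool, str | None]:
    """Valid iff a dash or a non-empty string over {A,C,G,T} (any case)."""
    if token is not None:
        t = token.strip()
        if t == "-" or _ALLELE_RE.match(t):
            return True, None
    return False, _code(fieldname, token)


def _parse_float(token: str | None) -> float | None:
    if token is None:
        return None
    try:
        v = float(token)
    except ValueError:
        return None
    return v if math.isfinite(v) else None


def validate_unit_interval(token: str | None, fieldname: str = "pval") -> tuple[bool, str | None]:
    """Valid iff a finite real in [0, 1] (p-values and allele frequencies)."""
    v = _parse_float(token)
    if v is not None and 0.0 <= v <= 1.0:
        return True, None
    return False, _code(fieldname, token)


def validate_real(token: str | None, fieldname: str = "beta") -> tuple[bool, str | None]:
    """Valid iff a finite real (betas and standard errors)."""
    if _parse_float(token) is not None:
        return True, None
    return False, _code(fieldname, token)


#: field → validator taking (token) and returning (valid, issue code).
FIELD_VALIDATORS = {
    "chr": validate_chromosome,
    "bp": validate_bp,
    "rsid": validate_rsid,
    "ea": lambda t: validate_allele(t, "ea"),
    "oa": lambda t: validate_allele(t, "oa"),
    "eaf": lambda t: validate_unit_interval(t, "eaf"),
    "beta": lambda t: validate_real(t, "beta"),
    "se": lambda t: validate_real(t, "se"),
    "pval": lambda t: validate_unit_interval(t, "pval"),
}


@dataclass
class ValidationReport:
    """Per-field issue counts and per-row invalidity for one table."""

    n_rows: int
    per_field_invalid: dict[str, int]
    per_row_issues: list[frozenset[str]]
    valid_mask: pd.DataFrame  # boolean, one column per standard field
    #: fraction of genome-wide-significant rows (valid pval < 5e-8) carrying
    #: any invalid field; None when no row is GW-significant.
    gw_significant_invalid_fraction: float | None

    def to_json_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "per_field_invalid": dict(self.per_field_invalid),
            "n_invalid_rows": int(sum(bool(s) for s in self.per_row_issues)),
            "issue_counts": self.issue_counts(),
            "gw_significant_invalid_fraction": self.gw_significant_invalid_fraction,
        }

    def issue_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for issues in self.per_row_issues:
            for code in issues:
                counts[code] = counts.get(code, 0) + 1
        return dict(sorted(counts.items()))


def validate_table(table: SumStatsTable) -> ValidationReport:
    """Flag every field of every row; idempotent and free of cross-field coupling."""
    masks: dict[str, np.ndarray] = {}
    codes: list[list[str | None]] = []
    for fieldname in STANDARD_FIELDS:
        validator = FIELD_VALIDATORS[fieldname]
        results = [validator(tok) for tok in table.data[fieldname]]
        masks[fieldname] = np.array([ok for ok, _ in results], dtype=bool) \
            if results else np.zeros(0, dtype=bool)
        codes.append([c for _, c in results])
    valid_mask = pd.DataFrame(masks, columns=list(STANDARD_FIELDS))
    per_row = [
        frozenset(c for c in row if c is not None)
        for row in zip(*codes)
    ] if table.n_rows else []
    per_field_invalid = {f: int((~valid_mask[f]).sum()) for f in STANDARD_FIELDS}

    pvals = table.numeric("pval")
    gw = valid_mask["pval"].to_numpy() & (pvals < GW_SIGNIFICANCE) if table.n_rows \
        else np.zeros(0, dtype=bool)
    if gw.any():
        invalid_row = np.array([bool(s) for s in per_row])
        gw_frac = float(invalid_row[gw].mean())
    else:
        gw_frac = None

    table.row_issues = per_row
    return ValidationReport(
        n_rows=table.n_rows,
        per_field_invalid=per_field_invalid,
        per_row_issues=per_row,
        valid_mask=valid_mask,
        gw_significant_invalid_fraction=gw_frac,
    )


@dataclass
class Resources:
    """What is available for restoration: a dbSNP index and/or a chain map."""

    dbsnp: object | None = None        # DbSnpIndex
    chain: object | None = None        # ChainMap
    target_build: int = 38


@dataclass
class RestorationPlan:
    sort_key: str                      # "chrbp" | "rsid" | "none"
    routes: list[str] = dc_field(default_factory=list)
    needs_liftover: bool = False
    target_build: int = 38


def _route_row_masks(report: ValidationReport) -> dict[str, np.ndarray]:
    """Per-route boolean row masks of currently-restorable rows."""
    v = report.valid_mask
    chrbp_ok = (v["chr"] & v["bp"]).to_numpy()
    rsid_ok = v["rsid"].to_numpy()
    one_allele_bad = (v["ea"] ^ v["oa"]).to_numpy()
    stat_bad = ((~v[["beta", "se", "pval"]]).sum(axis=1) == 1).to_numpy()
    return {
        "chr_bp": (~(v["chr"] & v["bp"]).to_numpy()) & rsid_ok,
        "rsid": (~rsid_ok) & chrbp_ok,
        "allele": one_allele_bad & (rsid_ok | chrbp_ok),
        "eaf": (~v["eaf"].to_numpy()) & v["ea"].to_numpy() & (rsid_ok | chrbp_ok),
        "stat": stat_bad,
    }


def plan_restoration(report: ValidationReport, resources: Resources,
                     input_build: int | None = None) -> RestorationPlan:
    """Decide which restoration routes apply and in which sort order.

    Without a dbSNP index only the statistical (beta/se/pval) route exists.
    The sort key follows the lookup direction needed: restore chr/bp → sort
    by rsID; restore rsID → sort by chr+bp. When both directions are needed
    the key with fewer invalid entries goes first and the outer loop picks up
    the rest on a later pass.
    """
    target = resources.target_build
    needs_liftover = input_build is not None and input_build != target
    if needs_liftover and resources.chain is None:
        raise PlanningError(
            f"input build {input_build} differs from target {target} "
            "but no chain file was supplied")

    masks = _route_row_masks(report)
    routes: list[str] = []
    if resources.dbsnp is not None:
        for r in ("chr_bp", "rsid", "allele", "eaf"):
            if masks[r].any():
                routes.append(r)
    if masks["stat"].any():
        routes.append("stat")

    v = report.valid_mask
    n_bad_rsid = int((~v["rsid"]).sum())
    n_bad_chrbp = int((~(v["chr"] & v["bp"])).sum())
    if "chr_bp" in routes and "rsid" in routes:
        # both lookup directions needed: start with the better-populated key
        sort_key = "rsid" if n_bad_rsid <= n_bad_chrbp else "chrbp"
        routes.remove("rsid" if sort_key == "rsid" else "chr_bp")
    elif "chr_bp" in routes:
        sort_key = "rsid"
    elif "rsid" in routes:
        sort_key = "chrbp"
    elif any(r in routes for r in ("allele", "eaf")):
        sort_key = "chrbp" if n_bad_chrbp <= n_bad_rsid else "rsid"
    else:
        sort_key = "none"

    return RestorationPlan(sort_key=sort_key, routes=routes,
                           needs_liftover=needs_liftover, target_build=target)
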