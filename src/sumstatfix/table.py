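"""The standardized per-variant table that flows through the pipeline.

Every value is kept as its raw string token (``None`` for missing) so that
formatting is preserved exactly: no pipeline stage re-serializes a value it did
not itself restore. Numeric views are parsed on demand.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The nine standard summary-statistics fields, in internal order.
STANDARD_FIELDS: tuple[str, ...] = (
    "chr", "bp", "rsid", "ea", "oa", "eaf", "beta", "se", "pval",
)

#: Header names used in the standardized output file.
OUTPUT_HEADER: dict[str, str] = {
    "chr": "Chr", "bp": "BP", "rsid": "rsID", "ea": "EA", "oa": "OA",
    "eaf": "EAF", "beta": "Beta", "se": "SE", "pval": "Pval",
}

#: Fields scored with the banded absolute-difference accuracy (quantitative).
QUANTITATIVE_FIELDS: tuple[str, ...] = ("eaf", "beta", "se", "pval")

#: Token written for missing values in standardized output.
MISSING_OUT = "."

#: Format used for values the pipeline itself computes (full double precision).
FLOAT_FMT = ".17g"

#: Chromosome aliasing applied during lookups and concordance, never in output.
CHR_ALIASES: dict[str, str] = {"23": "X", "MT": "M"}

#: Sort order of chromosome tokens: 1..22, X, Y, M.
CHR_ORDER: dict[str, int] = {str(i): i for i in range(1, 23)}
CHR_ORDER.update({"X": 23, "Y": 24, "M": 25})


def normalize_chr(token: str) -> str:
    """Canonical chromosome token for lookup/comparison (23→X, MT→M, upper)."""
    t = token.strip().upper()
    if t.startswith("CHR"):
        t = t[3:]
    t = t.lstrip("0") or t
    return CHR_ALIASES.get(t, t)


def chr_sort_key(token: str) -> int:
    return CHR_ORDER.get(normalize_chr(token), 99)


def fmt_float(x: float) -> str:
    return format(float(x), FLOAT_FMT)


@dataclass
class SumStatsTable:
    """Ordered per-variant records with string tokens and provenance.

    Parameters
    ----------
    data
        DataFrame with exactly the columns :data:`STANDARD_FIELDS`, object
        dtype; ``None`` encodes a missing entry. Row order is the input order
        and is never changed by any pipeline stage.
    input_build
        Genome build the coordinates refer to (36, 37 or 38).
    source
        Path the table was read from, if any.
    """

    data: pd.DataFrame
    input_build: int = 38
    source: str | None = None
    #: issue codes per row, filled in by validation; parallel to ``data``.
    row_issues: list[frozenset[str]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [f for f in STANDARD_FIELDS if f not in self.data.columns]
        if missing:
            raise ValueError(f"table missing standard fields: {missing}")
        self.data = self.data.loc[:, list(STANDARD_FIELDS)].reset_index(drop=True)

    # -- construction -----------------------------------------------------

    @classmethod
    def empty(cls, input_build: int = 38) -> "SumStatsTable":
        return cls(pd.DataFrame({f: pd.Series(dtype=object) for f in STANDARD_FIELDS}),
                   input_build=input_build)

    @classmethod
    def from_records(cls, records: list[dict], input_build: int = 38) -> "SumStatsTable":
        df = pd.DataFrame(records, columns=list(STANDARD_FIELDS), dtype=object)
        df = df.where(pd.notna(df), None)
        return cls(df, input_build=input_build)

    # -- views ------------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def numeric(self, fieldname: str) -> np.ndarray:
        """Float view of a column; NaN where missing or unparseable."""
        return pd.to_numeric(self.data[fieldname], errors="coerce").to_numpy(dtype=float)

    def copy(self) -> "SumStatsTable":
        t = SumStatsTable(self.data.copy(), input_build=self.input_build,
                          source=self.source)
        t.row_issues = None if self.row_issues is None else list(self.row_issues)
        return t

    def equals(self, other: "SumStatsTable") -> bool:
        return self.data.equals(other.data)
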