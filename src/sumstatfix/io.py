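"""Reading arbitrary-layout summary-statistics files into the standard table.

A JSON column-mapping config names which raw column holds each of the nine
standard fields; nothing is ever guessed from headers. Input may be plain
text, ``.gz`` or ``.zip``. Output is always the fixed 9-column TSV.
"""
from __future__ import annotations

import gzip
import io as _io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigError
from .table import MISSING_OUT, OUTPUT_HEADER, STANDARD_FIELDS, SumStatsTable, fmt_float

DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "na", ".", "nan"})
SUPPORTED_BUILDS = (36, 37, 38)

_CONFIG_KEYS = set(STANDARD_FIELDS) | {
    "eaf_columns", "eaf_weights", "input_build", "delimiter", "missing_tokens",
}


@dataclass
class ColumnConfig:
    """Mapping from a file's raw columns to the nine standard fields.

    ``field_map`` values may be raw header names or 0-based column indices.
    When several cohort-specific EAF columns exist, ``eaf_columns`` lists them
    and ``eaf_weights`` (e.g. cohort sample sizes) weights their average.
    """

    field_map: dict[str, str | int] = field(default_factory=dict)
    eaf_columns: list[str | int] = field(default_factory=list)
    eaf_weights: list[float] | None = None
    input_build: int = 38
    delimiter: str = "\t"
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS

    def __post_init__(self) -> None:
        unknown = set(self.field_map) - set(STANDARD_FIELDS)
        if unknown:
            raise ConfigError(f"unknown standard-field name(s): {sorted(unknown)}")
        if self.input_build not in SUPPORTED_BUILDS:
            raise ConfigError(
                f"unsupported build {self.input_build!r}; expected one of {SUPPORTED_BUILDS}")
        if self.eaf_weights is not None:
            if len(self.eaf_weights) != len(self.eaf_columns):
                raise ConfigError("eaf_weights must match eaf_columns in length")
            if any(w < 0 for w in self.eaf_weights) or sum(self.eaf_weights) <= 0:
                raise ConfigError("eaf_weights must be non-negative with positive sum")
        if len(self.delimiter) != 1:
            raise ConfigError("delimiter must be a single character")
        self.missing_tokens = frozenset(self.missing_tokens)

    @classmethod
    def standard(cls, input_build: int = 38) -> "ColumnConfig":
        """Config that reads this package's own standardized output."""
        return cls(field_map={f: OUTPUT_HEADER[f] for f in STANDARD_FIELDS},
                   input_build=input_build)


def load_config(path: str | Path) -> ColumnConfig:
    """Load a JSON column-mapping config, applying defaults for absent keys."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a JSON object, got {type(raw).__name__}")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    kwargs: dict = {
        "field_map": {f: raw[f] for f in STANDARD_FIELDS if f in raw},
        "eaf_columns": raw.get("eaf_columns", []),
        "eaf_weights": raw.get("eaf_weights"),
        "input_build": raw.get("input_build", 38),
    }
    if "delimiter" in raw:
        kwargs["delimiter"] = raw["delimiter"]
    if "missing_tokens" in raw:
        kwargs["missing_tokens"] = frozenset(raw["missing_tokens"])
    return ColumnConfig(**kwargs)


def _open_text(path: Path) -> _io.TextIOBase:
    """Transparently open plain, gzip- or zip-compressed text."""
    head = path.open("rb").read(4)
    if head[:2] == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    if head[:4] == b"PK\x03\x04":
        zf = zipfile.ZipFile(path)
        names = zf.namelist()
        if not names:
            raise OSError(f"empty zip archive: {path}")
        return _io.TextIOWrapper(zf.open(names[0]), encoding="utf-8")
    return path.open("rt", encoding="utf-8")


def _resolve(col: str | int, columns: pd.Index, path: Path) -> str:
    if isinstance(col, int):
        if not 0 <= col < len(columns):
            raise ConfigError(f"column index {col} out of range for {path}")
        return columns[col]
    if col not in columns:
        raise ConfigError(f"mapped column {col!r} absent from header of {path}")
    return col


def _strip_chr_prefix(token: str | None) -> str | None:
    if token is not None and token[:3].lower() == "chr":
        return token[3:]
    return token


def load_sumstats(path: str | Path, config: ColumnConfig) -> SumStatsTable:
    """Read a summary-statistics file into the standard table.

    Columns are selected and reordered per the config; ``chr``/``CHR``
    prefixes are stripped from chromosome tokens; multiple EAF columns are
    collapsed to their weighted average over non-missing values. Unmapped
    fields are wholly missing. The data-row count is preserved exactly.
    """
    path = Path(path)
    with _open_text(path) as fh:
        raw = pd.read_csv(fh, sep=config.delimiter, dtype=str, header=0,
                          keep_default_na=False, skip_blank_lines=False)

    def tok(col: str) -> pd.Series:
        s = raw[col].astype(object).str.strip()
        return s.where(~s.isin(config.missing_tokens), None)

    out: dict[str, pd.Series] = {}
    for fieldname in STANDARD_FIELDS:
        if fieldname == "eaf" and config.eaf_columns:
            continue
        if fieldname in config.field_map:
            out[fieldname] = tok(_resolve(config.field_map[fieldname], raw.columns, path))
        else:
            out[fieldname] = pd.Series([None] * len(raw), dtype=object)

    if config.eaf_columns:
        cols = [tok(_resolve(c, raw.columns, path)) for c in config.eaf_columns]
        weights = config.eaf_weights or [1.0] * len(cols)
        vals = pd.concat([pd.to_numeric(c, errors="coerce") for c in cols], axis=1)
        vals.columns = range(len(cols))
        w = pd.DataFrame({i: vals[i].notna() * float(weights[i]) for i in range(len(cols))})
        wsum = w.sum(axis=1)
        avg = (vals.fillna(0.0) * w).sum(axis=1) / wsum.where(wsum > 0)
        out["eaf"] = pd.Series(
            [None if pd.isna(v) else fmt_float(v) for v in avg], dtype=object)

    out["chr"] = out["chr"].map(_strip_chr_prefix)
    df = pd.DataFrame(out, columns=list(STANDARD_FIELDS), dtype=object)
    df = df.where(pd.notna(df), None)
    return SumStatsTable(df, input_build=config.input_build, source=str(path))


def write_sumstats(table: SumStatsTable, path: str | Path) -> None:
    """Write the standardized 9-column TSV (``.`` for missing, Unix newlines)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(OUTPUT_HEADER[f] for f in STANDARD_FIELDS) + "\n")
        for row in table.data.itertuples(index=False):
            fh.write("\t".join(MISSING_OUT if v is None else str(v) for v in row) + "\n")
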