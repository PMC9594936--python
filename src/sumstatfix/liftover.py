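"""UCSC chain-file liftover between genome builds 36/37/38.

Chain files describe colinear alignment blocks between two assemblies in
0-based half-open coordinates; summary-statistics positions are 1-based.
Conversions happen exactly once, at this module's boundary.
"""
from __future__ import annotations

import bisect
import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ChainParseError
from .table import SumStatsTable, normalize_chr

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped alignment block (equal length on source and target)."""

    src_chr: str
    src_start: int          # 0-based half-open on source
    src_end: int
    dst_chr: str
    dst_start: int          # 0-based on destination (strand of dst_strand)
    dst_strand: str         # "+" or "-"
    dst_size: int           # destination chromosome length (for "-" reflection)
    score: float


@dataclass
class ChainMap:
    blocks: list[ChainBlock]
    src_build: str | None = None
    dst_build: str | None = None

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks,
                             key=lambda b: (b.src_chr, b.src_start, -b.score))
        self._by_chr: dict[str, list[ChainBlock]] = {}
        for b in self.blocks:
            self._by_chr.setdefault(b.src_chr, []).append(b)
        self._starts = {c: [b.src_start for b in bs] for c, bs in self._by_chr.items()}


def parse_chain(path: str | Path) -> ChainMap:
    """Parse a UCSC chain file (plain or gzip) into expanded alignment blocks."""
    path = Path(path)
    opener = gzip.open if path.open("rb").read(2) == b"\x1f\x8b" else open
    blocks: list[ChainBlock] = []
    header: list[str] | None = None
    src_pos = dst_pos = 0
    score = 0.0
    with opener(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                header = None
                continue
            parts = line.split()
            if parts[0] == "chain":
                if len(parts) < 12:
                    raise ChainParseError("chain header needs 12 fields", lineno)
                header = parts
                score = float(parts[1])
                src_pos = int(parts[5])
                dst_pos = int(parts[10])
                continue
            if header is None:
                raise ChainParseError("alignment line outside any chain", lineno)
            try:
                nums = [int(x) for x in parts]
            except ValueError as exc:
                raise ChainParseError(f"bad alignment line: {exc}", lineno) from exc
            if len(nums) not in (1, 3):
                raise ChainParseError("alignment line must have 1 or 3 numbers", lineno)
            size = nums[0]
            blocks.append(ChainBlock(
                src_chr=normalize_chr(header[2]),
                src_start=src_pos, src_end=src_pos + size,
                dst_chr=normalize_chr(header[7]),
                dst_start=dst_pos, dst_strand=header[9],
                dst_size=int(header[8]), score=score,
            ))
            if len(nums) == 3:
                src_pos += size + nums[1]
                dst_pos += size + nums[2]
            else:
                if src_pos + size != int(header[6]):
                    raise ChainParseError(
                        f"block arithmetic does not reach src end "
                        f"({src_pos + size} != {header[6]})", lineno)
                header = None
    if not blocks:
        raise ChainParseError(f"no chains found in {path}")
    return ChainMap(blocks)


def map_position(chain: ChainMap, chrom: str, bp_1based: int) -> tuple[str, int] | None:
    """Map a 1-based (chr, bp) to the destination build, or None if uncovered.

    When several chains cover a position the highest-scoring one wins
    (ties are logged). Positions on "-" strand chains are reflected onto the
    destination's forward strand.
    """
    key = normalize_chr(chrom)
    cand = chain._by_chr.get(key)
    if not cand:
        return None
    pos0 = bp_1based - 1
    i = bisect.bisect_right(chain._starts[key], pos0)
    hits = []
    # blocks sorted by start; scan left while they might still cover pos0
    for b in reversed(cand[:i]):
        if b.src_end > pos0:
            hits.append(b)
        # src blocks within one chain don't overlap, but chains may; keep
        # scanning until starts are too far left to matter for desk-scale maps
        if pos0 - b.src_start > 500_000_000:
            break
    if not hits:
        return None
    best = max(hits, key=lambda b: b.score)
    if sum(1 for b in hits if b.score == best.score) > 1:
        log.info("tie between chains covering %s:%d; using first", chrom, bp_1based)
    offset = pos0 - best.src_start
    dst0 = best.dst_start + offset
    if best.dst_strand == "-":
        dst0 = best.dst_size - 1 - dst0
    return best.dst_chr, dst0 + 1


def lift_table(table: SumStatsTable, chain: ChainMap) -> tuple[SumStatsTable, int]:
    """Lift every row with a syntactically valid (chr, bp) to the target build.

    Rows whose position falls outside all chain blocks are retained with
    chr/bp cleared (flagged missing), leaving them eligible for rsID-based
    restoration later. Returns the lifted table and the unmapped-row count.
    The row count never changes.
    """
    from .validation import validate_bp, validate_chromosome

    out = table.copy()
    n_unmapped = 0
    chrs = out.data["chr"].tolist()
    bps = out.data["bp"].tolist()
    for i in range(out.n_rows):
        if not (validate_chromosome(chrs[i])[0] and validate_bp(bps[i])[0]):
            continue
        mapped = map_position(chain, chrs[i], int(bps[i]))
        if mapped is None:
            chrs[i] = None
            bps[i] = None
            n_unmapped += 1
        else:
            chrs[i], bps[i] = mapped[0], str(mapped[1])
    out.data["chr"] = pd.Series(chrs, dtype=object)
    out.data["bp"] = pd.Series(bps, dtype=object)
    return out, n_unmapped
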