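"""dbSNP-style VCF preprocessing and the two sorted lookup tables.

A dbSNP VCF is condensed into two sort orders — by (chromosome, position)
and by numeric rsID — so that every restoration query is a binary search.
Per-allele frequencies are taken from dbSNP's ``FREQ`` INFO annotation
(``source:f_ref,f_alt1,...`` groups separated by ``|``), aligned to
(REF, ALT1, ...).
"""
from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .errors import PreprocessError
from .table import chr_sort_key, normalize_chr

log = logging.getLogger(__name__)

BY_CHRBP_FILE = "by_chrbp.tsv.gz"
BY_RSID_FILE = "by_rsid.tsv.gz"
SIDECAR_FILE = "index.json"


@dataclass(frozen=True)
class VariantRecord:
    """One dbSNP variant: site, alleles, and per-source allele frequencies."""

    rsid_num: int
    chr: str
    bp: int                      # 1-based VCF POS
    ref: str
    alts: tuple[str, ...]
    #: source name → frequencies aligned to (ref, *alts); None where absent.
    freqs: dict[str, tuple[float | None, ...]] = field(default_factory=dict)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    def frequency_of(self, allele: str, sources: tuple[str, ...]) -> float | None:
        """Frequency of ``allele`` from the first preferred source carrying it."""
        allele = allele.upper()
        if allele not in self.alleles:
            return None
        i = self.alleles.index(allele)
        for src in sources:
            vals = self.freqs.get(src)
            if vals is not None and i < len(vals) and vals[i] is not None:
                return vals[i]
        return None


@dataclass
class DbSnpIndex:
    """Variant records queryable by (chr, bp) and by rsID number."""

    records: list[VariantRecord]          # sorted by (chr order, bp, rsid)
    build: int = 38
    source: str | None = None
    freq_sources: tuple[str, ...] = ()
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.records = sorted(self.records,
                              key=lambda r: (chr_sort_key(r.chr), r.bp, r.rsid_num))
        self._chrbp_keys = [(chr_sort_key(r.chr), r.bp) for r in self.records]
        self._by_rsid = sorted(range(len(self.records)),
                               key=lambda i: self.records[i].rsid_num)
        self._rsid_keys = [self.records[i].rsid_num for i in self._by_rsid]

    def __len__(self) -> int:
        return len(self.records)


def _parse_freq_info(freq_field: str, n_alleles: int) -> dict[str, tuple[float | None, ...]]:
    out: dict[str, tuple[float | None, ...]] = {}
    for group in freq_field.split("|"):
        if ":" not in group:
            continue
        name, _, vals = group.partition(":")
        parsed: list[float | None] = []
        for tok in vals.split(","):
            tok = tok.strip()
            try:
                parsed.append(float(tok))
            except ValueError:
                parsed.append(None)
        parsed = (parsed + [None] * n_alleles)[:n_alleles]
        out[name.strip()] = tuple(parsed)
    return out


def preprocess_dbsnp(vcf_path: str | Path, out_dir: str | Path,
                     build: int = 38) -> DbSnpIndex:
    """Condense a dbSNP VCF into the two sorted lookup tables.

    Records without a parseable ``rs<digits>`` ID are skipped and counted.
    Both sort orders are materialized on disk (BGZF TSV) next to a JSON
    sidecar with provenance; :func:`load_index` reads them back.
    """
    vcf_path, out_dir = Path(vcf_path), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records: list[VariantRecord] = []
    n_skipped = 0
    sources: list[str] = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            try:
                rid = rec.id
                if rid is None or not rid.startswith("rs") or not rid[2:].isdigit():
                    n_skipped += 1
                    continue
                alts = tuple(a for a in (rec.alts or ()) if a is not None)
                freq_raw = rec.info.get("FREQ")
                freqs: dict[str, tuple[float | None, ...]] = {}
                if freq_raw is not None:
                    if isinstance(freq_raw, tuple):
                        freq_raw = ",".join(str(x) for x in freq_raw)
                    freqs = _parse_freq_info(str(freq_raw), 1 + len(alts))
                    for s in freqs:
                        if s not in sources:
                            sources.append(s)
                records.append(VariantRecord(
                    rsid_num=int(rid[2:]),
                    chr=normalize_chr(rec.chrom),
                    bp=rec.pos,
                    ref=(rec.ref or "").upper(),
                    alts=tuple(a.upper() for a in alts),
                    freqs=freqs,
                ))
            except (ValueError, TypeError) as exc:  # malformed record
                n_skipped += 1
                log.warning("skipping malformed VCF record: %s", exc)
    if not records:
        raise PreprocessError(f"no usable dbSNP records in {vcf_path}")
    if n_skipped:
        log.info("skipped %d unusable VCF records", n_skipped)

    records.sort(key=lambda r: (chr_sort_key(r.chr), r.bp, r.rsid_num))
    index = DbSnpIndex(records, build=build, source=str(vcf_path),
                       freq_sources=tuple(sources), n_skipped=n_skipped)
    _write_index(index, out_dir)
    return index


def _record_line(r: VariantRecord) -> str:
    freqs = "|".join(
        f"{s}:" + ",".join("." if v is None else format(v, ".10g") for v in vals)
        for s, vals in r.freqs.items()) or "."
    return "\t".join([str(r.rsid_num), r.chr, str(r.bp), r.ref,
                      ",".join(r.alts) or ".", freqs])


def _write_index(index: DbSnpIndex, out_dir: Path) -> None:
    header = "#rsid_num\tchr\tbp\tref\talts\tfreqs\n"
    with pysam.BGZFile(str(out_dir / BY_CHRBP_FILE), "wb") as fh:
        fh.write(header.encode())
        for r in index.records:
            fh.write((_record_line(r) + "\n").encode())
    with pysam.BGZFile(str(out_dir / BY_RSID_FILE), "wb") as fh:
        fh.write(header.encode())
        for i in index._by_rsid:
            fh.write((_record_line(index.records[i]) + "\n").encode())
    sidecar = {
        "build": index.build,
        "n_records": len(index),
        "n_skipped": index.n_skipped,
        "freq_sources": list(index.freq_sources),
        "source_vcf": index.source,
    }
    (out_dir / SIDECAR_FILE).write_text(json.dumps(sidecar, indent=2) + "\n")


def load_index(index_dir: str | Path) -> DbSnpIndex:
    """Load a preprocessed index directory written by :func:`preprocess_dbsnp`."""
    index_dir = Path(index_dir)
    sidecar = json.loads((index_dir / SIDECAR_FILE).read_text())
    records: list[VariantRecord] = []
    with pysam.BGZFile(str(index_dir / BY_CHRBP_FILE), "rb") as fh:
        for line in fh:
            line = line.decode().rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rsid_num, chrom, bp, ref, alts, freqs = line.split("\t")
            alts_t = tuple(alts.split(",")) if alts != "." else ()
            freq_map = {} if freqs == "." else _parse_freq_info(freqs, 1 + len(alts_t))
            records.append(VariantRecord(int(rsid_num), chrom, int(bp), ref,
                                         alts_t, freq_map))
    return DbSnpIndex(records, build=sidecar["build"], source=sidecar.get("source_vcf"),
                      freq_sources=tuple(sidecar.get("freq_sources", ())),
                      n_skipped=sidecar.get("n_skipped", 0))


# -- queries ---------------------------------------------------------------

def lookup_by_rsid(index: DbSnpIndex, rsid_num: int) -> VariantRecord | None:
    """Record with the given rsID number, or None.

    Duplicate rsIDs keep the record first in (chr, bp) order; the duplication
    is logged.
    """
    i = bisect.bisect_left(index._rsid_keys, rsid_num)
    if i == len(index._rsid_keys) or index._rsid_keys[i] != rsid_num:
        return None
    hits = []
    while i < len(index._rsid_keys) and index._rsid_keys[i] == rsid_num:
        hits.append(index.records[index._by_rsid[i]])
        i += 1
    if len(hits) > 1:
        log.warning("rs%d appears %d times; keeping first by (chr, bp)",
                    rsid_num, len(hits))
        hits.sort(key=lambda r: (chr_sort_key(r.chr), r.bp))
    return hits[0]


def lookup_by_chrbp(index: DbSnpIndex, chrom: str, bp: int) -> list[VariantRecord]:
    """All records at (chr, bp); chromosome passed through the 23↔X alias."""
    key = (chr_sort_key(normalize_chr(chrom)), bp)
    lo = bisect.bisect_left(index._chrbp_keys, key)
    hi = bisect.bisect_right(index._chrbp_keys, key)
    return sorted(index.records[lo:hi], key=lambda r: r.rsid_num)


def most_likely_allele(records: list[VariantRecord], known_allele: str,
                       sources: tuple[str, ...] = ()) -> str | None:
    """Most likely partner of ``known_allele`` among the given site records.

    Among records whose allele set contains the known allele, the partner with
    the highest annotated frequency wins; ties prefer the reference allele,
    then alphabetical order. None when no record carries the known allele or
    no partner exists.
    """
    known = known_allele.upper()
    candidates: dict[str, tuple[float, bool]] = {}   # allele → (freq, is_ref)
    for rec in records:
        if known not in rec.alleles:
            continue
        srcs = sources or tuple(rec.freqs)
        for partner in rec.alleles:
            if partner == known:
                continue
            f = rec.frequency_of(partner, srcs)
            score = -1.0 if f is None else f
            prev = candidates.get(partner)
            is_ref = partner == rec.ref
            if prev is None or score > prev[0]:
                candidates[partner] = (score, is_ref)
    if not candidates:
        return None
    best = max(candidates.items(),
               key=lambda kv: (kv[1][0], kv[1][1], [-ord(c) for c in kv[0]]))
    tied = [a for a, (s, _) in candidates.items() if s == best[1][0]]
    if len(tied) > 1:
        log.info("allele tie at frequency %.4g among %s; chose %s",
                 best[1][0], sorted(tied), best[0])
    return best[0]


def allele_frequency(records: list[VariantRecord], allele: str,
                     sources: tuple[str, ...] = ()) -> float | None:
    """Frequency of ``allele`` from the first record carrying it, or None."""
    for rec in records:
        f = rec.frequency_of(allele, sources or tuple(rec.freqs))
        if f is not None:
            return f
    return None
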