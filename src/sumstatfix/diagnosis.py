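"""Diagnosis outputs: where do the invalid entries sit on the significance axis?

Rows are binned by −log10(p) so that the stacked valid/invalid histogram
shows at a glance whether the broken entries cluster among the genome-wide
significant variants (where they would hurt downstream PRS work most) or in
the null bulk. Rows whose p-value is itself invalid cannot be placed and are
counted separately.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import ParameterError
from .table import SumStatsTable
from .validation import GW_SIGNIFICANCE, ValidationReport

#: floor for p = 0 so it lands in the most significant bin
_P_FLOOR = 1e-320


@dataclass
class DiagnosisReport:
    """Valid/invalid counts per significance bin plus per-bin issue breakdowns."""

    bin_edges: list[float]                  # length n_bins + 1, −log10(p) scale
    valid_counts: list[int]
    invalid_counts: list[int]
    per_bin_issue_counts: list[dict[str, int]]
    unbinned_count: int
    n_rows: int

    def to_json_dict(self) -> dict:
        return {
            "bin_edges_neglog10p": self.bin_edges,
            "valid_counts": self.valid_counts,
            "invalid_counts": self.invalid_counts,
            "per_bin_issue_counts": self.per_bin_issue_counts,
            "unbinned_count": self.unbinned_count,
            "n_rows": self.n_rows,
        }


def bin_by_significance(table: SumStatsTable, report: ValidationReport,
                        n_bins: int = 10) -> DiagnosisReport:
    """Assign each row with a valid p-value to one −log10(p) bin.

    A row counts as invalid when *any* of its nine fields is flagged. Every
    row lands in exactly one bin or in ``unbinned_count``, so
    Σvalid + Σinvalid + unbinned = n_rows.
    """
    if n_bins < 1:
        raise ParameterError(f"n_bins must be >= 1, got {n_bins}")
    n = table.n_rows
    pval_ok = report.valid_mask["pval"].to_numpy() if n else np.zeros(0, bool)
    row_invalid = np.array([bool(s) for s in report.per_row_issues], dtype=bool) \
        if n else np.zeros(0, bool)

    p = table.numeric("pval")
    neglog = -np.log10(np.clip(p, _P_FLOOR, None), where=pval_ok,
                       out=np.zeros_like(p))
    scores = neglog[pval_ok]
    if scores.size:
        lo, hi = float(scores.min()), float(scores.max())
        if hi <= lo:
            hi = lo + 1.0
    else:
        lo, hi = 0.0, 1.0
    edges = np.linspace(lo, hi, n_bins + 1)

    idx = np.clip(np.digitize(scores, edges[1:-1], right=False), 0, n_bins - 1)
    inv = row_invalid[pval_ok]
    valid_counts = np.bincount(idx[~inv], minlength=n_bins)
    invalid_counts = np.bincount(idx[inv], minlength=n_bins)

    per_bin: list[dict[str, int]] = [dict() for _ in range(n_bins)]
    binned_rows = np.flatnonzero(pval_ok)
    for j, i in enumerate(binned_rows):
        for code in report.per_row_issues[i]:
            d = per_bin[idx[j]]
            d[code] = d.get(code, 0) + 1

    return DiagnosisReport(
        bin_edges=[float(e) for e in edges],
        valid_counts=[int(c) for c in valid_counts],
        invalid_counts=[int(c) for c in invalid_counts],
        per_bin_issue_counts=[dict(sorted(d.items())) for d in per_bin],
        unbinned_count=int((~pval_ok).sum()),
        n_rows=n,
    )


def render_diagnosis(report: DiagnosisReport, out_dir: str | Path) -> list[Path]:
    """Write the stacked histogram, one issue bar chart per bin, and the JSON.

    Returns the list of files written (deterministic given the report).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    edges = np.asarray(report.bin_edges)
    centers = (edges[:-1] + edges[1:]) / 2
    widths = np.diff(edges)

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.bar(centers, report.valid_counts, width=widths, color="tab:blue",
           label="valid", align="center")
    ax.bar(centers, report.invalid_counts, width=widths,
           bottom=report.valid_counts, color="tab:red", label="invalid",
           align="center")
    gw = -np.log10(GW_SIGNIFICANCE)
    if edges[0] <= gw <= edges[-1]:
        ax.axvline(gw, color="black", linestyle="--", linewidth=1,
                   label="genome-wide significance")
    ax.set_xlabel(r"$-\log_{10}(p)$")
    ax.set_ylabel("SNP count")
    ax.set_title(f"SNP validity by significance "
                 f"(n={report.n_rows}, unbinnable={report.unbinned_count})")
    ax.legend()
    hist_path = out_dir / "diagnosis_histogram.png"
    fig.savefig(hist_path, dpi=100)
    plt.close(fig)
    written.append(hist_path)

    for b, issues in enumerate(report.per_bin_issue_counts):
        fig, ax = plt.subplots(figsize=(6, 3.5))
        labels = sorted(issues)
        ax.bar(range(len(labels)), [issues[k] for k in labels], color="tab:red")
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
        ax.set_ylabel("issue count")
        ax.set_title(f"Issues in bin {b + 1} "
                     f"[{edges[b]:.2f}, {edges[b + 1]:.2f}) on $-\\log_{{10}}(p)$")
        fig.tight_layout()
        path = out_dir / f"bin_{b + 1:02d}_issues.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    json_path = out_dir / "diagnosis_report.json"
    json_path.write_text(json.dumps(report.to_json_dict(), indent=2,
                                    sort_keys=True) + "\n")
    written.append(json_path)
    return written
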