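"""Cross-modality genotype concordance and sample-identity verification.

Two samples from the same individual share genotypes at (nearly) every
locus called in both, while unrelated individuals agree only at the rate
chance allows (sum of squared genotype frequencies — 37.5 % at MAF 0.5
under Hardy–Weinberg). The concordance matrix over all sample pairs
therefore separates cleanly, and a sample swap shows up as an off-diagonal
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    NO_CALL,
    ConcordanceCell,
    ConcordanceMatrix,
    GenotypeMatrix,
    OmicidError,
)

MODES = ("full-dosage", "zygosity")

#: Default confirmation thresholds (percent agreement with the paired WGS
#: sample): DNA-level comparisons are near-perfect, RNA-seq tolerates
#: allele-specific expression and coverage noise.
DEFAULT_THRESHOLD_DNA = 90.0
DEFAULT_THRESHOLD_RNA = 60.0


def _comparable(v: np.ndarray, mode: str) -> np.ndarray:
    if mode == "full-dosage":
        return v
    if mode == "zygosity":
        # collapse both homozygotes to one class; NO_CALL preserved
        out = np.where(v == 2, 0, v)
        return np.where(v == NO_CALL, NO_CALL, out)
    raise OmicidError(f"unknown comparison mode {mode!r}")


def pair_concordance(a: np.ndarray, b: np.ndarray, mode: str = "full-dosage") -> ConcordanceCell:
    """Concordance between two genotype vectors over the same panel.

    Only loci called in both vectors enter the denominator; a pair with no
    shared called locus yields an undefined cell (pct is None), never 0 %.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise OmicidError("genotype vectors have different lengths")
    shared = (a != NO_CALL) & (b != NO_CALL)
    av = _comparable(a[shared], mode)
    bv = _comparable(b[shared], mode)
    return ConcordanceCell(int(shared.sum()), int((av == bv).sum()))


def concordance_matrix(
    a: GenotypeMatrix, b: GenotypeMatrix, mode: str = "full-dosage", label: str = ""
) -> ConcordanceMatrix:
    """All-pairs concordance between the samples of two genotype matrices.

    The matrices must share their panel (same loci, same order after
    restriction); transposing the arguments transposes the result.
    """
    if a.panel.ids != b.panel.ids:
        common = [i for i in a.panel.ids if i in set(b.panel.ids)]
        if not common:
            raise OmicidError("genotype matrices share no loci")
        shared_panel = a.panel.subset(common, name="shared")
        a = a.restrict(shared_panel)
        b = b.restrict(shared_panel)
    if not label:
        label = f"{a.modality} vs {b.modality}"
    cells = [
        [pair_concordance(a.dosages[i], b.dosages[j], mode) for j in range(b.n_samples)]
        for i in range(a.n_samples)
    ]
    return ConcordanceMatrix(list(a.sample_ids), list(b.sample_ids), cells, label)


@dataclass
class MatchReportRow:
    """One row of the identity-verification report."""

    sample_id: str
    comparison: str
    loci_n: int  # loci called in both members of the expected pair
    loci_pct: float  # 100 * loci_n / panel size
    n_match: int
    matched_pct: float | None
    status: str  # confirmed | flagged | unevaluable
    best_match: str  # argmax column sample (competitor when flagged)


def verify_identity(
    cm: ConcordanceMatrix,
    pairing: dict[str, str] | None = None,
    threshold: float = DEFAULT_THRESHOLD_DNA,
    panel_size: int | None = None,
) -> list[MatchReportRow]:
    """Confirm or flag each row sample against its expected column sample.

    A row is confirmed iff its paired cell is defined, is the row maximum
    (ties flag, never silently confirm) and meets the threshold; otherwise
    it is flagged with the best-scoring competitor. Rows whose paired cell
    is undefined are unevaluable.
    """
    if pairing is None:
        pairing = {s: s for s in cm.row_samples}
    unknown = [
        (r, c)
        for r, c in pairing.items()
        if r not in cm.row_samples or c not in cm.col_samples
    ]
    if unknown:
        raise OmicidError(f"pairing references unknown samples: {unknown}")
    if panel_size is None:
        panel_size = max(
            (c.n_shared for row in cm.cells for c in row),
            default=0,
        )
    rows: list[MatchReportRow] = []
    for i, sid in enumerate(cm.row_samples):
        expected = pairing.get(sid)
        if expected is None:
            continue
        cells = cm.cells[i]
        pcts = np.array([np.nan if c.pct is None else c.pct for c in cells])
        paired = cm.cell(sid, expected)
        if paired.pct is None:
            rows.append(
                MatchReportRow(sid, cm.label, 0, 0.0, 0, None, "unevaluable", "")
            )
            continue
        finite = np.nan_to_num(pcts, nan=-1.0)
        best_j = int(np.argmax(finite))
        is_unique_max = (
            finite[cm.col_samples.index(expected)] >= finite.max()
            and (finite == finite.max()).sum() == 1
        )
        confirmed = is_unique_max and cm.col_samples[best_j] == expected and paired.pct >= threshold
        rows.append(
            MatchReportRow(
                sid,
                cm.label,
                paired.n_shared,
                100.0 * paired.n_shared / panel_size if panel_size else float("nan"),
                paired.n_match,
                paired.pct,
                "confirmed" if confirmed else "flagged",
                cm.col_samples[best_j],
            )
        )
    return rows


@dataclass
class MatchSummary:
    """Cohort-level agreement for one comparison.

    ``macro_pct`` averages the per-sample percentages; ``micro_pct`` pools
    matches over pooled shared loci. Both are reported because a quoted
    "mean agreement" can be either. ``micro_pct_truncated`` is the pooled
    value truncated (not rounded) to two decimals, a convention some
    summaries use.
    """

    comparison: str
    n_rows: int
    total_shared: int
    total_match: int
    macro_pct: float
    micro_pct: float
    macro_pct_2dp: float
    micro_pct_2dp: float
    micro_pct_truncated: float
    mean_loci_pct: float


def summarize_matching(rows: list[MatchReportRow], panel_size: int | None = None) -> MatchSummary | None:
    """Aggregate report rows for one comparison label.

    Returns None for empty input. Rows with undefined concordance are
    excluded from the means.
    """
    if not rows:
        return None
    labels = {r.comparison for r in rows}
    if len(labels) > 1:
        raise OmicidError(f"rows mix comparison labels: {sorted(labels)}")
    evaluable = [r for r in rows if r.matched_pct is not None]
    if not evaluable:
        return None
    total_shared = sum(r.loci_n for r in evaluable)
    total_match = sum(r.n_match for r in evaluable)
    macro = float(np.mean([r.matched_pct for r in evaluable]))
    if total_shared == 0:
        micro = float("nan")
    else:
        micro = 100.0 * total_match / total_shared
    if panel_size:
        mean_loci_pct = float(np.mean([100.0 * r.loci_n / panel_size for r in evaluable]))
    else:
        mean_loci_pct = float(np.mean([r.loci_pct for r in evaluable]))
    return MatchSummary(
        comparison=labels.pop(),
        n_rows=len(evaluable),
        total_shared=total_shared,
        total_match=total_match,
        macro_pct=macro,
        micro_pct=micro,
        macro_pct_2dp=round(macro, 2),
        micro_pct_2dp=round(micro, 2),
        micro_pct_truncated=float("nan") if np.isnan(micro) else int(micro * 100) / 100.0,
        mean_loci_pct=mean_loci_pct,
    )


def report_frame(rows: list[MatchReportRow]) -> pd.DataFrame:
    """Report rows as a table (per-sample layout with loci n/% and matched %)."""
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "comparison": r.comparison,
                "loci_n": r.loci_n,
                "loci_pct": round(r.loci_pct, 2),
                "matched_pct": None if r.matched_pct is None else round(r.matched_pct, 2),
                "status": r.status,
                "best_match": r.best_match,
            }
            for r in rows
        ]
    )


def plot_concordance(cm: ConcordanceMatrix, path: str) -> None:
    """Save a heat map of the match percentages (0–100)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = cm.pct_frame()
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(frame.to_numpy(), vmin=0, vmax=100, cmap="Blues")
    ax.set_xticks(range(len(cm.col_samples)), cm.col_samples, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.row_samples)), cm.row_samples, fontsize=7)
    ax.set_title(cm.label)
    fig.colorbar(im, ax=ax, label="% matching genotypes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
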