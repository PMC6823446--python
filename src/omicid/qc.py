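"""Sequencing and array quality-control summary statistics.

Covers the per-sample metrics a multi-omics QC table reports: median
coverage depth and the fraction of bases at or above a depth threshold,
read duplication and GC percentages, array detection-p/bead-count
availability and pass rates, and simple mean/min/max aggregation of a
table column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import BetaMatrix, OmicidError

DEFAULT_DEPTH_THRESHOLD = 30
DEFAULT_P_CUT = 0.01
DEFAULT_BEAD_CUT = 3


@dataclass(frozen=True)
class CoverageSummary:
    median_depth: float
    fraction_ge_threshold: float
    threshold: int
    n_positions: int


def coverage_summary(depths: Iterable[int], threshold: int = DEFAULT_DEPTH_THRESHOLD) -> CoverageSummary:
    """Median depth and fraction of positions at >= threshold.

    The median is the lower median for even-length input, matching the
    integer depth style of coverage tables (e.g. "32.0X").
    """
    d = np.asarray(list(depths))
    if d.size == 0:
        raise OmicidError("coverage summary needs at least one position")
    if (d < 0).any():
        raise OmicidError("negative depths")
    s = np.sort(d)
    median = float(s[(d.size - 1) // 2])  # lower median
    frac = float((d >= threshold).sum() / d.size)
    return CoverageSummary(median, frac, threshold, int(d.size))


def read_stats(n_duplicates: int, n_total: int, base_counts: Mapping[str, int]) -> tuple[float, float]:
    """Duplication % and GC % from read and base tallies.

    GC excludes N bases from the denominator.
    """
    if n_total <= 0:
        raise OmicidError("n_total must be positive")
    if not 0 <= n_duplicates <= n_total:
        raise OmicidError("n_duplicates must be within [0, n_total]")
    acgt = sum(int(base_counts.get(b, 0)) for b in "ACGT")
    if acgt <= 0:
        raise OmicidError("no A/C/G/T bases counted")
    gc = int(base_counts.get("G", 0)) + int(base_counts.get("C", 0))
    return 100.0 * n_duplicates / n_total, 100.0 * gc / acgt


@dataclass(frozen=True)
class ArrayQCSummary:
    frac_detp_available: float
    frac_detp_pass: float  # of available, p < p_cut
    frac_beads_available: float
    frac_beads_pass: float  # of available, count >= bead_cut
    mean_bead_count: float


def _availability(df: pd.DataFrame, col: str) -> tuple[float, np.ndarray]:
    vals = df[col].to_numpy(dtype=float)
    avail = ~np.isnan(vals)
    return float(avail.mean()) if vals.size else float("nan"), vals[avail]


def array_qc_summary(
    bm: BetaMatrix, p_cut: float = DEFAULT_P_CUT, bead_cut: int = DEFAULT_BEAD_CUT
) -> tuple[pd.DataFrame, ArrayQCSummary]:
    """Detection-p and bead-count QC fractions per array column plus pooled.

    Pass fractions are computed over available values only. The pooled
    summary is the unweighted mean of the per-column fractions.
    """
    rows = []
    for col in bm.columns:
        detp_avail, detp = _availability(bm.detection_p, col)
        beads_avail, beads = _availability(bm.bead_count, col)
        rows.append(
            {
                "column": col,
                "frac_detp_available": detp_avail,
                "frac_detp_pass": float((detp < p_cut).mean()) if detp.size else float("nan"),
                "frac_beads_available": beads_avail,
                "frac_beads_pass": float((beads >= bead_cut).mean()) if beads.size else float("nan"),
                "mean_bead_count": float(beads.mean()) if beads.size else float("nan"),
            }
        )
    per_col = pd.DataFrame(rows).set_index("column")
    pooled = ArrayQCSummary(
        *(float(per_col[c].mean()) for c in per_col.columns)
    )
    return per_col.reset_index(), pooled


@dataclass(frozen=True)
class ColumnAggregate:
    mean: float
    min: float
    max: float


def table_aggregate(values: Iterable[float], decimals: int = 2) -> ColumnAggregate:
    """Mean, min and max of a numeric table column, rounded."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise OmicidError("cannot aggregate an empty column")
    return ColumnAggregate(
        round(float(v.mean()), decimals),
        round(float(v.min()), decimals),
        round(float(v.max()), decimals),
    )
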