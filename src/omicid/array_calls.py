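"""Genotype calls from SNP-probe methylation-array beta values.

At SNP-targeting probes the array signal is genetic, not epigenetic: beta
values cluster in three peaks — near 0 and 1 for the two homozygotes and
near 0.5 for heterozygotes — so fixed thresholds separate the zygosity
classes. Probe orientation (which allele drives beta toward 1) converts a
class into an alt-allele dosage.
"""

from __future__ import annotations

import math
from enum import Enum

import numpy as np
import pandas as pd

from .core import NO_CALL, BetaMatrix, GenotypeMatrix, LocusPanel, OmicidError, TISSUES

DEFAULT_LOW_CUT = 0.25
DEFAULT_HIGH_CUT = 0.75
DETECTION_P_CUT = 0.01
BEAD_COUNT_MIN = 3


class BetaClass(Enum):
    LOW = "LOW"
    MID = "MID"
    HIGH = "HIGH"
    NO_CALL = "NO_CALL"


def classify_beta(
    beta: float | None, low_cut: float = DEFAULT_LOW_CUT, high_cut: float = DEFAULT_HIGH_CUT
) -> BetaClass:
    """Assign a beta value to its zygosity peak.

    MID (between the cuts, inclusive) is heterozygous; LOW and HIGH are the
    two homozygotes. Missing values give NO_CALL; values outside [0, 1] are
    rejected.
    """
    if not 0 <= low_cut < high_cut <= 1:
        raise OmicidError(f"invalid cuts low={low_cut} high={high_cut}")
    if beta is None or (isinstance(beta, float) and math.isnan(beta)):
        return BetaClass.NO_CALL
    if not 0 <= beta <= 1:
        raise OmicidError(f"beta value {beta} outside [0, 1]")
    if beta < low_cut:
        return BetaClass.LOW
    if beta > high_cut:
        return BetaClass.HIGH
    return BetaClass.MID


def classify_matrix(
    bm: BetaMatrix, low_cut: float = DEFAULT_LOW_CUT, high_cut: float = DEFAULT_HIGH_CUT
) -> pd.DataFrame:
    """Per-cell BetaClass for every probe x column."""
    return bm.beta.map(lambda b: classify_beta(b, low_cut, high_cut))


def array_genotypes(
    bm: BetaMatrix,
    low_cut: float = DEFAULT_LOW_CUT,
    high_cut: float = DEFAULT_HIGH_CUT,
    qc_filter: bool = False,
    tissue: str = "blood",
) -> GenotypeMatrix:
    """Call alt-allele dosages from one tissue's array columns.

    MID maps to dosage 1; HIGH maps to 2 when the probe's high-beta allele
    is alt, else 0 (LOW is the complement). With ``qc_filter`` on, cells
    with detection p >= 0.01 or bead count < 3 become NO_CALL.
    """
    if tissue not in TISSUES:
        raise OmicidError(f"unknown tissue {tissue!r}")
    cols = [c for c in bm.columns if BetaMatrix.split_column(c)[1] == tissue]
    if not cols:
        raise OmicidError(f"no {tissue} columns in beta matrix")
    sample_ids = [BetaMatrix.split_column(c)[0] for c in cols]
    panel = LocusPanel("array", [p.locus for p in bm.probes])
    high_is_alt = np.array([p.high_beta_allele == "alt" for p in bm.probes])

    grid = np.full((len(cols), len(panel)), NO_CALL, dtype=np.int8)
    for i, col in enumerate(cols):
        for j, probe in enumerate(bm.probes):
            if qc_filter:
                detp = bm.detection_p.at[probe.probe_id, col]
                beads = bm.bead_count.at[probe.probe_id, col]
                if (
                    pd.isna(detp)
                    or detp >= DETECTION_P_CUT
                    or pd.isna(beads)
                    or beads < BEAD_COUNT_MIN
                ):
                    continue
            cls = classify_beta(bm.beta.at[probe.probe_id, col], low_cut, high_cut)
            if cls is BetaClass.NO_CALL:
                continue
            if cls is BetaClass.MID:
                grid[i, j] = 1
            elif cls is BetaClass.HIGH:
                grid[i, j] = 2 if high_is_alt[j] else 0
            else:
                grid[i, j] = 0 if high_is_alt[j] else 2
    return GenotypeMatrix(sample_ids, panel, grid, "array")


def cross_tissue_check(
    bm: BetaMatrix,
    low_cut: float = DEFAULT_LOW_CUT,
    high_cut: float = DEFAULT_HIGH_CUT,
) -> pd.DataFrame:
    """Blood-vs-saliva zygosity agreement per individual.

    Agreement is computed at the BetaClass level over probes classified in
    both tissues. Individuals lacking one tissue are reported as
    unevaluable rather than raising. Returns a frame with columns
    individual, n_probes, n_match, pct, mismatching_probes, evaluable.
    """
    classes = classify_matrix(bm, low_cut, high_cut)
    by_ind: dict[str, dict[str, str]] = {}
    for col in bm.columns:
        sample, tissue = BetaMatrix.split_column(col)
        by_ind.setdefault(sample, {})[tissue] = col

    rows = []
    for ind, tissues in by_ind.items():
        if not all(t in tissues for t in TISSUES):
            rows.append(
                {
                    "individual": ind,
                    "n_probes": 0,
                    "n_match": 0,
                    "pct": np.nan,
                    "mismatching_probes": "",
                    "evaluable": False,
                }
            )
            continue
        blood = classes[tissues["blood"]]
        saliva = classes[tissues["saliva"]]
        called = (blood != BetaClass.NO_CALL) & (saliva != BetaClass.NO_CALL)
        match = called & (blood == saliva)
        mismatches = [pid for pid in classes.index[called & ~match]]
        n = int(called.sum())
        rows.append(
            {
                "individual": ind,
                "n_probes": n,
                "n_match": int(match.sum()),
                "pct": 100.0 * match.sum() / n if n else np.nan,
                "mismatching_probes": ",".join(mismatches),
                "evaluable": n > 0,
            }
        )
    return pd.DataFrame(rows)
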