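"""Forced diploid genotype calls at fixed loci from allele read counts.

A transparent binomial MAP caller: for alt-allele dosage d the per-read
alt probability is p_d = (d/2)(1-eps) + (1-d/2)eps, the likelihood is
binomial in the (ref, alt) counts with a flat prior over {0, 1, 2}, and
the call is the maximising dosage (ties break toward the heterozygote,
which is symmetric for concordance). Loci below ``min_depth`` total reads
are NO_CALL. For bisulfite data, observations that chemistry could have
manufactured (C→T on the original-top strand, G→A on the bottom) are
discarded before calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd

from .core import (
    COUNT_COLUMNS,
    NO_CALL,
    AlleleCountTable,
    GenotypeMatrix,
    Locus,
    LocusPanel,
    OmicidError,
)

DEFAULT_EPSILON = 0.01
DEFAULT_MIN_DEPTH = 4
DOSAGES = (0, 1, 2)


@dataclass(frozen=True)
class GenotypeLikelihoods:
    """Log-likelihoods over dosages 0/1/2 and the resulting call."""

    log_likelihoods: tuple[float, float, float]
    dosage: int  # 0/1/2 or NO_CALL
    depth: int


def _validate_epsilon(epsilon: float) -> None:
    if not 0 < epsilon < 0.5:
        raise OmicidError(f"epsilon must be in (0, 0.5), got {epsilon}")


def genotype_likelihoods(
    ref_count: int,
    alt_count: int,
    epsilon: float = DEFAULT_EPSILON,
    min_depth: int = DEFAULT_MIN_DEPTH,
    extra_depth: int = 0,
) -> GenotypeLikelihoods:
    """MAP dosage from ref/alt read counts under the binomial error model.

    ``extra_depth`` counts reads of other bases: they gate the depth
    threshold but do not enter the likelihood.
    """
    _validate_epsilon(epsilon)
    if ref_count < 0 or alt_count < 0 or extra_depth < 0:
        raise OmicidError("read counts must be non-negative")
    lls = []
    for d in DOSAGES:
        p = (d / 2.0) * (1 - epsilon) + (1 - d / 2.0) * epsilon
        lls.append(alt_count * math.log(p) + ref_count * math.log(1 - p))
    depth = ref_count + alt_count + extra_depth
    if depth < min_depth:
        return GenotypeLikelihoods(tuple(lls), NO_CALL, depth)
    best = max(lls)
    # ties break toward HET
    dosage = 1 if lls[1] == best else int(np.argmax(lls))
    return GenotypeLikelihoods(tuple(lls), dosage, depth)


def bisulfite_effective_counts(row: pd.Series | dict, locus: Locus) -> tuple[int, int]:
    """Conversion-safe (ref, alt) counts for one strand-resolved row.

    For a C/T polymorphism, a T seen on the original-top strand may be a
    converted unmethylated C, so top-strand T observations are dropped;
    symmetrically, bottom-strand A observations are dropped for G/A
    polymorphisms. All other observations pass through. A locus whose only
    evidence is convertible ends up with zero effective depth.
    """
    ref, alt = locus.ref_allele, locus.alt_allele
    alleles = {ref, alt}
    keep = {c: int(row[c]) for c in COUNT_COLUMNS[:4]}
    if alleles == {"C", "T"}:
        # drop T observations on the original-top strand
        if ref == "T":
            keep["ref_ot"] = 0
        else:
            keep["alt_ot"] = 0
    elif alleles == {"G", "A"}:
        # drop A observations on the original-bottom strand
        if ref == "A":
            keep["ref_ob"] = 0
        else:
            keep["alt_ob"] = 0
    return keep["ref_ot"] + keep["ref_ob"], keep["alt_ot"] + keep["alt_ob"]


def seq_genotype_matrix(
    act: AlleleCountTable,
    panel: LocusPanel,
    epsilon: float = DEFAULT_EPSILON,
    min_depth: int = DEFAULT_MIN_DEPTH,
    sample_ids: list[str] | None = None,
    bisulfite_aware: bool | None = None,
) -> GenotypeMatrix:
    """Force one genotype per (sample, panel locus) from an allele-count table.

    Loci with no row (zero coverage) or sub-threshold depth are NO_CALL.
    Bisulfite filtering applies automatically for wgbs tables and can be
    overridden via ``bisulfite_aware`` (the override exists so the naive
    strand-ignorant caller can be compared on the same counts).
    """
    _validate_epsilon(epsilon)
    if bisulfite_aware is None:
        bisulfite_aware = act.protocol == "wgbs"
    if sample_ids is None:
        sample_ids = sorted(set(act.table["sample_id"]))
    by_id = {l.id: l for l in panel}
    unknown = sorted(set(act.table["locus_id"]) - set(by_id))
    if unknown:
        raise OmicidError(f"allele counts reference loci outside the panel: {unknown[:5]}")
    col_idx = panel.index_of()
    grid = np.full((len(sample_ids), len(panel)), NO_CALL, dtype=np.int8)
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    for row in act.table.itertuples(index=False):
        i = sample_pos.get(row.sample_id)
        if i is None:
            continue
        locus = by_id[row.locus_id]
        rowd = row._asdict()
        if bisulfite_aware:
            ref_n, alt_n = bisulfite_effective_counts(rowd, locus)
            extra = 0  # dropped/other observations do not gate depth in bisulfite mode
        else:
            ref_n = rowd["ref_ot"] + rowd["ref_ob"]
            alt_n = rowd["alt_ot"] + rowd["alt_ob"]
            extra = rowd["other"]
        gl = genotype_likelihoods(ref_n, alt_n, epsilon, min_depth, extra_depth=extra)
        grid[i, col_idx[locus.id]] = gl.dosage
    modality = act.protocol
    return GenotypeMatrix(list(sample_ids), panel, grid, modality)
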