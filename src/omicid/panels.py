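"""Selection of RNA-seq-informative comparison loci.

The array SNP probes sit almost entirely outside protein-coding regions,
so the WGS-vs-RNA-seq comparison needs its own panel: exonic loci that are
variant in enough WGS samples to be discriminative, restricted to genes
expressed highly enough for RNA-seq reads to cover them. Selection is the
intersection of two independent filters and is order-invariant.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core import GenotypeMatrix, LocusPanel, OmicidError

logger = logging.getLogger(__name__)

DEFAULT_MIN_SAMPLES = 4
DEFAULT_TOP_K = 100


def aggregate_expression(expression: pd.DataFrame) -> pd.Series:
    """Mean expression per gene across samples (gene_id-indexed)."""
    if "gene_id" not in expression.columns:
        raise OmicidError("expression table needs a gene_id column")
    values = expression.set_index("gene_id")
    return values.mean(axis=1, numeric_only=True)


def top_expressed_genes(expression: pd.DataFrame, top_k: int = DEFAULT_TOP_K) -> list[str]:
    """Gene ids ranked by mean expression, ties broken by gene id."""
    if top_k < 1:
        raise OmicidError("top_k must be >= 1")
    agg = aggregate_expression(expression)
    ranked = agg.sort_values(ascending=False, kind="mergesort")
    # stable sort on descending value; break exact ties lexicographically
    frame = ranked.reset_index()
    frame.columns = ["gene_id", "value"]
    frame = frame.sort_values(["value", "gene_id"], ascending=[False, True], kind="mergesort")
    return frame["gene_id"].head(top_k).tolist()


def assign_loci_to_genes(panel: LocusPanel, gene_intervals: pd.DataFrame) -> dict[str, str]:
    """Map each locus to the first containing gene interval in sorted order.

    Intervals are 1-based inclusive (columns gene_id, chrom, start, end).
    Loci contained in no interval are excluded (logged); overlapping
    intervals are resolved by (chrom, start, end, gene_id) order (logged).
    """
    intervals = gene_intervals.sort_values(
        ["chrom", "start", "end", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    mapping: dict[str, str] = {}
    for locus in panel:
        sub = intervals[
            (intervals["chrom"] == locus.chrom)
            & (intervals["start"] <= locus.pos)
            & (locus.pos <= intervals["end"])
        ]
        if sub.empty:
            logger.info("locus %s maps to no gene interval; excluded", locus.id)
            continue
        if len(sub) > 1:
            logger.info(
                "locus %s contained in %d intervals; assigned to %s",
                locus.id,
                len(sub),
                sub.iloc[0]["gene_id"],
            )
        mapping[locus.id] = sub.iloc[0]["gene_id"]
    return mapping


def variant_sample_counts(wgs: GenotypeMatrix, presence_mode: str = "variant") -> pd.Series:
    """Per-locus count of WGS samples where the locus is 'present'.

    ``variant``: non-reference genotype called (dosage >= 1).
    ``covered``: any genotype called (dosage >= 0).
    """
    if presence_mode == "variant":
        counts = (wgs.dosages >= 1).sum(axis=0)
    elif presence_mode == "covered":
        counts = (wgs.dosages >= 0).sum(axis=0)
    else:
        raise OmicidError(f"unknown presence mode {presence_mode!r}")
    return pd.Series(counts, index=wgs.panel.ids)


def select_rnaseq_loci(
    wgs: GenotypeMatrix,
    expression: pd.DataFrame,
    gene_intervals: pd.DataFrame,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    top_k: int = DEFAULT_TOP_K,
    presence_mode: str = "variant",
    name: str = "rnaseq_panel",
) -> LocusPanel:
    """Build the WGS-vs-RNA-seq comparison panel.

    Keeps a candidate locus iff (a) it is present (non-reference by
    default) in at least ``min_samples`` WGS samples and (b) it lies inside
    one of the ``top_k`` most expressed genes. Output is ordered by
    (chrom, pos) and deterministic.
    """
    if min_samples < 1:
        raise OmicidError("min_samples must be >= 1")
    presence = variant_sample_counts(wgs, presence_mode)
    top_genes = set(top_expressed_genes(expression, top_k))
    locus_gene = assign_loci_to_genes(wgs.panel, gene_intervals)
    kept = [
        locus
        for locus in wgs.panel
        if presence[locus.id] >= min_samples and locus_gene.get(locus.id) in top_genes
    ]
    kept.sort(key=lambda l: (l.chrom, l.pos))
    return LocusPanel(name, kept)
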