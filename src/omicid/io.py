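"""Readers and writers for the pipeline's interchange formats.

Everything is plain text: tab-delimited tables with a header row and the
literal ``NA`` for missing cells, minimal GT-only VCF 4.2 for genotypes,
and BED for gene intervals (converted to 1-based inclusive coordinates on
read). Every reader/writer pair is a lossless round trip on valid input,
and writers are deterministic byte for byte.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    NA_TOKEN,
    NO_CALL,
    AlleleCountTable,
    BetaMatrix,
    COUNT_COLUMNS,
    GenotypeMatrix,
    Locus,
    LocusPanel,
    OmicidError,
    SnpProbe,
)

MANIFEST_COLUMNS = ["probe_id", "id", "chrom", "pos", "ref", "alt", "high_beta_allele"]


# ---------------------------------------------------------------------------
# SNP-probe manifest


def load_manifest(path: str) -> tuple[list[SnpProbe], LocusPanel]:
    """Load a SNP-probe manifest TSV, preserving file order.

    Returns the probes and the locus panel they imply. Allele letters and
    duplicate probe ids are validated with the offending line number in the
    error message (header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise OmicidError(f"manifest {path}: missing columns {missing}")
    probes: list[SnpProbe] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        if row.probe_id in seen:
            raise OmicidError(f"manifest line {line}: duplicate probe_id {row.probe_id}")
        seen.add(row.probe_id)
        try:
            locus = Locus(row.id, str(row.chrom), int(row.pos), row.ref, row.alt)
            probes.append(SnpProbe(row.probe_id, locus, row.high_beta_allele))
        except (OmicidError, TypeError) as exc:
            raise OmicidError(f"manifest line {line}: {exc}") from exc
    panel = LocusPanel(os.path.basename(path), [p.locus for p in probes])
    return probes, panel


def write_manifest(probes: Sequence[SnpProbe], path: str) -> None:
    rows = [
        {
            "probe_id": p.probe_id,
            "id": p.locus.id,
            "chrom": p.locus.chrom,
            "pos": p.locus.pos,
            "ref": p.locus.ref_allele,
            "alt": p.locus.alt_allele,
            "high_beta_allele": p.high_beta_allele,
        }
        for p in probes
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Panel TSV (loci without probe annotation)

PANEL_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


def write_panel(panel: LocusPanel, path: str) -> None:
    rows = [
        {"id": l.id, "chrom": l.chrom, "pos": l.pos, "ref": l.ref_allele, "alt": l.alt_allele}
        for l in panel
    ]
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_panel(path: str, name: str | None = None) -> LocusPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise OmicidError(f"panel {path}: missing columns {missing}")
    loci = [
        Locus(r.id, str(r.chrom), int(r.pos), r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]
    return LocusPanel(name or os.path.basename(path), loci)


# ---------------------------------------------------------------------------
# Minimal GT-only VCF


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (0, f"{int(c):09d}") if c.isdigit() else (1, c)


def write_genotype_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF 4.2 with GT-only FORMAT, in panel order.

    Byte output is deterministic for a given matrix.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", NO_CALL: "./."}
    chroms = sorted({l.chrom for l in gm.panel}, key=_chrom_sort_key)
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    lines += [f"##contig=<ID={c}>" for c in chroms]
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += gm.sample_ids
    lines.append("\t".join(header))
    for j, locus in enumerate(gm.panel):
        fields = [
            locus.chrom,
            str(locus.pos),
            locus.id,
            locus.ref_allele,
            locus.alt_allele,
            ".",
            ".",
            ".",
            "GT",
        ]
        fields += [gt_map[int(d)] for d in gm.dosages[:, j]]
        lines.append("\t".join(fields))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_genotype_vcf(path: str, modality: str = "wgs", panel_name: str | None = None) -> GenotypeMatrix:
    """Read GT calls from a biallelic VCF into a genotype matrix.

    Multiallelic records and records without a GT field are rejected.
    Loci are keyed by (chrom, pos) in file order.
    """
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    loci: list[Locus] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise OmicidError(
                f"{path}: multiallelic record at {var.CHROM}:{var.POS} not supported"
            )
        if "GT" not in (var.FORMAT or []):
            raise OmicidError(f"{path}: record at {var.CHROM}:{var.POS} has no GT field")
        rid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(Locus(rid, var.CHROM, var.POS, var.REF, var.ALT[0]))
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dosage = np.array(
            [{0: 0, 1: 1, 2: NO_CALL, 3: 2}[int(t)] for t in var.gt_types], dtype=np.int8
        )
        rows.append(dosage)
    vcf.close()
    panel = LocusPanel(panel_name or os.path.basename(path), loci)
    grid = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids, panel, grid, modality)


# ---------------------------------------------------------------------------
# Beta / detection-p / bead-count matrices


def _read_grid(path: str, probe_ids: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    unknown = [i for i in df.index if i not in set(probe_ids)]
    if unknown:
        raise OmicidError(f"{name} {path}: unknown probe ids {unknown[:5]}")
    if list(df.index) != probe_ids:
        df = df.reindex(probe_ids)
    return df


def read_beta_matrix(
    path_beta: str, path_detp: str, path_beads: str, probes: Sequence[SnpProbe]
) -> BetaMatrix:
    """Assemble a BetaMatrix from three aligned TSV grids (rows = probes).

    The three grids must agree in shape and column order; unknown probe
    ids are rejected; ``NA`` cells become missing values.
    """
    probe_ids = [p.probe_id for p in probes]
    beta = _read_grid(path_beta, probe_ids, "beta matrix")
    detp = _read_grid(path_detp, probe_ids, "detection-p matrix")
    beads = _read_grid(path_beads, probe_ids, "bead-count matrix")
    for name, df in (("detection-p", detp), ("bead-count", beads)):
        if df.shape != beta.shape or list(df.columns) != list(beta.columns):
            raise OmicidError(f"{name} matrix shape/columns do not match beta matrix")
    return BetaMatrix(list(probes), beta, detp, beads)


def _write_grid(df: pd.DataFrame, path: str, float_format: str | None) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=float_format, index_label="probe_id")


def write_beta_matrix(
    bm: BetaMatrix, path_beta: str, path_detp: str, path_beads: str
) -> None:
    """Write the three grids; beta/detection-p at 6 decimals, beads as ints."""
    _write_grid(bm.beta.round(6), path_beta, "%.6f")
    _write_grid(bm.detection_p.round(6), path_detp, "%.6f")
    _write_grid(bm.bead_count, path_beads, "%.0f")


# ---------------------------------------------------------------------------
# Allele-count tables


def write_allele_counts(act: AlleleCountTable, path: str) -> None:
    act.table.to_csv(path, sep="\t", index=False)


def read_allele_counts(
    path: str, protocol: str, panel: LocusPanel | None = None
) -> AlleleCountTable:
    """Read a per-(sample, locus) count TSV; absent rows mean zero coverage."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    act = AlleleCountTable(protocol, df)
    if panel is not None:
        known = set(panel.ids)
        unknown = sorted(set(act.table["locus_id"]) - known)
        if unknown:
            raise OmicidError(f"allele counts {path}: unknown locus ids {unknown[:5]}")
    return act


# ---------------------------------------------------------------------------
# Gene intervals (BED) and expression tables


def read_gene_bed(path: str) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) into 1-based inclusive.

    Returns a frame with columns gene_id, chrom, start, end.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise OmicidError(f"gene BED {path}: need at least 4 columns (chrom start end name)")
    out = pd.DataFrame(
        {
            "gene_id": df.iloc[:, 3],
            "chrom": df.iloc[:, 0],
            "start": df.iloc[:, 1].astype(int) + 1,
            "end": df.iloc[:, 2].astype(int),
        }
    )
    if (out["end"] < out["start"]).any():
        raise OmicidError(f"gene BED {path}: interval with end < start")
    return out


def write_gene_bed(genes: pd.DataFrame, path: str) -> None:
    """Write gene intervals (1-based inclusive in memory) back to BED."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"].astype(int) - 1,
            "end": genes["end"].astype(int),
            "gene_id": genes["gene_id"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_expression(path: str) -> pd.DataFrame:
    """Read a gene-expression TSV (gene_id plus one column per sample)."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    if "gene_id" not in df.columns or df.shape[1] < 2:
        raise OmicidError(f"expression table {path}: need gene_id plus value columns")
    return df


def write_expression(expr: pd.DataFrame, path: str) -> None:
    expr.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.6f")
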