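"""Shared domain types for multi-omics sample-identity validation.

All genomic coordinates are 1-based inclusive (VCF convention). Diploid
genotypes are stored as alt-allele dosage in {0, 1, 2}; the sentinel
``NO_CALL`` (-1) marks missing calls and is excluded from every
concordance denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

#: Missing-genotype sentinel used throughout dosage arrays.
NO_CALL: int = -1

#: Missing-data token in all TSV files.
NA_TOKEN = "NA"

VALID_MODALITIES = ("wgs", "wgbs", "rnaseq", "array", "truth")
SEQ_PROTOCOLS = ("wgs", "wgbs", "rnaseq")
TISSUES = ("blood", "saliva")


class OmicidError(ValueError):
    """Base class for domain validation errors."""


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP site at which all cross-modality comparisons happen."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise OmicidError(f"locus {self.id}: pos must be >= 1, got {self.pos}")
        for name in ("ref_allele", "alt_allele"):
            allele = getattr(self, name)
            if allele not in BASES:
                raise OmicidError(
                    f"locus {self.id}: {name} must be one of {BASES}, got {allele!r}"
                )
        if self.ref_allele == self.alt_allele:
            raise OmicidError(f"locus {self.id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class LocusPanel:
    """An ordered, duplicate-free collection of loci.

    Order is part of the identity of a panel: genotype matrices index their
    columns by it, and writers emit loci in panel order so output is
    reproducible byte for byte.
    """

    name: str
    loci: tuple[Locus, ...]

    def __init__(self, name: str, loci: Iterable[Locus]) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "loci", tuple(loci))
        seen_ids: set[str] = set()
        seen_pos: set[tuple[str, int]] = set()
        for locus in self.loci:
            if locus.id in seen_ids:
                raise OmicidError(f"panel {name}: duplicate locus id {locus.id}")
            key = (locus.chrom, locus.pos)
            if key in seen_pos:
                raise OmicidError(f"panel {name}: duplicate position {key}")
            seen_ids.add(locus.id)
            seen_pos.add(key)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def ids(self) -> list[str]:
        return [locus.id for locus in self.loci]

    def index_of(self) -> dict[str, int]:
        return {locus.id: i for i, locus in enumerate(self.loci)}

    def subset(self, ids: Sequence[str], name: str | None = None) -> "LocusPanel":
        by_id = {locus.id: locus for locus in self.loci}
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise OmicidError(f"panel {self.name}: unknown locus ids {missing}")
        return LocusPanel(name or self.name, [by_id[i] for i in ids])


def zygosity(dosage: int) -> str:
    """Collapse an alt-allele dosage to HET/HOM (the array-comparable level)."""
    if dosage == 1:
        return "HET"
    if dosage in (0, 2):
        return "HOM"
    raise OmicidError(f"cannot take zygosity of dosage {dosage}")


@dataclass
class GenotypeMatrix:
    """Per-sample, per-locus alt-allele dosage calls for one data modality.

    ``dosages`` is an int8 array of shape (n_samples, n_loci) holding
    0/1/2 or ``NO_CALL``.
    """

    sample_ids: list[str]
    panel: LocusPanel
    dosages: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.modality not in VALID_MODALITIES:
            raise OmicidError(f"unknown modality {self.modality!r}")
        expected = (len(self.sample_ids), len(self.panel))
        if self.dosages.shape != expected:
            raise OmicidError(
                f"genotype grid shape {self.dosages.shape} != samples x loci {expected}"
            )
        valid = np.isin(self.dosages, (NO_CALL, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.dosages[~valid])
            raise OmicidError(f"invalid dosage values {bad.tolist()}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise OmicidError("duplicate sample ids in genotype matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sample_ids)}

    def vector(self, sample_id: str) -> np.ndarray:
        return self.dosages[self.sample_index()[sample_id]]

    def restrict(self, panel: LocusPanel) -> "GenotypeMatrix":
        """Project onto ``panel``; loci absent from self become NO_CALL."""
        idx = self.panel.index_of()
        cols = np.full((self.n_samples, len(panel)), NO_CALL, dtype=np.int8)
        for j, locus in enumerate(panel):
            if locus.id in idx:
                cols[:, j] = self.dosages[:, idx[locus.id]]
        return GenotypeMatrix(list(self.sample_ids), panel, cols, self.modality)


@dataclass(frozen=True)
class SnpProbe:
    """A SNP-targeting array probe tied to a panel locus.

    ``high_beta_allele`` records which allele drives the array signal
    toward 1, so a beta class can be translated into a dosage relative to
    the manifest's ref allele.
    """

    probe_id: str
    locus: Locus
    high_beta_allele: str  # "ref" | "alt"

    def __post_init__(self) -> None:
        if self.high_beta_allele not in ("ref", "alt"):
            raise OmicidError(
                f"probe {self.probe_id}: high_beta_allele must be 'ref' or 'alt'"
            )


@dataclass
class BetaMatrix:
    """SNP-probe array signal with companion QC grids.

    Columns are ``<sample>_<tissue>`` identifiers; rows are probe ids.
    ``beta``, ``detection_p`` and ``bead_count`` are aligned DataFrames;
    NaN marks missing cells.
    """

    probes: list[SnpProbe]
    beta: pd.DataFrame
    detection_p: pd.DataFrame
    bead_count: pd.DataFrame

    def __post_init__(self) -> None:
        probe_ids = [p.probe_id for p in self.probes]
        if len(set(probe_ids)) != len(probe_ids):
            raise OmicidError("duplicate probe ids")
        for name in ("beta", "detection_p", "bead_count"):
            df = getattr(self, name)
            if list(df.index) != probe_ids:
                raise OmicidError(f"{name} rows do not match probe list")
            if list(df.columns) != list(self.beta.columns):
                raise OmicidError(f"{name} columns do not match beta columns")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                raise OmicidError("beta values outside [0, 1]")
        dp = self.detection_p.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(dp, initial=0.0) < 0 or np.nanmax(dp, initial=1.0) > 1:
                raise OmicidError("detection p-values outside [0, 1]")
        bc = self.bead_count.to_numpy(dtype=float)
        if np.nanmin(bc, initial=0.0) < 0:
            raise OmicidError("negative bead counts")

    @property
    def columns(self) -> list[str]:
        return list(self.beta.columns)

    @staticmethod
    def split_column(col: str) -> tuple[str, str]:
        """Split '<sample>_<tissue>' into (sample, tissue)."""
        sample, _, tissue = col.rpartition("_")
        if not sample or tissue not in TISSUES:
            raise OmicidError(f"column {col!r} is not '<sample>_<tissue>'")
        return sample, tissue

    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for col in self.columns:
            seen.setdefault(self.split_column(col)[0])
        return list(seen)


COUNT_COLUMNS = ("ref_ot", "alt_ot", "ref_ob", "alt_ob", "other")


@dataclass
class AlleleCountTable:
    """Strand-resolved read counts per (sample, locus) for one protocol.

    ``ot``/``ob`` are the original top/bottom bisulfite template strands;
    for non-bisulfite protocols all counts may sit in one strand bucket.
    Absent rows mean zero coverage.
    """

    protocol: str
    table: pd.DataFrame  # columns: sample_id, locus_id, ref_ot, alt_ot, ref_ob, alt_ob, other

    def __post_init__(self) -> None:
        if self.protocol not in SEQ_PROTOCOLS:
            raise OmicidError(f"unknown protocol {self.protocol!r}")
        required = ["sample_id", "locus_id", *COUNT_COLUMNS]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise OmicidError(f"allele count table missing columns {missing}")
        counts = self.table[list(COUNT_COLUMNS)].to_numpy()
        if (counts < 0).any():
            raise OmicidError("negative allele counts")
        self.table = self.table[required].reset_index(drop=True)

    def depth(self) -> pd.Series:
        return self.table[list(COUNT_COLUMNS)].sum(axis=1)

    def rows_for(self, sample_id: str) -> pd.DataFrame:
        return self.table[self.table["sample_id"] == sample_id]


@dataclass(frozen=True)
class ConcordanceCell:
    """Shared-locus count, match count and match percentage for one pair.

    ``pct`` is None (undefined) when no locus is called in both samples;
    an undefined cell is never treated as 0 %.
    """

    n_shared: int
    n_match: int

    def __post_init__(self) -> None:
        if self.n_shared < 0 or not (0 <= self.n_match <= max(self.n_shared, 0)):
            raise OmicidError(
                f"invalid concordance cell n_shared={self.n_shared} n_match={self.n_match}"
            )

    @property
    def pct(self) -> float | None:
        if self.n_shared == 0:
            return None
        return 100.0 * self.n_match / self.n_shared


@dataclass
class ConcordanceMatrix:
    """All-pairs concordance between two genotype matrices."""

    row_samples: list[str]
    col_samples: list[str]
    cells: list[list[ConcordanceCell]]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.row_samples) or any(
            len(r) != len(self.col_samples) for r in self.cells
        ):
            raise OmicidError("concordance grid dimensions inconsistent")

    def cell(self, row: str, col: str) -> ConcordanceCell:
        return self.cells[self.row_samples.index(row)][self.col_samples.index(col)]

    def pct_frame(self) -> pd.DataFrame:
        data = [[c.pct for c in row] for row in self.cells]
        return pd.DataFrame(data, index=self.row_samples, columns=self.col_samples, dtype=float)

    def transpose(self) -> "ConcordanceMatrix":
        cells = [
            [self.cells[i][j] for i in range(len(self.row_samples))]
            for j in range(len(self.col_samples))
        ]
        return ConcordanceMatrix(
            list(self.col_samples), list(self.row_samples), cells, self.label
        )
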