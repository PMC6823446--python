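"""Synthetic multi-omics cohort generator with known ground truth.

Emulates the data a small human reference cohort produces across four
modalities — WGS and WGBS read counts, RNA-seq read counts, and SNP-probe
methylation-array beta values — all driven by one set of Hardy–Weinberg
genotypes per individual, so that every downstream identity check can be
validated against truth. Optional label swaps provide negative controls
for swap detection.

Randomness is controlled by a single integer seed; each generation stage
draws from its own substream derived by stable hashing of
``(seed, stage name)``, so adding a stage never perturbs earlier stages.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    BASES,
    COUNT_COLUMNS,
    AlleleCountTable,
    BetaMatrix,
    GenotypeMatrix,
    Locus,
    LocusPanel,
    OmicidError,
    SnpProbe,
    TISSUES,
)

_ALLELE_PAIRS = [(a, b) for a in BASES for b in BASES if a != b]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for one generation stage (stable across runs)."""
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(stage.encode())])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Depth means follow the sequencing design the pipeline targets (30X WGS,
    15X WGBS, expression-scaled RNA-seq); the array SNP probes are maximally
    informative (MAF 0.5) while exonic loci carry population-style MAFs.
    """

    n_individuals: int = 10
    n_array_loci: int = 65
    n_exonic_loci: int = 300
    n_genes: int = 500
    maf_array: float = 0.5
    maf_exonic_range: tuple[float, float] = (0.05, 0.5)
    depth_wgs: float = 30.0
    depth_wgbs: float = 15.0
    depth_rnaseq: float = 30.0
    base_error: float = 0.01
    conversion_rate: float = 0.995
    methylation_rate: float = 0.75
    beta_centers: tuple[float, float, float] = (0.05, 0.50, 0.95)
    beta_noise_sd: float = 0.04
    detp_fail_rate: float = 5e-4
    bead_mean: float = 14.0
    allelic_imbalance_sd: float = 0.5
    expression_sigma: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf_array <= 0.5:
            raise OmicidError("maf_array must be in (0, 0.5]")
        lo, hi = self.maf_exonic_range
        if not (0 < lo <= hi <= 0.5):
            raise OmicidError("maf_exonic_range must lie in (0, 0.5]")
        for name in ("depth_wgs", "depth_wgbs", "depth_rnaseq", "bead_mean"):
            if getattr(self, name) <= 0:
                raise OmicidError(f"{name} must be > 0")
        if not 0 <= self.base_error <= 0.05:
            raise OmicidError("base_error must be in [0, 0.05]")
        if not 0.95 <= self.conversion_rate <= 1:
            raise OmicidError("conversion_rate must be in [0.95, 1]")
        for name in ("methylation_rate", "detp_fail_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise OmicidError(f"{name} must be a probability")
        if not (self.beta_centers[0] < self.beta_centers[1] < self.beta_centers[2]):
            raise OmicidError("beta_centers must be strictly increasing")


@dataclass
class TruthSet:
    """Ground-truth genotypes plus the gene landscape behind RNA-seq depth."""

    config: SimConfig
    sample_ids: list[str]
    array_probes: list[SnpProbe]
    array_panel: LocusPanel
    exonic_panel: LocusPanel
    genotypes: GenotypeMatrix  # modality "truth", over array ∪ exonic panel
    genes: pd.DataFrame  # gene_id, chrom, start, end, expression (true level)
    locus_gene: dict[str, str]  # exonic locus id -> gene id
    maf: pd.Series  # per-locus minor-allele frequency used

    def truth_for(self, panel: LocusPanel, modality: str = "truth") -> GenotypeMatrix:
        gm = self.genotypes.restrict(panel)
        gm.modality = modality
        return gm


def _sample_ids(n: int, rng: np.random.Generator) -> list[str]:
    ids: list[str] = []
    seen: set[str] = set()
    while len(ids) < n:
        sid = "uk" + "".join(rng.choice(list("0123456789ABCDEF"), size=6))
        if sid not in seen:
            seen.add(sid)
            ids.append(sid)
    return ids


def simulate_truth(config: SimConfig) -> TruthSet:
    """Draw the cohort: HWE genotypes, gene intervals, expression levels.

    Array loci sit in intergenic space; each exonic locus falls inside
    exactly one gene. Deterministic for a given ``config.seed``.
    """
    if config.n_individuals < 2:
        raise OmicidError("need at least 2 individuals for pairwise matching")
    if config.n_exonic_loci > 0 and config.n_genes < 1:
        raise OmicidError("exonic loci require at least one gene")
    rng = stage_rng(config.seed, "truth")
    sample_ids = _sample_ids(config.n_individuals, rng)

    # Gene landscape: non-overlapping intervals laid out along 22 autosomes.
    gene_len = 20_000
    gap = 30_000
    genes_rows = []
    for g in range(config.n_genes):
        chrom = f"chr{g % 22 + 1}"
        slot = g // 22
        start = 1_000_000 + slot * (gene_len + gap)
        genes_rows.append(
            {
                "gene_id": f"gene{g:04d}",
                "chrom": chrom,
                "start": start,
                "end": start + gene_len - 1,
            }
        )
    genes = pd.DataFrame(genes_rows)
    genes["expression"] = rng.lognormal(mean=1.0, sigma=config.expression_sigma, size=len(genes))

    # Array panel: intergenic loci, one per slot upstream of the gene grid.
    array_loci: list[SnpProbe] = []
    probes: list[SnpProbe] = []
    loci: list[Locus] = []
    for i in range(config.n_array_loci):
        chrom = f"chr{i % 22 + 1}"
        pos = 500_000 + (i // 22) * 1_000 + int(rng.integers(0, 900))
        ref, alt = _ALLELE_PAIRS[int(rng.integers(0, len(_ALLELE_PAIRS)))]
        locus = Locus(f"rs{1000000 + i}", chrom, pos, ref, alt)
        loci.append(locus)
        probes.append(
            SnpProbe(f"snp_{locus.id}", locus, "alt" if rng.random() < 0.5 else "ref")
        )
    array_panel = LocusPanel("array", loci)

    # Exonic panel: each locus inside one gene, unique positions.
    exonic_loci: list[Locus] = []
    locus_gene: dict[str, str] = {}
    used: set[tuple[str, int]] = set()
    gene_order = rng.integers(0, config.n_genes, size=max(config.n_exonic_loci, 1))
    for i in range(config.n_exonic_loci):
        gene = genes.iloc[int(gene_order[i])]
        while True:
            pos = int(rng.integers(gene["start"], gene["end"] + 1))
            if (gene["chrom"], pos) not in used:
                break
        used.add((gene["chrom"], pos))
        ref, alt = _ALLELE_PAIRS[int(rng.integers(0, len(_ALLELE_PAIRS)))]
        locus = Locus(f"rs{2000000 + i}", gene["chrom"], pos, ref, alt)
        exonic_loci.append(locus)
        locus_gene[locus.id] = gene["gene_id"]
    exonic_panel = LocusPanel("exonic", exonic_loci)

    # Genotypes under HWE: dosage ~ Binomial(2, maf) with alt as minor allele.
    maf_values = np.concatenate(
        [
            np.full(config.n_array_loci, config.maf_array),
            rng.uniform(*config.maf_exonic_range, size=config.n_exonic_loci),
        ]
    )
    combined = LocusPanel("truth", list(array_panel) + list(exonic_panel))
    dosages = rng.binomial(2, maf_values[None, :], size=(config.n_individuals, len(combined)))
    genotypes = GenotypeMatrix(sample_ids, combined, dosages.astype(np.int8), "truth")
    maf = pd.Series(maf_values, index=combined.ids)
    return TruthSet(
        config, sample_ids, probes, array_panel, exonic_panel, genotypes, genes, locus_gene, maf
    )


# ---------------------------------------------------------------------------
# Methylation array


def _beta_class_index(dosage: np.ndarray, high_is_alt: np.ndarray) -> np.ndarray:
    """Index into beta_centers: 0=low, 1=mid, 2=high, per probe orientation."""
    return np.where(high_is_alt[None, :], dosage, 2 - dosage)


def simulate_array(truth: TruthSet, config: SimConfig | None = None) -> BetaMatrix:
    """Simulate SNP-probe beta values for blood and saliva per individual.

    Beta values form three peaks (homozygote low / heterozygote / homozygote
    high) with truncated-Gaussian noise inside [0, 1]; both tissues share the
    individual's genotype. Detection p-values and bead counts follow the
    configured failure rate and bead mean.
    """
    config = config or truth.config
    rng = stage_rng(config.seed, "array")
    dosage = truth.truth_for(truth.array_panel).dosages  # individuals x probes
    high_is_alt = np.array([p.high_beta_allele == "alt" for p in truth.array_probes])
    centers = np.asarray(config.beta_centers)
    class_idx = _beta_class_index(dosage, high_is_alt)

    columns = [f"{sid}_{tissue}" for sid in truth.sample_ids for tissue in TISSUES]
    n_probes = len(truth.array_probes)
    beta = np.empty((n_probes, len(columns)))
    for k, col in enumerate(columns):
        ind = k // len(TISSUES)
        mu = centers[class_idx[ind]]
        if config.beta_noise_sd == 0:
            vals = mu.astype(float).copy()
        else:
            vals = rng.normal(mu, config.beta_noise_sd)
            bad = (vals < 0) | (vals > 1)
            while bad.any():  # truncation by rejection
                vals[bad] = rng.normal(mu[bad], config.beta_noise_sd)
                bad = (vals < 0) | (vals > 1)
        beta[:, k] = vals

    detp = rng.uniform(0.0, 0.01, size=beta.shape)
    failed = rng.random(beta.shape) < config.detp_fail_rate
    detp[failed] = rng.uniform(0.01, 1.0, size=int(failed.sum()))
    beads = rng.poisson(config.bead_mean, size=beta.shape).astype(float)

    probe_ids = [p.probe_id for p in truth.array_probes]
    return BetaMatrix(
        list(truth.array_probes),
        pd.DataFrame(np.round(beta, 6), index=probe_ids, columns=columns),
        pd.DataFrame(np.round(detp, 6), index=probe_ids, columns=columns),
        pd.DataFrame(beads, index=probe_ids, columns=columns),
    )


# ---------------------------------------------------------------------------
# Sequencing read counts


def _other_base(base: str, rng: np.random.Generator, size: int) -> np.ndarray:
    choices = [b for b in BASES if b != base]
    return np.array(choices)[rng.integers(0, 3, size=size)]


def _panel_for(truth: TruthSet, protocol: str) -> LocusPanel:
    if protocol == "wgs":
        return truth.genotypes.panel
    if protocol == "wgbs":
        return truth.array_panel
    return truth.exonic_panel


def rnaseq_depth_weights(truth: TruthSet, panel: LocusPanel) -> np.ndarray:
    """Per-locus depth multipliers ∝ gene expression, normalised to mean 1."""
    expr = truth.genes.set_index("gene_id")["expression"]
    w = np.array([expr[truth.locus_gene[l.id]] for l in panel])
    return w / w.mean()


def simulate_counts(
    truth: TruthSet, protocol: str, config: SimConfig | None = None
) -> AlleleCountTable:
    """Simulate strand-resolved allele counts for one sequencing protocol.

    Depth is Poisson around the protocol mean (expression-scaled for
    RNA-seq, which is how dropout at weakly expressed loci arises). Each
    read carries the true allele with probability 1 − base_error, else a
    uniformly chosen other base, and lands on the original-top or -bottom
    strand with probability 1/2. WGBS additionally applies per-read
    methylation and bisulfite conversion: an unmethylated C read on the
    original-top strand converts to T (symmetrically G→A on the bottom),
    the confound the downstream caller must survive. RNA-seq heterozygotes
    get a per-(sample, locus) allelic-imbalance shift on the alt fraction.
    """
    config = config or truth.config
    if protocol not in ("wgs", "wgbs", "rnaseq"):
        raise OmicidError(f"unknown protocol {protocol!r}")
    if protocol == "rnaseq" and not truth.locus_gene:
        raise OmicidError("rnaseq simulation requires the gene table")
    rng = stage_rng(config.seed, f"counts:{protocol}")
    panel = _panel_for(truth, protocol)
    gm = truth.truth_for(panel)
    depth_mean = {"wgs": config.depth_wgs, "wgbs": config.depth_wgbs, "rnaseq": config.depth_rnaseq}[
        protocol
    ]
    weights = rnaseq_depth_weights(truth, panel) if protocol == "rnaseq" else np.ones(len(panel))

    rows = []
    for i, sid in enumerate(truth.sample_ids):
        depths = rng.poisson(depth_mean * weights)
        for j, locus in enumerate(panel):
            n = int(depths[j])
            if n == 0:
                continue
            d = int(gm.dosages[i, j])
            alt_p = d / 2.0
            if protocol == "rnaseq" and d == 1 and config.allelic_imbalance_sd > 0:
                shift = rng.normal(0.0, config.allelic_imbalance_sd)
                alt_p = 1.0 / (1.0 + np.exp(-shift))
            bases = np.where(rng.random(n) < alt_p, locus.alt_allele, locus.ref_allele)
            err = rng.random(n) < config.base_error
            if err.any():
                for k in np.flatnonzero(err):
                    bases[k] = _other_base(bases[k], rng, 1)[0]
            on_top = rng.random(n) < 0.5
            if protocol == "wgbs":
                unmeth = rng.random(n) >= config.methylation_rate
                conv = rng.random(n) < config.conversion_rate
                convert = unmeth & conv
                bases = bases.copy()
                bases[on_top & convert & (bases == "C")] = "T"
                bases[~on_top & convert & (bases == "G")] = "A"
            counts = {
                "ref_ot": int(np.sum(on_top & (bases == locus.ref_allele))),
                "alt_ot": int(np.sum(on_top & (bases == locus.alt_allele))),
                "ref_ob": int(np.sum(~on_top & (bases == locus.ref_allele))),
                "alt_ob": int(np.sum(~on_top & (bases == locus.alt_allele))),
            }
            counts["other"] = n - sum(counts.values())
            rows.append({"sample_id": sid, "locus_id": locus.id, **counts})
    table = pd.DataFrame(rows, columns=["sample_id", "locus_id", *COUNT_COLUMNS])
    return AlleleCountTable(protocol, table)


def observed_expression(truth: TruthSet, config: SimConfig | None = None) -> pd.DataFrame:
    """Per-sample expression summaries: true gene level with mild jitter."""
    config = config or truth.config
    rng = stage_rng(config.seed, "expression")
    base = truth.genes["expression"].to_numpy()
    data = {"gene_id": truth.genes["gene_id"]}
    for sid in truth.sample_ids:
        data[sid] = base * rng.lognormal(0.0, 0.1, size=len(base))
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Label swaps


def _check_permutation(perm: Mapping[str, str], sample_ids: list[str]) -> None:
    if set(perm) != set(sample_ids) or set(perm.values()) != set(sample_ids):
        raise OmicidError("permutation must be a bijection over the sample ids")


def inject_swap(dataset, permutation: Mapping[str, str]):
    """Relabel observation data: sample s's data is re-issued under label
    permutation[s]. Truth labels are untouched — the swap is the test oracle.
    Accepts a GenotypeMatrix, BetaMatrix or AlleleCountTable.
    """
    if isinstance(dataset, GenotypeMatrix):
        _check_permutation(permutation, dataset.sample_ids)
        new_ids = [permutation[s] for s in dataset.sample_ids]
        return GenotypeMatrix(new_ids, dataset.panel, dataset.dosages.copy(), dataset.modality)
    if isinstance(dataset, AlleleCountTable):
        _check_permutation(permutation, sorted(set(dataset.table["sample_id"])))
        table = dataset.table.copy()
        table["sample_id"] = table["sample_id"].map(permutation)
        return AlleleCountTable(dataset.protocol, table)
    if isinstance(dataset, BetaMatrix):
        _check_permutation(permutation, dataset.individuals())

        def rename(col: str) -> str:
            sample, tissue = BetaMatrix.split_column(col)
            return f"{permutation[sample]}_{tissue}"

        return BetaMatrix(
            list(dataset.probes),
            dataset.beta.rename(columns=rename),
            dataset.detection_p.rename(columns=rename),
            dataset.bead_count.rename(columns=rename),
        )
    raise OmicidError(f"cannot relabel object of type {type(dataset).__name__}")


def transposition(sample_ids: list[str], a: str, b: str) -> dict[str, str]:
    """Permutation swapping two samples and fixing the rest."""
    perm = {s: s for s in sample_ids}
    perm[a], perm[b] = b, a
    return perm
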