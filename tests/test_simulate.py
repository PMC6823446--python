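"""Synthetic cohort generator: HWE recovery, zero-noise limits, determinism,
the bisulfite conversion confound, and label swaps."""

import numpy as np
import pytest
from scipy import stats

from omicid import (
    NO_CALL,
    OmicidError,
    SimConfig,
    inject_swap,
    simulate_array,
    simulate_counts,
    simulate_truth,
    transposition,
)
from omicid.simulate import stage_rng


def test_truth_requires_two_individuals():
    with pytest.raises(OmicidError, match="at least 2"):
        simulate_truth(SimConfig(n_individuals=1))


def test_hwe_frequencies_at_maf_half():
    """Genotype frequencies at MAF 0.5 match (1/4, 1/2, 1/4) within 3 sigma.

    Oracle: exact binomial CI on each genotype count over n individuals x
    independent loci.
    """
    cfg = SimConfig(seed=11, n_individuals=500, n_array_loci=20, n_exonic_loci=0)
    truth = simulate_truth(cfg)
    d = truth.genotypes.dosages
    n = d.size
    for dosage, p in ((0, 0.25), (1, 0.5), (2, 0.25)):
        count = int((d == dosage).sum())
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(count - n * p) < 3 * sigma


def test_exonic_maf_respected_and_gene_mapping_total():
    truth = simulate_truth(SimConfig(seed=2))
    assert set(truth.locus_gene) == set(truth.exonic_panel.ids)
    gene_ids = set(truth.genes["gene_id"])
    assert all(g in gene_ids for g in truth.locus_gene.values())
    exonic_maf = truth.maf[truth.exonic_panel.ids]
    assert (exonic_maf >= 0.05).all() and (exonic_maf <= 0.5).all()


def test_same_seed_identical_truth_and_observations():
    a = simulate_truth(SimConfig(seed=5))
    b = simulate_truth(SimConfig(seed=5))
    assert a.sample_ids == b.sample_ids
    assert (a.genotypes.dosages == b.genotypes.dosages).all()
    assert a.genes.equals(b.genes)
    ba, bb = simulate_array(a), simulate_array(b)
    assert ba.beta.equals(bb.beta)
    ca, cb = simulate_counts(a, "wgbs"), simulate_counts(b, "wgbs")
    assert ca.table.equals(cb.table)


def test_stage_substreams_are_independent():
    assert stage_rng(1, "truth").integers(0, 2**31) != stage_rng(1, "array").integers(0, 2**31)


def test_zero_noise_beta_sits_exactly_at_centers(tiny_truth):
    cfg = SimConfig(
        seed=tiny_truth.config.seed,
        n_individuals=3,
        n_array_loci=6,
        n_exonic_loci=12,
        n_genes=30,
        beta_noise_sd=0.0,
    )
    truth = simulate_truth(cfg)
    bm = simulate_array(truth, cfg)
    assert set(np.unique(bm.beta.to_numpy())) <= set(cfg.beta_centers)


def test_beta_matrix_has_both_tissues_sharing_genotype(default_truth, default_beta):
    assert sorted(default_beta.individuals()) == sorted(default_truth.sample_ids)
    for sid in default_truth.sample_ids:
        assert f"{sid}_blood" in default_beta.columns
        assert f"{sid}_saliva" in default_beta.columns


def test_dosage_zero_and_no_error_yields_no_alt_reads():
    cfg = SimConfig(seed=3, n_individuals=4, n_array_loci=20, n_exonic_loci=0, base_error=0.0)
    truth = simulate_truth(cfg)
    # force all-reference genotypes by zeroing dosages
    truth.genotypes.dosages[:] = 0
    act = simulate_counts(truth, "wgs", cfg)
    assert len(act.table) > 0
    assert (act.table[["alt_ot", "alt_ob", "other"]].to_numpy() == 0).all()


def test_mean_depth_within_poisson_ci():
    """Observed WGS depth over many loci sits inside a 3-sigma Poisson band."""
    cfg = SimConfig(seed=13, n_individuals=2, n_array_loci=500, n_exonic_loci=0)
    truth = simulate_truth(cfg)
    act = simulate_counts(truth, "wgs", cfg)
    total = act.depth().sum()
    n_cells = 2 * 500
    expected = cfg.depth_wgs * n_cells
    # zero-depth cells are absent rows but contribute 0 to the total anyway
    assert abs(total - expected) < 3 * np.sqrt(expected)


def test_wgbs_full_conversion_makes_top_strand_all_t():
    """With no methylation and complete conversion, every original-top read
    at a C/T locus reports T — the confound the caller must survive."""
    cfg = SimConfig(
        seed=4,
        n_individuals=3,
        n_array_loci=40,
        n_exonic_loci=0,
        methylation_rate=0.0,
        conversion_rate=1.0,
        base_error=0.0,
    )
    truth = simulate_truth(cfg)
    act = simulate_counts(truth, "wgbs", cfg)
    by_id = {l.id: l for l in truth.array_panel}
    ct_rows = 0
    for row in act.table.itertuples(index=False):
        locus = by_id[row.locus_id]
        if {locus.ref_allele, locus.alt_allele} == {"C", "T"}:
            ct_rows += 1
            c_col = "ref_ot" if locus.ref_allele == "C" else "alt_ot"
            assert getattr(row, c_col) == 0  # no C survives on the top strand
    assert ct_rows > 0


def test_rnaseq_requires_gene_table():
    cfg = SimConfig(seed=6, n_individuals=2, n_array_loci=4, n_exonic_loci=0)
    truth = simulate_truth(cfg)
    truth.locus_gene = {}
    with pytest.raises(OmicidError, match="gene table"):
        simulate_counts(truth, "rnaseq", cfg)


def test_rnaseq_depth_tracks_expression(default_truth):
    act = simulate_counts(default_truth, "rnaseq")
    expr = default_truth.genes.set_index("gene_id")["expression"]
    depth = act.table.assign(depth=act.depth())
    per_locus = depth.groupby("locus_id")["depth"].sum()
    locus_expr = np.array([expr[default_truth.locus_gene[l]] for l in per_locus.index])
    r = stats.spearmanr(per_locus.to_numpy(), locus_expr).statistic
    assert r > 0.8


def test_inject_swap_identity_is_noop(default_truth, default_wgs_counts):
    perm = {s: s for s in default_truth.sample_ids}
    swapped = inject_swap(default_wgs_counts, perm)
    assert swapped.table.equals(default_wgs_counts.table)


def test_inject_swap_transposition_moves_counts(default_truth, default_wgs_counts):
    s1, s2 = default_truth.sample_ids[:2]
    perm = transposition(default_truth.sample_ids, s1, s2)
    swapped = inject_swap(default_wgs_counts, perm)
    orig_s1 = default_wgs_counts.rows_for(s1).drop(columns="sample_id").reset_index(drop=True)
    now_s2 = swapped.rows_for(s2).drop(columns="sample_id").reset_index(drop=True)
    assert orig_s1.equals(now_s2)


def test_inject_swap_rejects_non_bijection(default_truth, default_wgs_counts):
    perm = {s: default_truth.sample_ids[0] for s in default_truth.sample_ids}
    with pytest.raises(OmicidError, match="bijection"):
        inject_swap(default_wgs_counts, perm)


def test_config_validation():
    with pytest.raises(OmicidError):
        SimConfig(maf_array=0.6)
    with pytest.raises(OmicidError):
        SimConfig(beta_centers=(0.5, 0.5, 0.9))
    with pytest.raises(OmicidError):
        SimConfig(conversion_rate=0.5)
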