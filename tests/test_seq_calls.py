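"""Binomial MAP caller: brute-force agreement, symmetry, depth gating,
bisulfite filtering, and parameter recovery on simulated counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from omicid import (
    NO_CALL,
    Locus,
    OmicidError,
    SimConfig,
    bisulfite_effective_counts,
    genotype_likelihoods,
    seq_genotype_matrix,
    simulate_counts,
    simulate_truth,
)


def _oracle_map(ref: int, alt: int, eps: float) -> int:
    """Independent oracle: scipy binomial pmf argmax, HET on ties."""
    n = ref + alt
    probs = [eps, 0.5, 1 - eps]
    lls = [stats.binom.logpmf(alt, n, p) for p in probs]
    best = max(lls)
    return 1 if np.isclose(lls[1], best) else int(np.argmax(lls))


def test_all_ref_reads_call_dosage_zero():
    assert genotype_likelihoods(15, 0).dosage == 0


def test_balanced_reads_call_het():
    gl = genotype_likelihoods(7, 8)
    assert gl.dosage == 1
    assert gl.log_likelihoods[1] == max(gl.log_likelihoods)


def test_min_depth_gate():
    assert genotype_likelihoods(1, 2, min_depth=4).dosage == NO_CALL
    assert genotype_likelihoods(1, 2, min_depth=3).dosage == 1


def test_other_bases_gate_depth_but_not_likelihood():
    gl = genotype_likelihoods(1, 2, min_depth=4, extra_depth=1)
    assert gl.dosage == 1
    assert gl.depth == 4


def test_epsilon_validation():
    with pytest.raises(OmicidError):
        genotype_likelihoods(1, 1, epsilon=0.0)
    with pytest.raises(OmicidError):
        genotype_likelihoods(1, 1, epsilon=0.5)


@pytest.mark.parametrize("eps", [0.001, 0.01, 0.05])
def test_map_call_matches_brute_force_all_depths_to_50(eps):
    """Exhaustive oracle over every (ref, alt) pair with depth <= 50."""
    for n in range(1, 51):
        for alt in range(n + 1):
            got = genotype_likelihoods(n - alt, alt, epsilon=eps, min_depth=1).dosage
            assert got == _oracle_map(n - alt, alt, eps), (n - alt, alt, eps)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 100), st.integers(0, 100))
def test_ref_alt_symmetry(ref, alt):
    """Swapping ref and alt counts maps dosage d to 2 - d."""
    a = genotype_likelihoods(ref, alt, min_depth=1).dosage
    b = genotype_likelihoods(alt, ref, min_depth=1).dosage
    if a != NO_CALL:
        assert b == 2 - a


@pytest.mark.parametrize(
    "ref,alt,strand_counts,expected",
    [
        # C/T SNP with counts only on the original-top strand: T dropped
        ("C", "T", dict(ref_ot=6, alt_ot=4, ref_ob=0, alt_ob=0), (6, 0)),
        # same SNP, bottom strand untouched
        ("C", "T", dict(ref_ot=6, alt_ot=4, ref_ob=5, alt_ob=5), (11, 5)),
        # orientation flipped: ref=T means the *ref* top-strand counts drop
        ("T", "C", dict(ref_ot=4, alt_ot=6, ref_ob=5, alt_ob=5), (5, 11)),
        # G/A SNP: A observations on the original-bottom strand drop
        ("G", "A", dict(ref_ot=5, alt_ot=5, ref_ob=6, alt_ob=4), (11, 5)),
        # A/T SNP has no convertible allele: counts pass through
        ("A", "T", dict(ref_ot=3, alt_ot=2, ref_ob=4, alt_ob=1), (7, 3)),
    ],
)
def test_bisulfite_effective_counts(ref, alt, strand_counts, expected):
    locus = Locus("rs1", "chr1", 100, ref, alt)
    row = {**strand_counts, "other": 0}
    assert bisulfite_effective_counts(row, locus) == expected


def test_sample_with_zero_rows_is_all_no_call(default_truth, default_wgs_counts):
    act = default_wgs_counts
    ghost = "ukGHOST1"
    gm = seq_genotype_matrix(
        act, default_truth.genotypes.panel, sample_ids=default_truth.sample_ids + [ghost]
    )
    assert (gm.vector(ghost) == NO_CALL).all()


def test_wgs_caller_recovers_truth(default_truth, default_wgs_counts):
    """30X WGS counts at eps=0.01 recover >= 99.5% of called genotypes."""
    gm = seq_genotype_matrix(default_wgs_counts, default_truth.genotypes.panel,
                             sample_ids=default_truth.sample_ids)
    truth = default_truth.genotypes
    called = gm.dosages != NO_CALL
    assert called.mean() > 0.95
    assert (gm.dosages[called] == truth.dosages[called]).mean() >= 0.995


def test_zero_coverage_loci_no_call(default_truth):
    """RNA-seq: loci in weakly expressed genes drop out via the depth gate."""
    act = simulate_counts(default_truth, "rnaseq")
    gm = seq_genotype_matrix(act, default_truth.exonic_panel,
                             sample_ids=default_truth.sample_ids)
    covered = set(zip(act.table["sample_id"], act.table["locus_id"]))
    col = default_truth.exonic_panel.index_of()
    for i, sid in enumerate(default_truth.sample_ids):
        for locus in default_truth.exonic_panel:
            if (sid, locus.id) not in covered:
                assert gm.dosages[i, col[locus.id]] == NO_CALL
    assert (gm.dosages == NO_CALL).any()


def test_recovery_monotone_in_depth_and_error():
    """Accuracy never degrades with more depth, nor improves with more
    sequencing error (Monte-Carlo at fixed seeds)."""

    def accuracy(depth, base_error, seed):
        cfg = SimConfig(seed=seed, n_individuals=6, n_array_loci=60, n_exonic_loci=0,
                        depth_wgs=depth, base_error=base_error)
        truth = simulate_truth(cfg)
        act = simulate_counts(truth, "wgs", cfg)
        gm = seq_genotype_matrix(act, truth.array_panel, sample_ids=truth.sample_ids,
                                 epsilon=max(base_error, 0.001))
        tr = truth.truth_for(truth.array_panel)
        called = gm.dosages != NO_CALL
        return (gm.dosages[called] == tr.dosages[called]).mean()

    acc_by_depth = [np.mean([accuracy(d, 0.01, s) for s in range(3)]) for d in (5, 15, 40)]
    assert acc_by_depth == sorted(acc_by_depth)
    acc_by_err = [np.mean([accuracy(8, e, s) for s in range(3)]) for e in (0.0, 0.05)]
    assert acc_by_err[0] >= acc_by_err[1]


def test_bisulfite_aware_beats_naive_on_same_draws(default_truth):
    """At 15X, the conversion-aware caller recovers confounded C/T and G/A
    loci better than a strand-ignorant caller on identical counts."""
    act = simulate_counts(default_truth, "wgbs")
    truth = default_truth.truth_for(default_truth.array_panel)
    confounded = np.array(
        [
            {l.ref_allele, l.alt_allele} in ({"C", "T"}, {"G", "A"})
            for l in default_truth.array_panel
        ]
    )
    assert confounded.any()

    def acc(aware):
        gm = seq_genotype_matrix(act, default_truth.array_panel,
                                 sample_ids=default_truth.sample_ids,
                                 bisulfite_aware=aware)
        m = (gm.dosages != NO_CALL) & confounded[None, :]
        return (gm.dosages[m] == truth.dosages[m]).mean()

    assert acc(True) > acc(False)


def test_panel_mismatch_rejected(default_truth, default_wgs_counts):
    with pytest.raises(OmicidError, match="outside the panel"):
        seq_genotype_matrix(default_wgs_counts, default_truth.array_panel)
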