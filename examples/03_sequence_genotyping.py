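"""Forced genotype calls from read counts; why WGBS needs strand awareness.

The caller maximises a binomial likelihood over dosages {0, 1, 2}. For
bisulfite data, unmethylated C reads convert to T on the original-top
strand (G to A on the bottom), so a naive caller over-calls the T allele
at C/T SNPs; the aware caller drops the convertible observations first.
"""

import numpy as np

from omicid import (
    NO_CALL,
    SimConfig,
    genotype_likelihoods,
    seq_genotype_matrix,
    simulate_counts,
    simulate_truth,
)

gl = genotype_likelihoods(ref_count=7, alt_count=8, epsilon=0.01)
print(f"ref=7 alt=8 -> dosage {gl.dosage}, log-likelihoods {np.round(gl.log_likelihoods, 2)}")

truth = simulate_truth(SimConfig(seed=1))
tb = truth.truth_for(truth.array_panel)
act = simulate_counts(truth, "wgbs")
confounded = np.array(
    [{l.ref_allele, l.alt_allele} in ({"C", "T"}, {"G", "A"}) for l in truth.array_panel]
)

for aware in (True, False):
    gm = seq_genotype_matrix(
        act, truth.array_panel, sample_ids=truth.sample_ids, bisulfite_aware=aware
    )
    m = (gm.dosages != NO_CALL) & confounded[None, :]
    acc = (gm.dosages[m] == tb.dosages[m]).mean()
    label = "bisulfite-aware" if aware else "naive (strand-ignorant)"
    print(f"{label}: {100 * acc:.2f}% correct at {int(confounded.sum())} confounded loci")
# the aware caller should be several points more accurate at C/T and G/A sites
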