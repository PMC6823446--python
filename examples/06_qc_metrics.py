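"""QC summary metrics: coverage, read stats, array detection-p/bead counts.

The same summaries a sequencing QC table reports, computed from a
simulated Poisson depth track and the synthetic array matrices.
"""

import numpy as np

from omicid import (
    SimConfig,
    array_qc_summary,
    coverage_summary,
    read_stats,
    simulate_array,
    simulate_truth,
    table_aggregate,
)

rng = np.random.default_rng(1)
depths = rng.poisson(30, 1_000_000)
cs = coverage_summary(depths, threshold=30)
print(
    f"WGS-like track: median {cs.median_depth:.0f}X, "
    f"{100 * cs.fraction_ge_threshold:.1f}% of bases >= 30X"
)

dup, gc = read_stats(80_000, 1_000_000, {"A": 29_500_000, "C": 20_500_000,
                                         "G": 20_500_000, "T": 29_500_000})
print(f"duplication {dup:.1f}%, GC content {gc:.1f}%")

truth = simulate_truth(SimConfig(seed=1))
_, pooled = array_qc_summary(simulate_array(truth))
print(
    f"array QC pooled: {100 * pooled.frac_detp_pass:.2f}% detection p < 0.01, "
    f"{100 * pooled.frac_beads_pass:.2f}% bead counts >= 3, "
    f"mean bead count {pooled.mean_bead_count:.1f}"
)

rin = [8.8, 9.1, 9.2, 8.5, 8.3, 7.9, 8.7, 9.3, 8.6, 7.1]
agg = table_aggregate(rin)
print(f"RIN column: mean {agg.mean} (range {agg.min}-{agg.max})")
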