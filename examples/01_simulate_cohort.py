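"""Simulate a 10-individual multi-omics cohort with known ground truth.

One set of Hardy-Weinberg genotypes drives four observation layers:
methylation-array beta values (blood + saliva), 30X WGS counts, 15X WGBS
counts with bisulfite conversion, and expression-scaled RNA-seq counts.
"""

from omicid import SimConfig, simulate_array, simulate_counts, simulate_truth

config = SimConfig(seed=1)
truth = simulate_truth(config)

print(f"individuals: {truth.sample_ids}")
print(f"array panel: {len(truth.array_panel)} SNP probes (MAF {config.maf_array})")
print(f"exonic panel: {len(truth.exonic_panel)} loci in {config.n_genes} genes")

beta = simulate_array(truth)
print(f"beta matrix: {beta.beta.shape[0]} probes x {len(beta.columns)} sample/tissue columns")

for protocol in ("wgs", "wgbs", "rnaseq"):
    act = simulate_counts(truth, protocol)
    print(
        f"{protocol}: {len(act.table)} covered (sample, locus) cells, "
        f"mean depth {act.depth().mean():.1f}X"
    )

# WGS depth should sit near 30X and WGBS near 15X; RNA-seq mean depth is
# expression-weighted, so many weakly expressed loci are simply absent.
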