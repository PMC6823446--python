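# Methods

## Problem and model

Given datasets from several molecular modalities attributed to the same
individuals, the package tests whether each attribution is correct. The
shared signal is the diploid genotype at fixed biallelic SNP panels,
encoded as alt-allele dosage g ∈ {0, 1, 2} with a NO_CALL sentinel that is
excluded from every denominator.

Two panels are used. The array panel corresponds to the SNP control probes
of the 450k methylation platform (65 by default), which are designed to be
highly polymorphic and therefore maximally discriminative between
individuals. The exonic panel supplies the WGS-vs-RNA-seq comparison,
because RNA-seq only covers expressed sequence.

### Array genotyping

At a SNP-targeting probe the β-value measures allele ratio, not
methylation, and forms three well-separated peaks. Classification uses
fixed cuts: β < 0.25 → LOW, β > 0.75 → HIGH, otherwise MID (cut values are
tunable; boundary values are MID). Fixed cuts were chosen over a fitted
mixture model because the peaks are separated by design — an estimation
step would add failure modes without discriminative benefit. MID is the
heterozygote; LOW/HIGH map to dosage 0/2 through the probe's recorded
high-β allele. When orientation is unavailable or distrusted, the zygosity
comparison mode collapses dosages to {HOM, HET}, which is what an
orientation-free analysis can see; full-dosage mode is the default since
it is strictly more discriminative. Optional QC masking (detection
p ≥ 0.01 or bead count < 3 → NO_CALL) is off by default: the SNP probes'
QC behaviour is the same as any probe's, and masking rarely changes a
65-locus comparison.

### Forced sequencing calls

At each panel locus the caller receives strand-resolved ref/alt/other read
counts and maximises a binomial likelihood over the three dosages, with
per-read alt probability p_d = (d/2)(1−ε) + (1−d/2)ε and flat prior.
Defaults ε = 0.01 and min_depth = 4. Ties break toward the heterozygote
(conservative for concordance: a HET error is symmetric between the two
samples). "Other"-base reads count toward the depth gate but not the
likelihood: they attest coverage while carrying no allele information.
This transparent model replaces a full variant-calling pipeline because
the task is only to force calls at a few hundred known biallelic sites;
its argmax is verified in the tests against independent brute-force
evaluation for every count pair up to depth 50.

### The bisulfite confound

Bisulfite chemistry converts unmethylated C to T on the read's template
strand; in reference coordinates this means top-strand C→T and
bottom-strand G→A. At a C/T SNP a top-strand T observation is therefore
ambiguous (true T allele, or converted unmethylated C) and is discarded;
symmetrically, bottom-strand A observations are discarded at G/A SNPs.
All other observations pass through, including top-strand C reads at C/T
SNPs, which are unambiguous but depleted by conversion — this keeps usable
depth at the cost of a known allele-ratio bias toward the unconvertible
allele; the HET-tie-break and the binomial model absorb most of it. In
bisulfite mode the depth gate counts only the retained ref/alt
observations, since discarded reads carry no usable signal. SNPs where
conversion produces an "other" base (e.g. C/A) pass through unfiltered;
the converted reads fall into the other-base bucket and only slightly
deplete the C depth.

### RNA-seq panel selection

A candidate exonic locus is kept iff (a) it is non-reference in ≥ 4 WGS
samples ("present" is read as variant-present; a coverage-based mode is
available) and (b) its containing gene ranks in the top 100 by expression.
Expression is aggregated as the mean across samples — the natural choice
when no metric is mandated — with exact ties broken lexicographically by
gene id, and gene assignment uses the first containing interval in sorted
order. Both filters are pure set intersections, so selection commutes;
the tests verify this against an independent re-implementation.

### Concordance and verification

For each pair of samples, n_shared counts loci called in both, n_match
counts equal dosage (or equal zygosity in zygosity mode), and
pct = 100·n_match/n_shared; n_shared = 0 yields an undefined cell, never
0 %. Under Hardy–Weinberg, two unrelated individuals match by chance at
Σ_g f_g² per locus — 0.375 at MAF 0.5 — giving wide separation from the
same-individual rate. `verify_identity` confirms a sample iff its expected
partner is the unique row maximum and meets the threshold; ties and
sub-threshold maxima are flagged with the best competitor. Default
thresholds 90 % (DNA modalities vs WGS) and 60 % (RNA-seq vs WGS) bracket
observed same-individual ranges (≈98–100 % and ≈70–83 %) with margin on
both sides of the chance rate. Cohort summaries report both the macro mean
(average of per-sample percentages) and the micro/pooled mean
(Σ matches / Σ shared), plus the pooled value truncated to two decimals,
because a quoted "mean agreement" is ambiguous among these conventions
(548/551 = 99.4556 prints as 99.46 rounded, 99.45 truncated).

## Synthetic cohort generator

The generator emulates a 10-participant multi-omics reference cohort:

- **Genotypes.** Per-locus Hardy–Weinberg draws, dosage ~ Binomial(2, MAF).
  Array loci use MAF 0.5 (SNP control probes are selected for high
  heterozygosity); exonic loci draw MAF ~ Uniform(0.05, 0.5).
- **Array.** β ~ Gaussian around class centers (0.05, 0.50, 0.95),
  truncated to [0, 1] by rejection, sd 0.04. Centers sit inside the unit
  interval because real β never reaches 0 or 1. Blood and saliva columns
  share the individual's genotype. Detection p-values are sub-0.01 except
  for a 5·10⁻⁴ failure rate; bead counts are Poisson with mean 14.
- **Sequencing.** Depth ~ Poisson per (sample, locus): mean 30 for WGS and
  15 for WGBS, matching the sequencing design the pipeline targets; for
  RNA-seq the mean is 30 scaled by the locus's gene expression normalised
  to panel mean 1, so dropout at weakly expressed loci emerges from the
  depth model rather than an explicit dropout parameter. Gene expression
  levels are log-normal (σ = 1.2), which yields roughly 10–15 % zero-depth
  RNA-seq cells at defaults — qualitatively matching the partial locus
  coverage seen in real expressed-SNP comparisons. Each read carries the
  true allele with probability 1−ε (ε = 0.01), else a uniform other base,
  and lands on either strand with probability 1/2. WGBS applies per-read
  methylation (rate 0.75) then conversion (rate 0.995) to produce the
  strand-specific C→T / G→A confound. RNA-seq heterozygotes receive a
  per-(sample, locus) Gaussian log-odds shift (sd 0.5) on the alt
  fraction, emulating allelic imbalance.
- **Swaps.** `inject_swap` relabels observation data under a permutation
  while truth labels stay put, providing an exact oracle for
  swap-detection tests.

Randomness: a single integer seed; every stage draws from
`default_rng([seed, crc32(stage_name)])`, so stages are independent and
adding one never perturbs another. Outputs are deterministic per seed.

What the generator does **not** model: GC/coverage bias, duplicated reads,
mapping ambiguity, index-hopping or cross-contamination (a swap is all or
none), batch effects in β, genotyping-array failure modes beyond the
detection-p/bead mechanism, linkage between loci, or population structure
(individuals are unrelated by construction). Passing tests therefore show
the pipeline's logic is correct under its stated noise model, not that the
thresholds are optimal for any particular real platform.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 10 individuals with 65
array and 300 exonic loci, pooling over ten fixed seeds where a rate is
asserted (genotype recovery, chance concordance, cross-tissue agreement);
swap detection uses ten random transpositions in each of three seeded
cohorts. These sizes put Monte-Carlo error well inside the asserted
bounds (3σ binomial bands are computed from pooled counts) while keeping
the whole suite under a minute. β values are rounded to six decimals on
output; TSV missing cells are the literal `NA`; coordinates are 1-based
inclusive everywhere, with BED converted on read; the lower median is used
for even-length depth tracks. The minimal VCF writer emits GT-only
records deterministically; multiallelic records are out of scope.

## Known limitations

- The bisulfite filter addresses only the conversion-mimics-allele
  ambiguity; it does not model incomplete conversion rates per sample or
  non-CpG methylation contexts.
- The caller assumes independent reads; PCR duplicates would violate this
  (deduplication is assumed upstream).
- Array genotyping presumes the three-peak structure; probes with poor
  separation (e.g. cross-hybridising) would need the QC filter or a
  user-trimmed manifest.
- Real-array use requires a user-supplied SNP-probe manifest with allele
  orientation; the synthetic generator writes one, but no public manifest
  ships with the package.
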