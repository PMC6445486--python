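# Methods

This note documents the statistical model behind `mirtraj`, the defaults and
why they were chosen, the synthetic-data generator's assumptions, and the
numerical choices a maintainer would want written down.

## Study design and contrasts

The analysis assumes a 2 × 2 factorial: genotype ∈ {WT, dKO} × stage ∈
{ESC, RA} with n replicates per cell (n ≥ 2 required; default 3). Two
contrasts drive everything downstream:

- **differentiation**: WT-RA vs WT-ESC — the differentiation response in an
  unperturbed background;
- **genotype**: dKO-RA vs WT-RA — the mutation's effect among
  differentiated cells, where the developmental phenotypes manifest.

Both are configurable (`default_contrasts` is a convenience, not a
constraint). An alternative definition of the differentiation response — the
union of the WT and dKO responses — is supported by running the `diff_dko`
contrast, which the pipeline also computes to report the shared/specific
partition of the two genotypes' differentiation responses.

## Normalization

TMM scaling factors follow the method's published defaults, which are its
de-facto definition: reference sample = the one whose 75th-percentile count
fraction is closest to the mean of those fractions; per gene, M-value
(log₂ ratio of depth-normalized proportions) and A-value (mean log₂
abundance); genes with a zero count in either compared sample excluded;
two-sided trimming of 30% of M-values and 5% of A-values by average ranks;
weights the inverse delta-method variance (N−y)/(Ny) summed over the two
samples; factors rescaled to geometric mean 1. A sample sharing no
co-expressed gene with the reference gets factor 1 with a warning.
Development cross-checks against edgeR 4.0.16 `calcNormFactors` agreed to
< 1e-7 on random matrices; the shipped tests use an independent step-by-step
oracle instead.

TMM is *not* invariant to rescaling a single column (the variance weights
shift non-uniformly; edgeR behaves identically). It is invariant to global
rescaling, and a column that is an exact multiple of another yields unit
factors; those are the depth-invariance properties the tests assert.

log₂ CPM uses a prior expressed in CPM units: value = log₂(CPM + prior),
equivalently a per-sample prior count of `prior × eff_lib / 1e6`. This keeps
the transform exactly invariant to global depth changes and finite at zero
counts; with prior 0 the CPM columns sum to exactly 1e6. Default prior 0.5.

"Standard normalized expression" for correlation analysis is interpreted as
per-feature z-scores of TMM-log-CPM across all 4 × n samples, with the
sample (n−1) SD convention. Constant features are set to zero and flagged.
Both the transform and the sample subset are pluggable; using all samples is
the default because the miRNA–target anti-correlation signal spans both the
differentiation and the genotype factor.

## Differential expression

The test is the classic conditional exact test for negative-binomial counts
with a *fixed* common dispersion φ (variance μ + φμ²; default φ = 0.1 — no
dispersion estimation is attempted, by design). Library sizes are first
equalized by scaling every sample to the geometric mean of the effective
(TMM-corrected) library sizes and rounding half-to-even — a documented
approximation to quantile-adjusted pseudo-counts. Conditional on a feature's
total t, the group-A sum is beta-binomial BB(t, n_A/φ, n_B/φ); the two-sided
p-value doubles the smaller tail, includes the tie mass at the observed
value, and is capped at 1. A feature with zero total gets p = 1, logFC = 0.
The log₂ fold change uses prior-augmented group mean counts (prior 0.5 per
group mean) so it is always finite; the reported average log₂CPM uses the
same prior on the overall mean. p-values agree with edgeR's `exactTest` at
the same dispersion to ~1e-14 on equal-library inputs.

Calling thresholds: raw p < 0.05, |log₂FC| > 0.75, average log₂CPM > 0.
The raw p is thresholded (BH-adjusted values are computed and reported;
`use_fdr=True` switches the criterion) because the calling rule is stated in
terms of the unadjusted p-value.

## Trajectory classes

A feature enters a class only when called in *both* contrasts: up_up =
diff-up ∩ geno-up, and so on; everything else is `unclassified`. The four
classes are mutually exclusive by construction. miRNAs are classified with
the identical operation on the miRNA DE calls. Class trajectory summaries
average z-scores per genotype × stage cell (per-feature cell means, then
mean ± SD across features).

## Gene-set enrichment

One-sided over-representation: p = P(X ≥ overlap) under the hypergeometric
distribution given (universe, set, query) sizes; odds ratio from the 2 × 2
table with a 0.5 continuity correction when any cell is zero. The universe
defaults to features passing the expression filter (average log₂CPM > 0) in
the relevant dataset — enrichment against expressed genes avoids detection
bias — and is configurable to any id list. BH FDR is computed across the
entire query × set table (scope configurable by calling per query).
Regulator-target (ChIP-style) analyses are the same engine applied to a
regulator-target GMT; there is no separate code path.

## miRNA regulator nomination

For every target-map edge with both endpoints expressed and non-constant,
Pearson r across all samples of standardized expression (Spearman ρ computed
and reported alongside, but only Pearson feeds the test). Per miRNA with at
least `min_targets` tested edges (default 5 — the smallest n at which the
exact one-sided signed-rank test can reach 0.05), a one-sample Wilcoxon
signed-rank test of the r values against zero, alternative median < 0: exact
null distribution when n ≤ 25 with no zeros or tied magnitudes, otherwise
normal approximation with continuity and tie corrections (zeros dropped).

Candidates must (a) sit in a down class — down_down ("down_enhanced") or
down_up ("down_counteracted") — i.e. opposite to their up-class targets, and
(b) have shift p < 0.05. No multiplicity correction is applied across miRNAs
by default (the criterion is a raw threshold); BH is available on the
output table. Candidates are ranked by ascending p; ties break by more
negative mean r, then lexicographic id, making the ranking deterministic.
"Anti-correlated targets" are tested targets with r < 0 (no magnitude cut —
consistent with testing the whole correlation distribution; a cut can be
applied downstream) that belong to an up class.

## Synthetic data generator

The generator emulates exactly the structure the analysis assumes, nothing
more: NB counts (gamma-Poisson, variance μ + φμ²) with φ_true = 0.1 matching
the analysis dispersion; log-normal library sizes (mean 1e6 mRNA / 5e5
miRNA, CV 0.2); log-normal baseline abundances (sdlog 1.2 genes / 1.0
miRNAs) so the log₂CPM > 0 filter is non-trivially exercised; planted
differentiation effects on 15% + 15% of features at ±2 log₂ units, genotype
effects on 60% of those (signs split evenly), so the four planted classes
have reproducible sizes. Expected proportions are renormalized within each
sample, so expected column totals equal the drawn library sizes and strong
planted effects create the composition bias TMM exists to correct.

Regulator miRNAs (default 20 of 200) are forced into down_down/down_up
(half each). Functional target edges couple a target's expected count to
−(repression_strength) × its regulator's standardized latent (noise-free)
log₂ abundance — the latent signal is used so the planted anti-correlation
strength is controlled, not diluted by count noise. Functional targets are
drawn from the class matching the regulator's flavor (down_down regulator →
up_up targets; down_up → up_down), mirroring de-repression logic: the
repression term then reinforces the target's own planted class instead of
contradicting it. Decoy edges (default 25% per regulator; all edges of
non-regulator miRNAs) point at genes with no planted effects. Every miRNA
appears in the target map, so the shift test's specificity is genuinely
exercised. At most one functional regulator per gene.

All randomness flows from one `numpy.random.default_rng(seed)` in a fixed
draw order (library sizes, baselines, regulator selection, effect
assignment, target sampling, counts), so identical configs give bit-identical
datasets.

What the generator does **not** emulate: batch effects, isoform structure,
read-level noise, dispersion heterogeneity across genes, correlated
replicates, or miRNA targeting via sequence. Passing recovery tests
therefore show the pipeline is correct and calibrated under its own model
assumptions — not that those assumptions hold for any particular real
dataset.

## Problem sizes and numerical choices

- Null calibration runs use 20 000 genes / 2 000 miRNAs / 20 decoy targets
  each at library size 5e5; recovery runs use the default config (5 000
  genes, 200 miRNAs, 20 regulators, 25 targets, 25% decoys, n = 3). These
  sizes give Monte-Carlo error well inside the asserted bands while keeping
  a full run under a minute on one CPU.
- The conditional exact test enumerates the full split distribution per
  feature in log space (gammaln), normalized by max subtraction; cost is
  linear in the feature's total count.
- Rounding in library equalization is half-to-even; tie mass at the observed
  split is included in both tails before doubling.
- "Null genes" for the false-class rate are features with no planted effect
  in either contrast; features with a single planted effect genuinely
  respond in one contrast and are excluded from that denominator.
- Output tables are written with a fixed `%.10g` float format so repeated
  runs are byte-identical; run metadata contains no timestamps for the same
  reason (the log keeps counts only).

## Known limitations

- No dispersion estimation (qCML/tagwise) or GLM/quasi-likelihood framework;
  the fixed-dispersion exact test is the entire DE model.
- No GSEA-style rank enrichment, GO topology, or de-novo target prediction.
- The exact test's library equalization is an approximation; with grossly
  unequal depths the conditional distribution is only approximately valid
  (the acceptance checks compare against the oracle on equalized counts, and
  null calibration confirms the p < 0.05 rate stays in [0.03, 0.07] at
  CV 0.2 depth variation).
- Class assignment is hard (no soft membership); features near thresholds
  flip classes under resampling.
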