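# Methods

## The hierarchical sampling model

scWGA transfers allelic information from a handful of primary template
molecules into a sequencing library. Amplicons split into two
populations: *independent* amplicons copied directly from the primary
template, and *redundant* amplicons copied from other amplicons. The DIA
is the effective count of the former at a locus.

`diaqc` models one heterozygous locus *i* (alleles A/B, expected A
fraction *p*) as

1. **Amplification**: each of the DIA independent amplicons carries
   allele A with probability *p*, so the A-amplicon count is
   `K_i ~ Binomial(DIA, p)` and the pool allele fraction is
   `P_i = K_i / DIA` with `Var(P_i) = p(1−p)/DIA`.
2. **Sequencing**: reads sample the pool,
   `y_i ~ Binomial(M_i, P_i)` at total depth `M_i`, giving the observed
   VAF `p̂_i = y_i / M_i`.

By the law of total variance,

```
Var(p̂_i) = p(1−p) [ 1/M_i + (1/DIA)(M_i − 1)/M_i ].
```

This is exact for any integer DIA ≥ 1 and M_i ≥ 1, strictly decreasing
in both arguments (for the other > 1), and interpolates between the
sequencing-only binomial floor `p(1−p)/M` (DIA → ∞) and the full
Bernoulli variance `p(1−p)` (DIA = 1, the pseudo-homozygous regime in
which every read descends from a single founding molecule).

## Estimator

Rearranging gives the per-locus standardized moment identity
`E[ M_i (p̂_i − p)² / (p(1−p)) ] = 1 + (M_i − 1)/DIA`. Summing over loci
and solving for DIA:

```
DIA^ = Σ_i (M_i − 1)  /  Σ_i [ M_i (p̂_i − p)² / (p(1−p)) − 1 ]
```

Implementation notes:

* The “− 1” sits **inside** the sum (equivalently, subtract N once);
  this is the only reading consistent with the per-locus moment
  identity, and it makes all-pseudo-homozygous data return exactly
  DIA = 1 for any depth profile.
* The moment identity is exact at every depth, so the estimator is
  essentially unbiased whenever the per-locus terms are averaged over
  enough loci; the ratio form contributes an O(CV²) upward bias that is
  negligible at ≥ 10⁴ loci and a few percent at ~10³ loci.
* **Saturation**: if the denominator is ≤ 0 the observed dispersion does
  not exceed the infinite-DIA floor; we report `inf` with
  `saturated=True` rather than a meaningless negative value.
* **VAF source**: p̂ uses allelic depths (AD ref + alt) rather than the
  DP field, so reads assigned to other alleles or removed by the caller
  do not distort the denominator of p̂. DP and GQ act only as filters.
* Loci with `M_i = 1` are kept (they contribute 0 to the numerator) but
  a warning fires when they exceed 10% of loci; a dataset consisting
  only of such loci is rejected as uninformative.
* Per-locus *p* is supported throughout, enabling CNV-aware estimation
  (e.g. p = 1/3 in an A/B/B triploid segment) from a BED-like segment
  table.

## Uncertainty

Percentile bootstrap over loci: B = 1000 resamples and a 95% interval by
default (no interval type is canonical here; percentile is the simplest
choice consistent with the heavy-tailed ratio statistic). Saturated
resamples are excluded from the percentiles and their count is reported;
an all-saturated bootstrap raises rather than fabricating an interval.
Simulated coverage at the default settings is at or slightly above
nominal (the interval is mildly conservative for the ratio statistic).
Every stochastic routine takes an explicit seed; equal seeds give equal
results.

## Accuracy metric

`accuracy = 1 − |DIA^ − DIA| / DIA`. Experiment summaries report two
forms: `accuracy_of_mean` applies the formula to the mean of the
replicate estimates (the headline form), and `mean_accuracy` averages
per-replicate accuracies (sensitive to replicate dispersion). The first
measures bias only; the second folds in variance and is the one that
degrades visibly at low depth or low locus counts.

## Simulator: what it emulates, and what it does not

`diaqc.simulate` draws loci independently through the two-stage model.
Defaults mirror the baseline study conditions: 100,000 loci, fixed depth
M = 30, p = 0.5, 100 replicates per condition. Perturbations:

* **DIA dispersion** across loci: truncated-normal
  (`dia_avg · X`, `X ~ N(1, cv)` truncated at 0, sampled exactly via
  `scipy.stats.truncnorm`) or uniform (`dia_avg · U(1−δ, 1+δ)`).
  Continuous draws are rounded to the nearest integer with floor 1,
  since binomial sampling needs integer trials. The accuracy ground
  truth for the truncated normal is the closed-form conditional mean
  `dia_avg · [1 + cv·φ(−1/cv)/(1 − Φ(−1/cv))]`; the small additional
  effect of integer rounding on the realized mean is ignored
  (documented approximation, < 1% at dia_avg ≥ 10).
* **Amplification errors**: each amplicon's allele flips with
  probability ε. The default is symmetric (both pools corrupt), under
  which the pool stays binomial with
  `K' ~ Binomial(DIA, p(1−ε) + (1−p)ε)` — at p = 0.5 the VAF variance is
  therefore *exactly* invariant in ε, which is the mechanism behind the
  estimator's error-rate decoupling. An asymmetric mode (only the
  tracked pool corrupts) is available behind `symmetric_errors=False`;
  it shifts the effective p and biases the estimator downward if the
  analyst's p is not adjusted.
* **Depth / locus-count reduction** and **ploidy-driven p** are plain
  parameter sweeps.

Not emulated: read-level artifacts (base-call errors, mapping,
duplicates), GC-dependent amplification efficiency, linkage between
loci, doublets. Passing simulation tests therefore demonstrates the
statistical machinery under the stated generative model, not robustness
to alignment- or chemistry-specific artifacts in real libraries.

`run_accuracy_experiment` simulates all replicates of a condition as one
vectorized block; `simulate_dataset` is the single-dataset path used for
round-trip and VCF tests. Both share the same primitives and seeds make
each deterministic.

## SNV-calling fidelity benchmark

Per-locus genotyping-error probabilities are estimated under the
two-stage model with error injection, using either Monte Carlo draws or
an exact enumeration over `(K', y)` (the binomial collapse above makes
enumeration O(DIA · M) per truth genotype). Homozygous loci have
`K_alt ~ Binomial(DIA, ε)` (reference) or `Binomial(DIA, 1−ε)`
(alternative).

The simulated genotyper is a VAF-threshold caller — VAF < 0.1 → 0/0,
VAF > 0.9 → 1/1, otherwise 0/1, with ≥ 2 alt reads required for any
non-reference call. No specific production caller is imitated; the
thresholds mirror common hard-filter heuristics, are configurable, and
are recorded in every profile. Genome-scale expected counts come from a
deterministic projection onto a site-composition model (3×10⁹ sites,
10⁶ true heterozygous, 10⁶ alternative-homozygous): TP counts any
non-reference call at a true variant site (a genotype-exact mode is a
switch), FN is a variant site called 0/0, FP a reference site called
non-reference, ADO a heterozygous site called homozygous either way;
sensitivity = TP/(TP+FN), precision = TP/(TP+FP). Expected counts equal
the mean of a full stochastic genome realization at a fraction of the
cost; the exact enumeration is also the only way to resolve FP rates of
order 10⁻⁶ per site.

**A non-monotonicity worth knowing about.** TP and sensitivity rise, and
ADO and FN fall, monotonically with DIA. FP does *not* fall monotonically
from DIA = 1: a single erroneous amplicon has pool frequency 1/DIA, so
for DIA between ~2 and ~20 (at M = 30 and t_low = 0.1) its expected VAF
sits squarely in the heterozygous-call window and FP *peaks* near
DIA ≈ 10 before consensus suppression takes over. This is intrinsic to
any threshold caller, not an implementation artifact; the package's
property tests assert FP/precision monotonicity on DIA ≥ 10 where the
consensus mechanism guarantees it.

## VCF workflow

* Bulk-heterozygous definition: bulk GT exactly 0/1 at biallelic SNVs;
  multiallelic and non-SNV records are skipped and counted.
* Filters: GQ ≥ 20 and DP ≥ 10 (inclusive, sample-level fields) in both
  the bulk and the amplified sample; autosomes only (1–22, `chr` prefix
  optional). The evaluated-samples set is a parameter.
* Concordance (TP/FN/FP/TN) uses the 0/0-vs-non-reference rules on the
  filtered records; somatic-mutation calls additionally require the
  non-reference genotype in both the single cell and its parent
  organoid (the biological filter), and SNR = |SM| / FP.
* Partitioning: 0-based half-open bins of 10 Mb by default (VCF
  positions are 1-based); bins with < 1000 informative loci are flagged
  low-confidence — below that, the denominator's sampling noise (and the
  ratio bias) makes single-bin estimates unreliable. Empty bins inside
  the observed range are emitted with a missing estimate.
* Uniformity metrics: Gini on sorted window depths
  (`Σ(2i−n−1)x_i / (n²μ)`) and KL(q‖uniform) with natural log, both
  scale-invariant. Depth-capping down-sampling caps windows at a chosen
  quantile and rescales to a 20× mean, emulating BAM-level manipulation
  on depth vectors; capping can only reduce Gini (majorization) and
  never touches the allele counts the DIA is computed from — the two
  metric families are decoupled by construction.

## Reporting

The HTML report embeds matplotlib-rendered SVG inline (no external
assets), and every number it shows is also written to a JSON sidecar so
downstream tooling never parses HTML. CLI runs log filter thresholds,
seeds and dropped-record counts.

## Problem sizes

Acceptance-scale experiments use the full study conditions (10⁵ loci ×
100 replicates per condition; ~1 minute vectorized). Unit and property
tests use 2×10³–5×10⁴ loci, sized so that Monte-Carlo noise stays well
inside the asserted bounds (3-SE criteria wherever an oracle is
stochastic).

## Known limitations

* The estimator needs ≈ 1000 informative heterozygous sites for a
  reliable estimate; sparse or LOH-heavy regions cannot be subdivided
  finely.
* A single pooled DIA is assumed per region; strong within-bin
  heterogeneity is summarized, not resolved.
* Likelihood-based or Bayesian estimation, and linkage-aware
  aggregation for sparse data, are out of scope.
* Saturated fits (dispersion at the binomial floor) are reported as
  non-identifiable rather than as a large finite DIA; deeply sequenced
  bulk-like libraries routinely saturate.
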