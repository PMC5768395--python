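# Methods

This note documents the models, conventions and defaults implemented in
`ctcfmeth`, in particular every place where a design choice was genuinely
open.

## Synthetic study generator

**Model.** Methylation proportions are bounded in [0, 1], so each site
carries a Beta distribution per tissue class: hypermethylated sites shift
the tumor distribution above normal, hypomethylated sites below, null
sites share one distribution.  Per sample a latent site-level value
`x ~ Beta(class)` is drawn; each CpG unit of the site reports
`expit(λ_u · (logit x − z₀) + z₀ + δ_u + ε)` with `z₀` anchoring the
normal-class mean, a fixed per-unit offset `δ_u ~ N(0, 0.2)` (units of one
fragment sit at systematically different levels), per-measurement noise
`ε ~ N(0, 0.15)` and an optional attenuation `λ_u ≤ 1`.  Entries are
masked missing completely at random.

**Why these defaults.**

| parameter | default | rationale |
|---|---|---|
| cohort | 84 normal; 108/39/101/47 tumors by stage | the emulated study layout |
| sites | 23 = 16 hyper + 7 hypo | the surviving marker set of the screen |
| units per site | 2–5 | typical mass-spec fragment counts per ~30 bp amplicon |
| Beta calibration | analytic AUCs span ~0.85–0.99 | the range strong single-locus markers report |
| missing rate | 0.05 | exercises the QC filters without dominating them |
| pairing fraction | 84/295 | every normal has a matched tumor |
| unit jitter σ | 0.2 (logit) | makes "highest-AUC unit" selection non-trivial |
| unit noise σ | 0.15 (logit) | measurement noise; decorrelates units of one site |

A note on attenuation: `λ_u` shrinks a unit's class signal toward the
normal-class anchor, but because it is a monotone transform it changes the
unit's *ranks* — and hence its AUC — only in combination with measurement
noise.  Fixtures that plant a "strongest unit" therefore raise the unit
noise to σ = 1 so the attenuated units genuinely discriminate less.

**Ground truth.** Per site the generator records the analytic AUC
`P(tumor more tumor-like than normal)` by Gauss quadrature of
`∫ f_tumor(x) F_normal(x) dx` (orientation flipped for hypo sites, so truth
AUC ≥ 0.5).  Tests verify this against brute-force double integration, and
empirical AUCs converge to it within ±0.02 at 2000 samples per class when
jitter and noise are off.

**What the generator does not emulate** — and hence what passing tests do
not show about real tissue data: within-patient correlation across sites,
batch and plate effects, informative (assay-failure-driven) missingness,
bisulfite-conversion error, stage-dependent effect sizes (available via
`stage_shift` but off by default, since published per-stage AUCs are
broadly flat), and any genomic structure in site coordinates.

**Melting-curve observations.** The melt-shift statistic is
`log10(1 + 99·m)` of the latent site-level methylation plus Gaussian noise
— any strictly increasing map works for interval binning; the log form
keeps the 1% standard well separated from 0%.  Standards at ratios
0/0.01/0.10/1.00 are emitted noiselessly.

**Cell-line panel.** Six immortal and seven normal lines.  True candidate
sites: occupied in every immortal line only, methylation low where
occupied (Beta(1.5, 15)) and high where not (Beta(15, 1.5)).  Null sites
keep an immortal-specific occupancy pattern over 3–6 lines — with fewer
occupied lines the exact rank-sum test is so discrete that its achieved
size collapses far below α, which would measure the test's discreteness
rather than the screen — and methylation iid Beta(2, 2).

## Reliability QC

Units with data in less than 30% of samples are discarded, then samples
missing more than 30% of the surviving data points.  Both comparisons are
strict, so exact-30% cases survive.  The order (units first, samples on
the reduced matrix) matters and is fixed and logged in the run manifest;
thresholds are configurable.  No imputation anywhere.

## Melting-curve triage

Bins are the intervals between consecutive standards,
left-closed/right-open except the last; observations outside the standard
range clamp to the outer bins.  Each matched pair votes
`sign(tumor bin − normal bin)`; a site passes when the majority direction
carries ≥ 60% of informative pairs.  Tied pairs count in the denominator —
a pair whose members fall in the same bin is evidence against tumor
specificity.  The 0.60 default sits just below the smallest specificity
fraction (64%) the emulated screen reported for its surviving sites; the
exact historical criterion is not public, so the threshold is configurable
and logged.

## ROC statistics

* AUC: Mann–Whitney with ties credited ½, computed on oriented values
  (hyper: high = tumor-like; hypo: low; `auto` picks the orientation with
  AUC ≥ 0.5, ties to hyper).
* Variance: DeLong placement estimator (midrank formulation), cross-checked
  against an independent R implementation; Hanley–McNeil available via
  `p_method="hanley-mcneil"`.  p-value: two-sided z-test of AUC = 0.5.
  With zero variance (complete separation) p is reported as 0.
* Sensitivity at specificity: candidate cutpoints are midpoints between
  adjacent distinct observed values plus guards beyond the range; the
  constraint is specificity ≥ level (conservative clinical convention, not
  "nearest"); ties in sensitivity resolve toward higher specificity.  The
  point estimate comes from the full data.  The CI is the percentile
  interval over stratified bootstrap replicates (classes resampled
  independently, preserving prevalence) with the cutpoint re-derived inside
  each replicate; 1000 replicates and 95% coverage by default.  Percentile
  intervals do not mechanically contain the full-data point estimate, but
  do so in practice at these settings; the acceptance suite verifies
  90–99% empirical coverage of the analytic sensitivity under the Beta
  model, the wide band acknowledging threshold re-estimation bias.
* Reported sensitivities are percent with two decimals at the reporting
  layer only; all computation is on proportions.

## Marker selection

Each site is represented by the CpG unit with the highest oriented AUC
(ties: lexicographically smallest unit id).  Ranking is by AUC descending,
then sensitivity at 95% specificity, then marker id — a total order.
Discovery tests methylation(unoccupied) > methylation(occupied) with a
one-sided exact Mann–Whitney at α = 0.05 per site (Spearman alternative
available); no multiplicity correction by default, matching a screen that
reports a raw candidate count, with Benjamini–Hochberg behind a flag.

## Panel evaluation

Per-marker positivity cutpoints default to each marker's own
95%-specificity threshold derived on the full negative class (the panel's
specificity then lands near, not at, 95%).  Hypo markers count positive at
or below their cutpoint.  A missing marker value is not positive
(conservative toward specificity); a sample missing all k markers has no
defined call and leaves every denominator.  The m = 1..k sweep reports
stage-stratified sensitivity, pooled (count-weighted) total sensitivity
and a single specificity, each with its raw counts; monotonicity in m
holds by set containment and is asserted unconditionally in tests.

## Clustering

Site-level values are transformed `log10(x + 0.005)` — the pseudocount is
half the 1% melting-assay detection floor and keeps zeros finite.
Distances between samples (and between sites, on the transpose) are
Bray–Curtis by default with Euclidean as the alternative; on log-scale
(negative) values Bray–Curtis uses the |u+v| denominator convention.
Missing entries are handled pairwise-complete.  Agglomerative clustering
uses average linkage (UPGMA, verified against a hand-worked 4-point
example); the sample tree is cut at its top merge into two clusters and
the one holding the majority of normals is labelled N-like.

## Problem sizes

The test suite runs the bootstrap-coverage study at 500 replicates of 60
samples per class with 200 bootstrap draws, the discovery null study at
1000 sites, and unit-selection recovery at 100 replicates; the acceptance
script runs the full funnel at the emulated scale (1236 discovery sites,
121 triage candidates, 379 tissue samples, 1000 bootstrap replicates).
These sizes keep the whole suite within a few minutes on one CPU while
leaving the statistical checks well-powered.

## Known limitations

* The triage pass criterion and the discovery association test formalise
  steps whose historical definitions are not public; both are configurable
  and surfaced in the run manifest.
* Bray–Curtis on log-transformed values is unconventional (the transform
  produces negative entries); Euclidean is the safer choice when in doubt
  and both are logged.
* The panel is calibrated and evaluated on the same cohort by default, as
  screening studies typically report; a held-out split is the caller's
  responsibility.
* No paired-marker AUC comparison test, partial AUC, or smooth ROC models.
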