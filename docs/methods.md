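# Methods

This note records the statistical model behind `clinsynth`, the parameters
that matter, what the bundled simulated cohorts do and do not emulate, and
the numerical choices made where the design was genuinely open.

## The synthesis model

The generator treats a feature matrix as a finite mixture over strata of
"similar patients" and, within each stratum, as an empirical distribution
smoothed by a product Gaussian kernel. Sampling is donor-based: a synthetic
row inherits all of its cross-feature dependence from a single real donor
row and then receives independent per-dimension kernel noise. This is a
deliberate variation on classical multivariate KDE sampling; classical KDE
alone neither censors unsupported regions nor handles mixed
continuous/categorical columns, and it smooths away genuine point masses.

Formally, for a stratum G of size m and numeric dimension j with
within-group bandwidth h_j, a synthetic value is

    x*_j = d_j + h_j ε,   ε ~ N(0, 1),

where d is a donor row drawn uniformly with replacement from G, followed by
envelope censoring to [min_G(x_j), max_G(x_j)]. Categorical dimensions copy
the donor's level — marginally identical to a draw from the stratum's
empirical frequency table (no smoothing noise is added to categorical
dimensions), while preserving the joint law with every other dimension.

### Stratification ("groups of similar patients")

Strata are the joint levels of the declared grouping categoricals crossed
with per-feature quantile bins (`n_quantile_bins`, default 4) of declared
continuous grouping anchors. With no grouping features the cohort is a
single stratum. Any stratum with fewer than `min_group_size` = k members
(default 10) is censored in full; its rows contribute nothing to any model.
Censoring entire small strata is the privacy mechanism: a patient in a
sparse corner of feature space simply does not exist for the generator, and
the output size may consequently fall a few percent short of the input
size. If every stratum falls below k the fit fails with a diagnostic
listing stratum sizes rather than silently producing nothing.

### Bandwidths and jitter scales

Per numeric dimension the bandwidth follows Silverman's rule computed
within the stratum: h = 0.9 · min(s, IQR/1.34) · m^(−1/5). Zero dispersion
gives h = 0, so constant columns are reproduced exactly instead of
erroring. Two refinements matter in practice:

* **Log-scale jitter for heavy tails.** For a strictly positive dimension
  whose within-group sample skewness exceeds 1, noise is added to log
  values (with h computed on the log scale). A single linear-scale
  bandwidth sized for a heavy-tailed bulk (alarm counts spanning 1 to
  ~18,000) is enormous relative to the lower quartile; combined with
  envelope rejection at the support boundary it systematically inflates the
  lower tail. Multiplicative noise respects the tail geometry and leaves
  rank-based comparisons between original and derivative undisturbed.
* **Atom preservation.** A value shared by at least k members of the
  stratum (a zero-inflated severity score, a heaped measurement) is emitted
  exactly, without jitter. Smoothing an atom of 40% zeros into a continuum
  visibly distorts the marginal; and a value carried by ≥ k patients is
  non-identifying by exactly the argument that justifies the stratum
  threshold.

Count-kind dimensions are rounded half away from zero after jitter and
clamped to the (integer) envelope and declared bounds.

### Envelope censoring

Policy reject-then-clip: a jittered value outside the stratum's observed
[min, max] triggers a redraw of the kernel noise, up to `max_rejects`
(default 10) rounds, after which it is clipped to the envelope and the clip
is counted in the output's audit sidecar. Consequences asserted by the test
suite: the synthetic support never exceeds the real support per feature
(synthetic maxima are typically *below* real maxima, since the extreme
order statistics are rarely redrawn), and with positive bandwidth the
probability of reproducing a real row exactly is zero.

### Determinism

All randomness flows from one `numpy` Generator seeded by a single integer.
Draw order is fixed: strata in sorted key order; within a stratum the donor
indices first, then each declared feature in spec order (noise, then
rejection redraws); finally one output permutation. Identical
(matrix, spec, config, seed) yields byte-identical output.

## The validation harness

**Fidelity.** Per numeric feature: the five-figure quantile panel (min,
25th, 50th, 75th, 90th, max; linear-interpolation quantiles) plus a
two-sided Wilcoxon rank-sum test (exact enumeration when the combined
sample is under 20 and tie-free, otherwise the tie-corrected normal
approximation without continuity correction) and a two-sample
Kolmogorov–Smirnov test. Per categorical/binary feature: Pearson's
chi-squared on the 2×L level-count table. Across features: all p(p−1)/2
pairwise correlations (Pearson or Spearman) in both tables with absolute
deltas. p-values are reported unadjusted — the report counts how many fall
below α (default 0.05, configurable) instead of applying a multiplicity
correction, because the per-feature values are descriptive, not
confirmatory.

**Utility (TSTR).** An L2-regularised logistic regression (penalty λ,
default 1 on standardised features; classification threshold 0.5) evaluated
over three train/test cells — (real, real), (synthetic, synthetic),
(synthetic, real) — each with training-split, stratified 5-fold
cross-validated, and 20% stratified-holdout metrics (accuracy, precision,
recall, F1, AUROC). The real holdout is split once and shared by the first
and third cells, so the TSTR comparison is on identical rows. The scaler is
always fitted on the training source only and applied to whatever is
scored, preventing leakage. The headline TSTR statistic is the absolute
AUROC gap between the synthetic-trained and real-trained models on that
shared real holdout.

**Rates.** Unadjusted event rates per 100,000 persons by year and zip with
census population denominators, reported to one decimal. Real-vs-synthetic
yearly differences are signed synthetic − real; the 95% CI is a Wald
interval with Poisson variance per arm, difference ± 1.96·√(r_r²/n_r +
r_s²/n_s). The CI construction for such comparisons is not standardised;
the point differences are exact arithmetic, the interval method is this
package's choice and is stated in the output.

## The simulated cohorts

The fixtures target published summary statistics of three real clinical
settings, not the unavailable patient-level data. Passing tests therefore
demonstrate that the pipeline preserves the *structure the generators
encode* — marginals with the right medians and tails, a calibrated rank
correlation, a known logistic outcome model, Poisson event counts — and
cannot certify behaviour on real EHR pathologies the generators omit:
informative missingness, measurement batch effects, coding drift, or tail
shapes beyond the assumed log-linear interpolation.

* **Trauma cohort** (default n = 410): severity score (zero-inflated
  discrete), alarm count and ICU length of stay (heavy-tailed, quantile-
  anchor marginals interpolated on the log scale), and the alarm-rate
  ratio. Dependence comes from a Gaussian copula whose latent correlations
  (0.305, 0.0, 0.60) were calibrated once so the realized Spearman
  correlation between severity and alarm rate centres on the 0.34 target;
  at n = 410 the realized value fluctuates with sd ≈ 0.05.
* **Sepsis case–control matrix** (default 643 cases, 2 controls per case,
  169 features; the test suite additionally runs a reduced 40-feature
  configuration for speed): one latent severity factor drives eight
  continuous vitals/demographics and a block of binary abnormal-flag and
  comorbidity indicators, padded with inert lab-summary features to the
  requested width. Labels follow a logistic model on standardised features
  whose coefficient scale (0.9) was calibrated once so the true predictor's
  AUROC is ≈ 0.89; exact case/control counts are enforced by stratified
  rejection, making prevalence exactly 1/3 by construction.
* **Chlamydia surveillance** (2010–2015, 12 zips, total population
  580,892, matching the denominator implied by the published first-year
  rate): per zip-year
  Poisson counts with yearly target rates of 78.5–105.5 per 100,000 and
  zip-level multipliers renormalised to population-weighted mean 1; ages
  normal(23, 5.7) truncated at 13, female share 57–69% by year.

## Open design points and how they were resolved

* Feature windows and abnormal-flag thresholds use closed (inclusive)
  endpoints; stays of exactly 24 h take the 12-hour index rule. Boundary
  conventions are otherwise arbitrary; these are documented and tested.
* Two-level categoricals one-hot encode to a single 0/1 column; higher
  cardinality gets one column per level.
* Variance and standard-deviation aggregators use the n−1 denominator.
* The `count` aggregator of an empty window is 0; every other aggregator
  yields missing. Missing composite operands propagate missing (with one
  log entry) rather than erroring.
* Control sampling is uniform without replacement from the non-case pool,
  exact in count, seeded.
* Rate tables round rates and differences to one decimal on report; full
  precision is kept internally.

## Problem sizes

The default test run keeps simulations at the scale the analyses need:
100 seeded replicates for the trauma similarity panel (n = 410), 100
replicates of the n = 2000 bivariate-normal fidelity check, 20 replicates
of the 40-feature TSTR grid (n = 1929), with the full 169-feature path
covered once at reduced n. The complete suite runs in well under a minute
of CPU time apart from the TSTR replicates (~10 s).

## Known limitations

* Donor-based sampling reproduces only dependence present in the original;
  it cannot extrapolate beyond the observed support (by design), so
  synthetic extremes under-represent real extremes.
* Kernel jitter attenuates Pearson correlations by roughly 1/(1 + h²/σ²)
  per dimension; at n = 2000 standard-normal inputs this is ≈ 4% of the
  correlation, visible in the fidelity band test.
* Stratification is axis-aligned (levels × quantile bins); it does not
  discover latent clusters.
* The chi-squared comparison needs expected counts that are not tiny; very
  rare levels are pooled out of the test rather than corrected.
* Privacy here is mechanistic (k-threshold censoring, envelope clipping,
  no row correspondence), not a formal differential-privacy guarantee.
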