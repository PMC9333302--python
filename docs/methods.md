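# Methods

## Model and assumptions

The data model is an *n* × *r* matrix of feature values with a binary
outcome per subject. Feature values are assumed i.i.d. across subjects
within each outcome class, each feature following some fixed per-class
marginal distribution; features need not be independent of one another.
Reproducibility is a property of the pair (data-generating distribution,
discovery operator): the expected Jaccard overlap of the biomarker sets
the operator returns on two independent, outcome-comparable datasets.
Only the *set* of proposed biomarkers is scored; rankings, effect sizes
and cross-size comparisons (e.g. a size-100 set against a size-300 set)
are out of scope, as is learning feature combinations.

The canonical discovery operator is the two-sided pooled-variance
two-sample *t*-test per feature, Benjamini–Hochberg (BH) correction
across all tested features, and a strict threshold `p_adj < alpha` with
`alpha = 0.05`. The pooled test implicitly assumes per-class normality
with equal variances; Welch's unequal-variance statistic is available as
a non-canonical alternative (`test="welch"`). Genotype matrices are first
converted to minor-allele counts {0, 1, 2} and then treated as
continuous.

## Estimators

All estimators draw `k` resampled dataset pairs, run discovery on each
member, and report the mean and sample standard deviation (ddof = 1) of
the `k` Jaccard values. Defaults: `k = 50` for oRS/uRS/bRS/RS-hat,
`k = 20` for subset-size curves.

* **oRS** — doubled-partition overbound. The doubled multiset (every
  subject twice) is split per class exactly in half over the 2·n_c copy
  slots, so each half carries the parent class counts and may contain a
  subject twice. Expected fraction of distinct subjects present in both
  halves: n_c/(2n_c − 1) ≈ 50%.
* **uRS** — disjoint-halving underbound. Per class, floor(n_c/2) subjects
  go to each half without replacement; with an odd class count one
  subject sits out that repetition (a fresh random choice each time), so
  the halves always remain exactly comparable.
* **bRS** — two independent per-class size-n bootstrap resamples per
  repetition.
* **RS-hat** — uRS on the full data, re-tagged: because its two halves
  are genuinely disjoint same-size samples, it estimates the true
  reproducibility of half-sized subsets and is the yardstick against
  which oRS/uRS computed on a fixed half-subset are validated.
* **Subset-size curve** — for each requested size s ≤ n/2, disjoint
  outcome-proportional size-s subset pairs (per-class quotas by largest
  remainder; infeasible sizes are skipped with a warning).
* **RS\*** — Monte-Carlo truth on synthetic data only: independent
  dataset pairs drawn from the known generating law.

Randomness: one root seed per estimator call; repetition *i* uses the
child generator `default_rng([seed, salt, i])` with a fixed
per-construction salt. Growing `k` therefore extends a run without
reshuffling earlier repetitions, and any single repetition can be
replayed from its logged child seed.

## Synthetic generator

Continuous mode draws equal-variance Gaussians: non-planted features are
N(0, σ²) in both classes; the first `n_true` features are shifted by
δ·σ in the positive class. This matches the pooled *t*-test's own
assumptions, so discovery power is governed by δ·√(n_c/2) alone.
Genotype mode draws minor-allele counts Binomial(2, maf) with a
class-dependent frequency on planted features. Two non-canonical options
support robustness experiments and default off: Student-t noise
(heavy tails) and equicorrelated feature blocks (parameter ρ, block size
10; marginals unchanged).

What the generator does *not* emulate: empirical expression
distributions (skew, heteroscedasticity, normalization artifacts),
realistic correlation structure, batch effects, or a continuum of effect
sizes — planted effects are all-or-nothing. Passing tests on this model
therefore demonstrate the estimators' behaviour under their own
assumptions, not performance on any particular public dataset.

## Numerical choices and degenerate inputs

* Zero pooled variance: equal means give t = 0 (p = 1); differing means
  give t = ±∞ (p = 0) — the continuity limit, so constant features never
  crash a run.
* Threshold is strict (`p_adj < alpha`); a feature whose adjusted p
  equals alpha exactly is not a discovery.
* BH family size is the number of features actually tested.
* Jaccard of two empty sets is 0 (a pipeline that finds nothing is not
  rewarded as reproducible); `alpha = 1` with no correction is permitted
  but logged as degenerate (every feature is selected, score trivially 1).
* Survival dichotomization: the median is computed once over *all* input
  times (order-independent, non-circular); times equal to the median
  count as long survival; subjects censored before the median are
  removed.
* Minor-allele ties at exactly 50/50 go to the lexicographically later
  symbol; monomorphic columns encode as all zeros.
* Positive-class label defaults to the lexicographically larger outcome
  string; the two-sided test makes discovery invariant to this choice.
* Missing values are rejected at construction; the reader can instead
  drop (and log) affected features.

## Regimes of validity — known limitations

The bracketing property of oRS/uRS is a heuristic, not a theorem, and
the package's own grid experiments delineate where it holds.

* In the weak-to-moderate signal regime (Jaccard scores roughly below
  0.5 — the regime typical of real cohort studies), uRS ≤ oRS and
  uRS ≤ RS-hat ≤ oRS behave as advertised; the test suite validates the
  RS-hat sandwich at δ = 0.5.
* Resampled halves containing duplicated subjects violate the t-test's
  independence assumption: on a doubled half the null rejection rate at
  nominal α = 0.05 roughly doubles (a test pins it between 0.08 and
  0.14). Under BH this floods oRS halves with false positives that are
  only partially shared between the two halves. Once discovery
  *saturates* (strong effects, large n: every true feature is found by
  every half), uRS approaches the near-perfect overlap of two correctly
  FDR-controlled sets while oRS is dragged down by its excess false
  positives — the bounds invert, and oRS also falls below the Monte-Carlo
  truth RS\*. The same mechanism, amplified, puts bRS below oRS outside
  the null regime. Scores in the saturated regime should be read as
  diagnostics of the resampling constructions, not as bounds.
* BH controls the false-discovery *rate*, not the probability of any
  false positive: even with overwhelming planted signal, roughly a third
  of datasets carry at least one extra feature beyond the planted truth,
  so exact set recovery is never guaranteed.
* RS\* (truth under the generating law) and the score the bounds target
  (reproducibility under the *empirical* distribution of the observed
  dataset) are distinct quantities; they are close only when n is large
  relative to the effect structure.

## Problem sizes used in the checks

Grid experiments use r = 200 features with 20 planted biomarkers —
the package's reference synthetic conditions — across
δ ∈ {0, 0.5, 1, 2} and n ∈ {60, 200} with k = 50; null calibration uses
200 zero-effect datasets of 100 + 100 × 200 features; the subset-size
curve uses δ = 1 at n = 400 with k = 20; oracle-agreement checks use 100
random datasets of at most 8 × 5.
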