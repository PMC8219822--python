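# Methods

## Data model

The unit of analysis is the published article. A `StudyRecord` carries
the publication year (window 2010–2019 inclusive by default), the
counts of female and male participants, and — for articles including
women — a ternary orientation-reported flag, per-orientation head
counts, a phase-reported flag, and an optional phase label. Transgender
participants are counted in the gender group the source article
reports; there is no separate field. Orientation detail that a study
reports without categorizing is the explicit category `unspecified`, so
count invariants (`Σ orientation counts ≤ n_women`) always validate.
Men-only studies must carry not-applicable flags. The interchange
format is a comma-separated UTF-8 CSV with a fixed header; orientation
counts serialize as `category:count` pairs joined by semicolons.
Reading and writing round-trip exactly, and malformed rows fail with
the line number and field named.

The modelling observation is `(t, y, N)` with `t = year − 2010` and
`y = n_women/N` computed exactly, so `y` is 0 or 1 only for single-sex
studies. Year is indexed, not centered: intercepts read as 2010-level
quantities. Because inflation is exact by construction of `n/N`, a `y`
within 1e−12 of an endpoint but not equal to it is treated as interior,
never snapped.

## Descriptive layer

Articles partition into women-only (`n_men = 0`), men-only
(`n_women = 0`) and mixed; participants partition accordingly, with
mixed studies contributing women and men separately. Every year in the
window yields a row (all-zero if empty), percentages are relative to
annual totals, and display rounding is half-up to one decimal, isolated
in a formatting helper — internal values are never rounded. Decade
averages use the arithmetic mean; the SD denominator defaults to n−1,
which is the convention the packaged decade table is numerically
consistent with, with `ddof=0` exposed since the convention cannot be
established beyond that. Quartiles use linear interpolation (type-7),
the default of most software; a different convention can shift an IQR
endpoint by about one participant, which matters when comparing against
published medians. Sample-size summaries flag empty categories as
absent rather than zero. The packaged aggregates are decade tables of
annual counts; summing them reproduces 1,407 articles and 28,030
participants, and the module always reports computed totals rather than
any quoted figure (published grand totals are not all mutually
consistent at the article level).

The orientation breakdown reports, among articles with women: the
percentage not reporting orientation; among reporters, the percentage
of articles involving each orientation category (an article with groups
in several categories counts toward each, so these can exceed 100 in
principle); the percentage controlling phase; and the phase-label split
among controllers.

## ZOIB regression

The mixture is parameterized conditionally: `p` is the probability of
an exact zero and `q` the probability of an exact one given not zero.
The published prose is ambiguous between joint and conditional forms;
the conditional form follows the standard zero-one-inflated beta
formulation, and the joint one-probability `(1−p)q` is recoverable for
reporting. The beta component uses the mean–precision parameterization
`Beta(μφ, (1−μ)φ)` with a single scalar φ (no covariates on shape).
All three components get logit links with their own intercept/slope
pairs in `t`.

Priors: normal(mean 0, precision 0.001) on the six coefficients, as
specified for the original analysis; the shape prior is not stated
there, so φ gets a diffuse gamma(0.01, 0.01) and is sampled as log φ
with the Jacobian term included. Conclusions about the slopes are
insensitive to this choice at the corpus sizes involved; intercept-level
comparisons with published coefficients may also be offset if the
original fit rescaled the year covariate, which is unstated.

Derived quantities are computed per posterior draw: the marginal
expected proportion `E[y|t]` for each year and the annual change
`(E[y|t_max] − E[y|0]) / t_max`, which equals the mean of the successive
yearly differences.

The likelihood is evaluated through per-year sufficient statistics
(counts of zeros, ones and interior observations, and interior sums of
`log y` and `log(1−y)`), which is algebraically identical to the
observation-wise sum but costs O(years) per evaluation; the tests
assert exact agreement between the two routes. Years with no interior
observations skip the beta term entirely, which also guards the `0·∞`
case when a proposal drives μ to an extreme.

## Sampler

A blockwise Gaussian random-walk Metropolis kernel, with blocks
(b0, b1), (a0, a1), (c0, c1), (log φ): the schedule (chains, draws,
burn-in, thinning) is specified for the original analysis but the
kernel is not, and random-walk Metropolis is the least-assumption
choice. Proposal scales adapt once per 100 burn-in sweeps by
`exp(2(rate − 0.3))` toward a 0.3 acceptance rate, and adaptation stops
at the end of burn-in so retained draws come from a fixed kernel. Each
chain's generator is spawned deterministically from the base seed and
chain index; the whole pipeline is a pure function of (data, config,
seed). Degenerate adaptation windows (zero acceptances) warn rather
than fail.

Defaults mirror the published schedule — 4 chains × 250,000
retained-eligible draws after 25,000 burn-in, thinned by 10. The
phrase "250,000 samples after a burn-in of 25,000 additional draws" is
read as 250,000 retained-eligible; if the original meant 250,000 total
the difference is a trivial change in Monte-Carlo error. Reduced
schedules (4 × 5,000 after 1,000) used in tests, examples and the
acceptance script differ only through `MCMCConfig` — there is no
separate fast code path. At the default corpus size the reduced
schedule yields split-chain R-hat ≲ 1.03 on all parameters and
credible intervals stable to the displayed precision.

Summaries are posterior means with equal-tailed 95% intervals
(empirical 2.5/97.5% quantiles); highest-density intervals are not
used. The split-chain R-hat is the classical (non-rank-normalized)
form, cross-checked in the tests against an independent implementation;
1.01 is an advisory threshold that is reported, never enforced.

## Reporting trend

One Bernoulli observation per article that includes at least one woman
(women-only and mixed articles weighted equally), with
`logit(π_t) = g0 + g1 t`. The slope prior is normal(0, 1) as specified
for the original analysis; that specification names only the year
coefficient, so the intercept gets a weakly informative normal(0,
sd 10) — a documented divergence risk for intercept-level comparisons.
Complete-separation corpora (everyone reports, or no one does) still
run; the priors keep the posterior proper and the intercept finite.

## Power

Exact two-sided power of the equal-`n` pooled-variance two-sample
t test: `P(|T'| > t_crit)` with `T'` noncentral t on `2n − 2` df and
noncentrality `d√(n/2)`. The lower rejection tail is included — at
`d = 0.8` it contributes under half a percentage point, but the
computation is exact rather than the common upper-tail approximation.
One-sided power is available. A vectorized Monte-Carlo oracle
(simulated t tests) backs the analytic values in the tests.

## Synthetic data generator

The generator draws, per study in year `t`: men-only with probability
`p_t`; otherwise women-only with probability `q_t`; otherwise a mixed
study with female share from `Beta(μ_t φ, (1−μ_t) φ)` — the exact
process the regression assumes. Defaults define the reference
conditions and are not tuning knobs:

- per-year study counts: the published annual totals
  (95, 120, 108, 117, 162, 167, 134, 162, 166, 176; 1,407 studies);
- truth `b0 = 1.0, b1 = −0.065` (men-only share ≈73% → ≈60%),
  `a0 = −0.55, a1 = 0.01` (mixed-study female share ≈37%),
  `c0 = −1.6, c1 = 0`, `φ = 5`, implying 2010/2019 expected proportions
  ≈12.7%/19.5% and an annual change ≈0.76 percentage points;
- sample sizes: shifted negative binomials supported on integers ≥ 2,
  with (shift 2, r 2.5, mean 16) for women-only (median 14),
  (2, 3, 11.5) for men-only (median 10) and (2, 4, 19) for mixed totals
  (subgroup medians ≈ 6 women / 11 men); `N` and `y` are drawn
  independently within mixed studies, a simplification flagged because
  the real joint distribution is unknown;
- reporting: `g0 = logit(0.28)`, `g1 = 0.03`; reporters' orientation
  split 64/26/10 across natural-menstruating / oral-contraceptive /
  unspecified; phase controlled with conditional probability 0.786
  given reporting, labels split 48/21/19/12 across follicular /
  placebo-pill / early-follicular / other.

Mixed-study counts are integers (`n_women = round(yN)` clamped to
`[1, N−1]`), so the emitted proportion sits on the `n/N` grid while the
model treats it as continuous. This discretization is deliberate — it
is exactly how real data reach the model — and it mildly biases small
shares upward (clamping at 1 woman) and coarsens φ. Recovery tests
therefore target the slopes and derived proportions, which are robust
to the rounding; `generate_observations` emits raw continuous `y` for
exact model-faithful checks. The generator does not emulate screening
decisions, within-study correlation of design choices, or any
year-to-year dependence beyond the configured trends, so passing tests
demonstrate correctness of the machinery under the assumed process, not
the realism of that process for any particular literature.

`recovery_experiment` runs generate → fit → score over independent
seeded replicates, reporting 95% CI coverage of each true slope, the
per-year error of the expected-proportion estimates, and the annual
change posterior means. At the default corpus size with the reduced
schedule, slope coverage is at or near nominal (≥ 16/20 in the packaged
check) and flat-truth corpora give annual-change estimates centered on
zero.

## Pipeline and CLI

`run_full_analysis` runs descriptives, the ZOIB fit, the reporting
trend and the power table, writing CSV/JSON outputs, a text report
whose every number is traceable to a machine-readable field, a
proportion-by-year figure with its credible band, and a run manifest
(command, config hash, seed, paths, timestamp, version). Summary files
are byte-stable given (data, config, seed); only the manifest carries a
timestamp. A corpus with no women still produces descriptives and the
ZOIB fit (all responses zero); the reporting stages are skipped with a
logged warning because `fit_reporting_trend` itself raises cleanly on
an empty eligible set. Any other stage failure aborts with the stage
name and removes partial outputs. The CLI is a thin wrapper
(`simulate`, `describe`, `fit-zoib`, `fit-reporting`, `power`,
`run-all`); `--fast` switches to the reduced schedule with a prominent
log line.

## Problem sizes

Tests and the acceptance script use the reduced sampler schedule and
the default 1,407-study corpus; the recovery check uses 20 replicates
at full corpus size. These sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping a full run to a few
minutes on one CPU.

## Known limitations

- The sampler is random-walk Metropolis; for much larger corpora or
  extra covariates a gradient-based kernel would mix better.
- Orientation categories are modelled (and generated) at article level
  with a single category per reporting article; real articles can
  include several orientation groups at once, which the data model
  supports but the generator does not produce.
- The reporting model ignores article sample size (one article, one
  flag), matching the article-level percentages it targets.
- Reproducing the published per-study coefficients requires the
  deposited review dataset, which is not bundled; the package validates
  against closed forms, independent oracles and parameter recovery
  instead.
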