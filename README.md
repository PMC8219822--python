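# thermorep

Tools for auditing the representation of women in a decade of
exercise-thermoregulation research (2010–2019): descriptive decade
tables, a Bayesian zero-one-inflated beta (ZOIB) regression of the
per-study female proportion on publication year, a Bayesian logistic
trend model for menstrual-orientation reporting, and exact power
calculations for the small two-sample designs typical of the field. It
is written for exercise physiologists and meta-researchers who want the
full analysis as a tested, reusable library rather than a one-off
script, and it ships a synthetic-corpus generator so every stage can be
exercised and validated without the underlying review data.

## The model

Each reviewed article contributes a female proportion `y = n/N` (`n`
women among `N` participants). `y` is exactly 0 for men-only and
exactly 1 for women-only studies, so the response is modelled as a
zero-one-inflated beta mixture indexed by year `t` (2010 → 0):

```
P(y = 0 | t)          = p_t
P(y = 1 | t, y ≠ 0)   = q_t
y | t, 0 < y < 1      ~ Beta(μ_t φ, (1 − μ_t) φ)

logit(p_t) = b0 + b1 t,   logit(q_t) = c0 + c1 t,   logit(μ_t) = a0 + a1 t
```

with normal(0, precision 0.001) priors on the six coefficients and a
diffuse gamma(0.01, 0.01) prior on the shared precision φ. The marginal
expected proportion `E[y|t] = (1−p_t)q_t + (1−p_t)(1−q_t)μ_t` and its
average change per year are derived from the posterior. Inference is by
blockwise adaptive random-walk Metropolis (default: 4 chains × 250,000
draws after 25,000 burn-in, thinned by 10), summarized as posterior
means with equal-tailed 95% credible intervals and split-chain R-hat.

Orientation reporting is a Bernoulli model with
`logit(π_t) = g0 + g1 t` over articles that include women (normal(0, 1)
prior on `g1`). Power for an equal-`n` two-sample t test uses the
noncentral t distribution with `df = 2n − 2` and noncentrality
`d·√(n/2)`, both rejection tails included.

## Worked example

```python
from thermorep import (GeneratorConfig, MCMCConfig, fit_zoib,
                       generate_study_dataset, to_observation)

corpus = generate_study_dataset(GeneratorConfig(seed=42))   # 1,407 studies
config = MCMCConfig(n_chains=4, n_draws=5_000, burn_in=1_000, thin=10, seed=7)
fit = fit_zoib([to_observation(r) for r in corpus], config)
```

Running `python examples/03_simulate_and_fit_zoib.py` (the same steps)
prints:

```
Simulated 1407 studies over 2010-2019
Expected proportion of women 2010: 14.4% [11.6, 17.6]
Expected proportion of women 2019: 18.3% [15.8, 21.1]
Annual change: 0.43 [-0.11, 0.97] %-points/year
P(men-only) slope: -0.045 [-0.088, -0.003]  (logit scale)
beta-mean slope: -0.007 [-0.037, +0.021]  (logit scale)
P(women-only) slope: +0.004 [-0.093, +0.096]  (logit scale)
```

Women are a minority of participants throughout the decade; the slow
rise in their expected share is driven by a credibly negative men-only
slope (fewer all-male studies) rather than by women making up more of
mixed samples or by more women-only studies. The other examples cover
the decade tables (`01`), power at typical subgroup sizes (`02` — 6 per
group gives 24% power for d = 0.8), and the reporting trend (`04`).

A thin CLI wraps the same functions:

```
thermorep simulate --seed 5 --out corpus.csv
thermorep run-all --input corpus.csv --outdir results --fast --seed 5
thermorep power --n 6 --d 0.8
```

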