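"""Did menstrual-orientation reporting change over the decade?

Simulates a corpus whose women-including articles report orientation
with probability ≈28% (flat trend), then fits the Bayesian logistic
trend model and prints the posterior for the year slope.
"""

from thermorep import (
    GeneratorConfig,
    MCMCConfig,
    fit_reporting_trend,
    generate_study_dataset,
    women_inclusion_breakdown,
)

corpus = generate_study_dataset(GeneratorConfig(seed=11))
breakdown = women_inclusion_breakdown(corpus)
print(
    f"{breakdown['n_articles_with_women']} articles include women; "
    f"{breakdown['pct_not_reporting_orientation']}% do not report orientation"
)
print(f"Orientation split among reporters: {breakdown['orientation_category_pct']}")

config = MCMCConfig(n_chains=4, n_draws=5_000, burn_in=1_000, thin=10, seed=3)
fit = fit_reporting_trend(corpus, config)
s = fit.slope
print(f"Reporting year slope: {s.mean:+.3f} [{s.ci_low:+.3f}, {s.ci_high:+.3f}] (logit scale)")
# A credible interval spanning zero means no evidence that reporting
# practice improved or worsened across the window.
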