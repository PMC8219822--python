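"""Synthetic study corpora with the statistical structure the analysis assumes.

Each simulated year draws a mixture of men-only studies (probability
p_t), women-only studies (q_t of the remainder), and mixed-sex studies
whose female share comes from the beta component — exactly the
zero-one-inflated beta process the regression fits. Sample sizes come
from shifted negative binomial distributions tuned to the field's
typical study sizes (medians ≈ 14 women-only, 10 men-only, and ≈ 10 men
/ 6 women within mixed studies), and orientation/phase reporting flags
follow a Bernoulli model whose log odds trend with year.

Mixed-study counts are integers: the continuous beta draw y is rounded
to ``n_women = round(y N)`` and clamped to [1, N−1]. This discretizes
the proportion onto the n/N grid, deliberately mirroring how real data
reach the model; :func:`generate_observations` emits the raw continuous
y instead for exact model-faithful recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logit

from .data_model import DEFAULT_WINDOW, NO, YES, ProportionObservation, StudyRecord, YearWindow
from .mcmc import MCMCConfig
from .trends import TrendCoefficients
from .zoib import (
    ZOIBParameters,
    annual_change,
    component_values,
    fit_zoib,
    marginal_expected_proportion,
)

#: published annual article totals, used as the default corpus scale
TABLE1_ANNUAL_TOTALS = (95, 120, 108, 117, 162, 167, 134, 162, 166, 176)

#: default data-generating truth: men-only probability falling from ≈0.73
#: to ≈0.60 over the decade, mixed-study female share ≈0.37 rising slowly,
#: women-only ≈0.17 of the non-men-only remainder, beta precision 5
DEFAULT_TRUTH = ZOIBParameters(b0=1.0, b1=-0.065, a0=-0.55, a1=0.01, c0=-1.6, c1=0.0, phi=5.0)

#: default reporting trend: ≈28% of women-including articles report
#: orientation in 2010, with a slight upward log-odds drift
DEFAULT_REPORTING = TrendCoefficients(g0=float(logit(0.28)), g1=0.03)

DEFAULT_ORIENTATION_DIST: dict[str, float] = {
    "natural-menstruating": 0.64,
    "oral-contraceptive": 0.26,
    "unspecified": 0.10,
}

DEFAULT_PHASE_DIST: dict[str, float] = {
    "follicular": 0.48,
    "placebo-pill": 0.21,
    "early-follicular": 0.19,
    "other": 0.12,
}


@dataclass(frozen=True)
class SizeModel:
    """Shifted negative binomial on integers ≥ shift: shift + NB(r, p(mean))."""

    shift: int = 2
    r: float = 3.0
    mean: float = 12.0

    def __post_init__(self) -> None:
        if self.shift < 2:
            raise ValueError("study sizes must be supported on integers >= 2")
        if self.r <= 0 or self.mean <= self.shift:
            raise ValueError("need r > 0 and mean > shift")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        p = self.r / (self.r + self.mean - self.shift)
        return self.shift + rng.negative_binomial(self.r, p, size)


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that defines a synthetic corpus, including its seed."""

    params: ZOIBParameters = DEFAULT_TRUTH
    studies_per_year: tuple[int, ...] = TABLE1_ANNUAL_TOTALS
    window: YearWindow = DEFAULT_WINDOW
    women_only_sizes: SizeModel = SizeModel(shift=2, r=2.5, mean=16.0)
    men_only_sizes: SizeModel = SizeModel(shift=2, r=3.0, mean=11.5)
    mixed_sizes: SizeModel = SizeModel(shift=2, r=4.0, mean=19.0)
    reporting: TrendCoefficients = DEFAULT_REPORTING
    orientation_dist: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORIENTATION_DIST)
    )
    phase_given_reported: float = 0.786
    phase_dist: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PHASE_DIST))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.studies_per_year) != self.window.n_years:
            raise ValueError("studies_per_year length must match the year window")
        if any(k < 0 for k in self.studies_per_year):
            raise ValueError("study counts must be non-negative")
        for dist, label in ((self.orientation_dist, "orientation"), (self.phase_dist, "phase")):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{label} distribution must sum to 1")
        if not 0.0 <= self.phase_given_reported <= 1.0:
            raise ValueError("phase_given_reported must lie in [0, 1]")


def _draw_structure(
    config: GeneratorConfig, rng: np.random.Generator, *, continuous: bool
) -> list:
    """Core mixture draw; returns StudyRecords or raw observations."""
    out = []
    for t, year in enumerate(config.window.years):
        p, q, mu = component_values(config.params, t)
        phi = config.params.phi
        for k in range(config.studies_per_year[t]):
            sid = f"Y{year}-{k + 1:03d}"
            u = rng.uniform()
            if u < p:  # men-only: exact zero
                n = int(config.men_only_sizes.sample(rng))
                if continuous:
                    out.append(ProportionObservation(t=t, y=0.0, N=n))
                else:
                    out.append(StudyRecord(study_id=sid, year=year, n_women=0, n_men=n))
            elif rng.uniform() < q:  # women-only: exact one
                n = int(config.women_only_sizes.sample(rng))
                if continuous:
                    out.append(ProportionObservation(t=t, y=1.0, N=n))
                else:
                    out.append(
                        StudyRecord(
                            study_id=sid, year=year, n_women=n, n_men=0,
                            orientation_reported=NO, phase_reported=NO,
                        )
                    )
            else:  # mixed: beta component
                y = float(rng.beta(mu * phi, (1.0 - mu) * phi))
                n_total = int(config.mixed_sizes.sample(rng))
                if continuous:
                    out.append(ProportionObservation(t=t, y=y, N=n_total))
                else:
                    n_women = int(np.clip(round(y * n_total), 1, n_total - 1))
                    out.append(
                        StudyRecord(
                            study_id=sid, year=year, n_women=n_women,
                            n_men=n_total - n_women,
                            orientation_reported=NO, phase_reported=NO,
                        )
                    )
    return out


def generate_study_dataset(config: GeneratorConfig) -> list[StudyRecord]:
    """A full synthetic corpus of study records, reporting flags attached.

    Deterministic given ``config.seed``: the structural mixture and the
    reporting flags use independent child streams of the same seed.
    """
    ss = np.random.SeedSequence(config.seed).spawn(2)
    structure_rng = np.random.Generator(np.random.PCG64(ss[0]))
    records = _draw_structure(config, structure_rng, continuous=False)
    return attach_reporting(
        records,
        config.reporting,
        orientation_dist=config.orientation_dist,
        seed=ss[1],
        phase_given_reported=config.phase_given_reported,
        phase_dist=config.phase_dist,
        window=config.window,
    )


def generate_observations(config: GeneratorConfig) -> list[ProportionObservation]:
    """Continuous-response variant: raw beta draws, no n/N discretization."""
    ss = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.Generator(np.random.PCG64(ss[0]))
    return _draw_structure(config, rng, continuous=True)


def attach_reporting(
    records: Sequence[StudyRecord],
    coeffs: TrendCoefficients,
    orientation_dist: Mapping[str, float] | None = None,
    seed: int | np.random.SeedSequence = 0,
    phase_given_reported: float = 0.786,
    phase_dist: Mapping[str, float] | None = None,
    window: YearWindow = DEFAULT_WINDOW,
) -> list[StudyRecord]:
    """Draw orientation/phase reporting fields for every record with women.

    Reporting is Bernoulli(inv-logit(g0 + g1 t)); reporters get a single
    orientation category for all their female participants from the
    configured distribution, and control phase with the configured
    conditional probability. Records without women are passed through.
    """
    orientation_dist = dict(orientation_dist or DEFAULT_ORIENTATION_DIST)
    phase_dist = dict(phase_dist or DEFAULT_PHASE_DIST)
    rng = np.random.Generator(np.random.PCG64(seed))
    cats = list(orientation_dist)
    cat_p = np.array([orientation_dist[c] for c in cats])
    labels = list(phase_dist)
    label_p = np.array([phase_dist[c] for c in labels])
    out: list[StudyRecord] = []
    for rec in records:
        if not rec.includes_women:
            out.append(rec)
            continue
        t = rec.year - window.start
        reported = rng.uniform() < expit(coeffs.g0 + coeffs.g1 * t)
        if not reported:
            out.append(
                replace(rec, orientation_reported=NO, orientation_counts={},
                        phase_reported=NO, phase_label=None)
            )
            continue
        cat = cats[int(rng.choice(len(cats), p=cat_p))]
        controls_phase = rng.uniform() < phase_given_reported
        label = labels[int(rng.choice(len(labels), p=label_p))] if controls_phase else None
        out.append(
            replace(
                rec,
                orientation_reported=YES,
                orientation_counts={cat: rec.n_women},
                phase_reported=YES if controls_phase else NO,
                phase_label=label,
            )
        )
    return out


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery results over seeded replicate corpora."""

    n_replicates: int
    truth: ZOIBParameters
    slope_coverage: dict[str, int]  # times the 95% CI covered each true slope
    annual_change_truth: float
    annual_change_means: np.ndarray  # per-replicate posterior means
    proportion_errors: np.ndarray  # (replicates, years): posterior mean − truth


def recovery_experiment(
    truth: ZOIBParameters,
    fit_config: MCMCConfig,
    n_replicates: int,
    seed: int = 0,
    gen_config: GeneratorConfig | None = None,
    continuous: bool = False,
) -> RecoveryReport:
    """Generate → fit → score, repeated over independent seeded corpora.

    Scores whether each true slope (b1, a1, c1) falls inside its 95%
    credible interval, the posterior-mean error of the per-year expected
    proportion, and the posterior mean of the annual change.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base = gen_config or GeneratorConfig()
    base = replace(base, params=truth)
    window = base.window
    from .data_model import to_observation  # local import avoids a cycle at module load

    slope_names = ("b1", "a1", "c1")
    coverage = {s: 0 for s in slope_names}
    change_means = np.empty(n_replicates)
    prop_err = np.empty((n_replicates, window.n_years))
    truth_props = np.array(
        [marginal_expected_proportion(truth, t) for t in range(window.n_years)]
    )
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    for i in range(n_replicates):
        cfg = replace(base, seed=int(rep_seeds[i]))
        if continuous:
            obs = generate_observations(cfg)
        else:
            obs = [to_observation(r, window) for r in generate_study_dataset(cfg)]
        try:
            fit = fit_zoib(obs, replace(fit_config, seed=int(rep_seeds[i])), window=window)
        except Exception as exc:  # noqa: BLE001 - annotate with replicate index
            raise RuntimeError(f"replicate {i} (seed {rep_seeds[i]}) failed to fit") from exc
        for name in slope_names:
            s = fit.params[name]
            if s.ci_low <= getattr(truth, name) <= s.ci_high:
                coverage[name] += 1
        change_means[i] = fit.annual_change.mean
        for t, year in enumerate(window.years):
            prop_err[i, t] = fit.proportion_by_year[year].mean - truth_props[t]
    return RecoveryReport(
        n_replicates=n_replicates,
        truth=truth,
        slope_coverage=coverage,
        annual_change_truth=annual_change(truth, window.n_years),
        annual_change_means=change_means,
        proportion_errors=prop_err,
    )
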