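"""Bayesian logistic trend model for menstrual-orientation reporting.

Unit of analysis is the article: every study that includes at least one
woman contributes one binary flag (orientation reported or not), and the
log odds of reporting are linear in the year index. The year slope
carries the normal(0, 1) prior; the intercept gets a weakly informative
normal(0, sd 10) prior, a documented divergence risk when comparing
intercept-level numbers against published fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import log_expit

from .data_model import DEFAULT_WINDOW, YES, StudyRecord, YearWindow
from .mcmc import MCMCConfig, PosteriorSummary, convergence, run_chains, summarize, thin_and_pool

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReportingObservation:
    """Year index and orientation-reported flag of one women-including article."""

    t: int
    reported: int

    def __post_init__(self) -> None:
        if self.reported not in (0, 1):
            raise ValueError("reported must be 0 or 1")


@dataclass(frozen=True)
class TrendCoefficients:
    """Intercept and year slope of the reporting model, logit scale."""

    g0: float
    g1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.g0) and math.isfinite(self.g1)):
            raise ValueError("trend coefficients must be finite")


def reporting_observations(
    records: Sequence[StudyRecord], window: YearWindow = DEFAULT_WINDOW
) -> list[ReportingObservation]:
    """One observation per article with women; others excluded with a logged count."""
    eligible = [r for r in records if r.includes_women]
    excluded = len(records) - len(eligible)
    if excluded:
        logger.info("excluded %d records without women from the reporting trend", excluded)
    return [
        ReportingObservation(t=r.year - window.start, reported=int(r.orientation_reported == YES))
        for r in eligible
    ]


def logistic_loglik(
    coeffs: TrendCoefficients, observations: Sequence[ReportingObservation]
) -> float:
    """Bernoulli log likelihood with pi = inv-logit(g0 + g1 t); 0 when empty."""
    if len(observations) == 0:
        return 0.0
    t = np.array([o.t for o in observations], dtype=float)
    r = np.array([o.reported for o in observations], dtype=float)
    eta = coeffs.g0 + coeffs.g1 * t
    return float(np.sum(r * log_expit(eta) + (1.0 - r) * log_expit(-eta)))


@dataclass(frozen=True)
class ReportingTrendFit:
    """Posterior fit of the reporting trend."""

    traces: np.ndarray
    pooled: np.ndarray
    intercept: PosteriorSummary
    slope: PosteriorSummary
    rhat: dict[str, float]
    n_observations: int

    def summary_dict(self) -> dict:
        return {
            "intercept": self.intercept.as_dict(),
            "slope": self.slope.as_dict(),
            "rhat": self.rhat,
            "n_observations": self.n_observations,
        }


def fit_reporting_trend(
    records: Sequence[StudyRecord],
    config: MCMCConfig,
    window: YearWindow = DEFAULT_WINDOW,
    slope_sd: float = 1.0,
    intercept_sd: float = 10.0,
) -> ReportingTrendFit:
    """Posterior mean and 95% CI for the reporting-trend intercept and slope.

    Degenerate corpora (all articles reporting, or none) still run: the
    posterior simply piles mass on large |g0|, bounded by the priors.
    """
    obs = reporting_observations(records, window)
    if not obs:
        raise ValueError("no records with women: cannot fit the reporting trend")
    t = np.array([o.t for o in obs], dtype=float)
    r = np.array([o.reported for o in obs], dtype=float)

    def log_target(v: np.ndarray) -> float:
        eta = v[0] + v[1] * t
        ll = float(np.sum(r * log_expit(eta) + (1.0 - r) * log_expit(-eta)))
        lp = -0.5 * (v[0] / intercept_sd) ** 2 - 0.5 * (v[1] / slope_sd) ** 2
        return ll + lp

    traces = run_chains(log_target, np.zeros(2), config, blocks=((0,), (1,)))
    pooled = thin_and_pool(traces, config.thin)
    rhat_vals = convergence(traces) if config.n_chains >= 2 else np.full(2, np.nan)
    s0, s1 = summarize(pooled[:, 0]), summarize(pooled[:, 1])
    return ReportingTrendFit(
        traces=traces,
        pooled=pooled,
        intercept=PosteriorSummary(
            s0.mean, s0.ci_low, s0.ci_high, s0.n_draws, rhat=float(rhat_vals[0])
        ),
        slope=PosteriorSummary(
            s1.mean, s1.ci_low, s1.ci_high, s1.n_draws, rhat=float(rhat_vals[1])
        ),
        rhat={"g0": float(rhat_vals[0]), "g1": float(rhat_vals[1])},
        n_observations=len(obs),
    )
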