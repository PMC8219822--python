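"""Zero-one-inflated beta (ZOIB) regression of female proportion on year.

The response is the per-study female proportion ``y = n/N``, which is
exactly 0 for men-only studies and exactly 1 for women-only studies. The
ZOIB mixture handles the point masses explicitly:

    P(y = 0)              = p_t
    P(y = 1 | y != 0)     = q_t                     (conditional form)
    y | 0 < y < 1         ~ Beta(mu_t * phi, (1 - mu_t) * phi)

with each of p, q, mu tied to the year index t through its own
intercept/slope pair on the logit scale, and a single precision phi
shared across years. The joint probability of an exact one is
``(1 - p_t) * q_t`` and is exposed for reporting. Coefficients carry
normal(mean 0, precision 0.001) priors; phi carries a diffuse
gamma(0.01, 0.01) prior and is sampled on the log scale with the
Jacobian included.

Exact zeros and ones arise from the construction of n/N, so inflation is
exact: a y within 1e-12 of an endpoint but not equal to it belongs to
the continuous component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betaln, expit, gammaln, log_expit

from .data_model import DEFAULT_WINDOW, ProportionObservation, YearWindow
from .mcmc import MCMCConfig, PosteriorSummary, convergence, run_chains, summarize, thin_and_pool

#: serialization order of the sampled parameter vector
PARAM_NAMES = ("b0", "b1", "a0", "a1", "c0", "c1", "log_phi")

#: coordinate blocks proposed together by the sampler: the zero-inflation
#: pair, the beta-mean pair, the one-inflation pair, and the log-precision
BLOCKS = ((0, 1), (2, 3), (4, 5), (6,))


@dataclass(frozen=True)
class ZOIBParameters:
    """Three intercept/slope pairs (logit scale) plus the beta precision.

    ``b`` governs the probability of an exact zero (men-only study),
    ``c`` the conditional probability of an exact one (women-only given
    not men-only), and ``a`` the mean of the beta component (female share
    within mixed studies).
    """

    b0: float
    b1: float
    a0: float
    a1: float
    c0: float
    c1: float
    phi: float

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError("beta precision phi must be strictly positive")
        for name in ("b0", "b1", "a0", "a1", "c0", "c1"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"coefficient {name} must be finite")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.b0, self.b1, self.a0, self.a1, self.c0, self.c1, math.log(self.phi)]
        )

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ZOIBParameters":
        b0, b1, a0, a1, c0, c1, log_phi = np.asarray(v, dtype=float)
        return cls(b0, b1, a0, a1, c0, c1, math.exp(log_phi))

    def to_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.to_vector().tolist()))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ZOIBParameters":
        return cls.from_vector([d[k] for k in PARAM_NAMES])


@dataclass(frozen=True)
class PriorSpec:
    """Priors: normal(mean, 1/precision) on coefficients, gamma on phi."""

    coef_mean: float = 0.0
    coef_precision: float = 0.001
    shape_a: float = 0.01
    shape_b: float = 0.01

    def __post_init__(self) -> None:
        if self.coef_precision <= 0 or self.shape_a <= 0 or self.shape_b <= 0:
            raise ValueError("prior precision and gamma hyperparameters must be positive")


DEFAULT_PRIORS = PriorSpec()


def component_values(params: ZOIBParameters, t) -> tuple:
    """(p, q, mu) at year index t: inverse-logit of the three linear predictors."""
    t = np.asarray(t, dtype=float)
    p = expit(params.b0 + params.b1 * t)
    q = expit(params.c0 + params.c1 * t)
    mu = expit(params.a0 + params.a1 * t)
    if t.ndim == 0:
        return float(p), float(q), float(mu)
    return p, q, mu


def zoib_logdensity(y: float, p: float, q: float, mu: float, phi: float) -> float:
    """Log density/mass of one observation under the ZOIB mixture.

    Point masses at the endpoints: log p at y = 0 and log((1-p) q) at
    y = 1; in the interior, log((1-p)(1-q)) plus the mean-precision beta
    log density Beta(y; mu*phi, (1-mu)*phi).
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError(f"proportion {y} outside [0, 1]")
    if y == 0.0:
        return math.log(p)
    if y == 1.0:
        return math.log1p(-p) + math.log(q)
    a, b = mu * phi, (1.0 - mu) * phi
    beta_logpdf = (a - 1.0) * math.log(y) + (b - 1.0) * math.log1p(-y) - betaln(a, b)
    return math.log1p(-p) + math.log1p(-q) + beta_logpdf


def pack_observations(observations: Sequence[ProportionObservation]) -> tuple[np.ndarray, np.ndarray]:
    """Year-index and proportion arrays from a sequence of observations."""
    t = np.array([o.t for o in observations], dtype=float)
    y = np.array([o.y for o in observations], dtype=float)
    return t, y


def _loglik_arrays(v: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    """Vectorized ZOIB log likelihood for the sampled vector (…, log_phi)."""
    b0, b1, a0, a1, c0, c1, log_phi = v
    phi = np.exp(log_phi)
    eta_p = b0 + b1 * t
    eta_q = c0 + c1 * t
    zero = y == 0.0
    one = y == 1.0
    mid = ~zero & ~one
    total = float(np.sum(log_expit(eta_p[zero])))
    total += float(np.sum(log_expit(-eta_p[one]) + log_expit(eta_q[one])))
    if np.any(mid):
        mu = expit(a0 + a1 * t[mid])
        a, b = mu * phi, (1.0 - mu) * phi
        ym = y[mid]
        beta_term = (a - 1.0) * np.log(ym) + (b - 1.0) * np.log1p(-ym) - betaln(a, b)
        total += float(
            np.sum(log_expit(-eta_p[mid]) + log_expit(-eta_q[mid]) + beta_term)
        )
    return total


def log_likelihood(params: ZOIBParameters, observations: Sequence[ProportionObservation]) -> float:
    """Sum of per-observation ZOIB log densities; 0 for an empty data set."""
    if len(observations) == 0:
        return 0.0
    t, y = pack_observations(observations)
    return _loglik_arrays(params.to_vector(), t, y)


class _SuffStats:
    """Per-year sufficient statistics of the ZOIB likelihood.

    The likelihood depends on the data only through, per distinct year
    index: the counts of exact zeros, exact ones, and interior values,
    and the interior sums of log y and log(1−y). Collapsing to these
    makes each likelihood evaluation O(#years) instead of O(#studies);
    the result is exactly equal to the observation-wise sum.
    """

    def __init__(self, t: np.ndarray, y: np.ndarray) -> None:
        self.t_grid = np.unique(t)
        zero, one = y == 0.0, y == 1.0
        mid = ~zero & ~one
        self.n0 = np.array([np.sum(zero & (t == u)) for u in self.t_grid], dtype=float)
        self.n1 = np.array([np.sum(one & (t == u)) for u in self.t_grid], dtype=float)
        self.nm = np.array([np.sum(mid & (t == u)) for u in self.t_grid], dtype=float)
        self.s_logy = np.array(
            [np.sum(np.log(y[mid & (t == u)])) for u in self.t_grid]
        )
        self.s_log1my = np.array(
            [np.sum(np.log1p(-y[mid & (t == u)])) for u in self.t_grid]
        )

    def loglik(self, v: np.ndarray) -> float:
        b0, b1, a0, a1, c0, c1, log_phi = v
        phi = np.exp(log_phi)
        eta_p = b0 + b1 * self.t_grid
        eta_q = c0 + c1 * self.t_grid
        mu = expit(a0 + a1 * self.t_grid)
        a, b = mu * phi, (1.0 - mu) * phi
        total = float(np.sum(self.n0 * log_expit(eta_p)))
        not_zero = self.n1 + self.nm
        total += float(np.sum(not_zero * log_expit(-eta_p)))
        total += float(np.sum(self.n1 * log_expit(eta_q) + self.nm * log_expit(-eta_q)))
        has_mid = self.nm > 0  # betaln may overflow for extreme mu; 0 * inf guards
        if np.any(has_mid):
            total += float(
                np.sum(
                    (a[has_mid] - 1.0) * self.s_logy[has_mid]
                    + (b[has_mid] - 1.0) * self.s_log1my[has_mid]
                    - self.nm[has_mid] * betaln(a[has_mid], b[has_mid])
                )
            )
        return total


def log_prior(params: ZOIBParameters, priors: PriorSpec = DEFAULT_PRIORS) -> float:
    """Log prior density of the parameters (phi on its natural scale)."""
    tau, m = priors.coef_precision, priors.coef_mean
    coeffs = np.array([params.b0, params.b1, params.a0, params.a1, params.c0, params.c1])
    norm_terms = 0.5 * np.log(tau / (2.0 * np.pi)) - 0.5 * tau * (coeffs - m) ** 2
    a, b = priors.shape_a, priors.shape_b
    gamma_term = a * math.log(b) - gammaln(a) + (a - 1.0) * math.log(params.phi) - b * params.phi
    return float(np.sum(norm_terms) + gamma_term)


def marginal_expected_proportion(params: ZOIBParameters, t) -> float:
    """E[Y | t] under the mixture: (1−p)q + (1−p)(1−q)·mu."""
    p, q, mu = component_values(params, t)
    return (1.0 - p) * q + (1.0 - p) * (1.0 - q) * mu


def annual_change(params: ZOIBParameters, n_years: int = DEFAULT_WINDOW.n_years) -> float:
    """Average per-year change of E[Y | t] across the window.

    Equals (E[Y | t_max] − E[Y | 0]) / t_max, i.e. the mean of the
    successive yearly differences; multiply by 100 for percentage points.
    """
    if n_years < 2:
        raise ValueError("annual change needs a window of at least two years")
    t_max = n_years - 1
    return (
        marginal_expected_proportion(params, t_max) - marginal_expected_proportion(params, 0)
    ) / t_max


# ---------------------------------------------------------------------------
# posterior fitting


@dataclass(frozen=True)
class ZOIBFit:
    """Posterior fit bundle: traces, summaries, and derived quantities."""

    traces: np.ndarray  # (chains, retained draws, 7), unthinned
    pooled: np.ndarray  # thinned and pooled draws, (n, 7)
    params: dict[str, PosteriorSummary]  # b0,b1,a0,a1,c0,c1,phi
    proportion_by_year: dict[int, PosteriorSummary]  # calendar year -> E[Y|t]
    annual_change: PosteriorSummary
    rhat: dict[str, float]
    config: MCMCConfig

    def summary_dict(self) -> dict:
        return {
            "parameters": {k: v.as_dict() for k, v in self.params.items()},
            "proportion_by_year": {
                str(year): s.as_dict() for year, s in self.proportion_by_year.items()
            },
            "annual_change": self.annual_change.as_dict(),
            "rhat": self.rhat,
        }


def _pooled_marginal(pooled: np.ndarray, t: float) -> np.ndarray:
    p = expit(pooled[:, 0] + pooled[:, 1] * t)
    q = expit(pooled[:, 4] + pooled[:, 5] * t)
    mu = expit(pooled[:, 2] + pooled[:, 3] * t)
    return (1.0 - p) * q + (1.0 - p) * (1.0 - q) * mu


def fit_zoib(
    observations: Sequence[ProportionObservation],
    config: MCMCConfig,
    priors: PriorSpec = DEFAULT_PRIORS,
    window: YearWindow = DEFAULT_WINDOW,
    init: np.ndarray | None = None,
) -> ZOIBFit:
    """Posterior inference for the ZOIB regression via blockwise Metropolis.

    The sampled vector is (b0, b1, a0, a1, c0, c1, log phi); the log
    target adds the log-scale Jacobian for phi. Initialization is all
    coefficients at 0 and log phi at 0 unless ``init`` is given.
    """
    if len(observations) == 0:
        raise ValueError("cannot fit a ZOIB model to an empty data set")
    t_arr, y_arr = pack_observations(observations)
    stats = _SuffStats(t_arr, y_arr)
    tau, m = priors.coef_precision, priors.coef_mean
    a_sh, b_sh = priors.shape_a, priors.shape_b

    def log_target(v: np.ndarray) -> float:
        log_phi = v[6]
        if abs(log_phi) > 50.0:  # keep exp() finite; far outside any posterior mass
            return -np.inf
        ll = stats.loglik(v)
        lp = -0.5 * tau * float(np.sum((v[:6] - m) ** 2))
        # gamma prior on phi plus d(phi)/d(log phi) Jacobian
        lp += a_sh * log_phi - b_sh * math.exp(log_phi)
        return ll + lp

    if init is None:
        init = np.zeros(7)
    traces = run_chains(log_target, init, config, blocks=BLOCKS)
    pooled = thin_and_pool(traces, config.thin)
    rhat_vals = convergence(traces) if config.n_chains >= 2 else np.full(7, np.nan)

    params: dict[str, PosteriorSummary] = {}
    for j, name in enumerate(PARAM_NAMES[:6]):
        s = summarize(pooled[:, j])
        params[name] = PosteriorSummary(
            s.mean, s.ci_low, s.ci_high, s.n_draws, rhat=float(rhat_vals[j])
        )
    phi_draws = np.exp(pooled[:, 6])
    s = summarize(phi_draws)
    params["phi"] = PosteriorSummary(
        s.mean, s.ci_low, s.ci_high, s.n_draws, rhat=float(rhat_vals[6])
    )

    proportion_by_year: dict[int, PosteriorSummary] = {}
    marg = {}
    for t in range(window.n_years):
        vals = _pooled_marginal(pooled, float(t))
        marg[t] = vals
        proportion_by_year[window.start + t] = summarize(vals)
    t_max = window.n_years - 1
    change = summarize((marg[t_max] - marg[0]) / t_max)

    return ZOIBFit(
        traces=traces,
        pooled=pooled,
        params=params,
        proportion_by_year=proportion_by_year,
        annual_change=change,
        rhat=dict(zip(PARAM_NAMES, (float(r) for r in rhat_vals))),
        config=config,
    )
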