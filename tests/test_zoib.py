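"""ZOIB density, likelihood, priors, and derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from thermorep import (
    PriorSpec,
    ProportionObservation,
    ZOIBParameters,
    annual_change,
    component_values,
    log_likelihood,
    log_prior,
    marginal_expected_proportion,
    zoib_logdensity,
)
from thermorep.zoib import _SuffStats, pack_observations

FLAT = ZOIBParameters(0, 0, 0, 0, 0, 0, phi=2.0)


def _params(**kw):
    base = dict(b0=0.0, b1=0.0, a0=0.0, a1=0.0, c0=0.0, c1=0.0, phi=2.0)
    base.update(kw)
    return ZOIBParameters(**base)


class TestComponentValues:
    def test_zero_coefficients_give_half(self):
        assert component_values(FLAT, 3) == (0.5, 0.5, 0.5)

    def test_log_odds_three_gives_three_quarters(self):
        p, _, _ = component_values(_params(b0=math.log(3)), 4)
        assert p == pytest.approx(0.75)

    def test_numeric_inverse_logit(self):
        _, _, mu = component_values(_params(a0=-1.6094, a1=0.1), 0)
        assert mu == pytest.approx(1 / (1 + math.exp(1.6094)), abs=1e-9)


class TestLogDensity:
    def test_point_masses(self):
        assert zoib_logdensity(0.0, 0.3, 0.5, 0.5, 2.0) == pytest.approx(math.log(0.3))
        assert zoib_logdensity(1.0, 0.2, 0.5, 0.5, 2.0) == pytest.approx(math.log(0.4))

    def test_uniform_beta_case(self):
        # mu=0.5, phi=2 is Beta(1,1): density 1, so mass (1-p)(1-q) = 0.5625
        val = zoib_logdensity(0.5, 0.25, 0.25, 0.5, 2.0)
        assert val == pytest.approx(math.log(0.5625))

    def test_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            zoib_logdensity(1.2, 0.3, 0.3, 0.5, 2.0)

    @pytest.mark.parametrize("p,q,mu,phi", [
        (0.3, 0.2, 0.4, 2.0), (0.7, 0.5, 0.2, 8.0), (0.05, 0.9, 0.6, 0.7), (0.5, 0.5, 0.5, 30.0),
    ])
    def test_normalization_to_one(self, p, q, mu, phi):
        """Point masses plus the continuous integral sum to 1 within 1e-6."""
        cont, _ = quad(
            lambda y: math.exp(zoib_logdensity(y, p, q, mu, phi)), 0, 1,
            points=[0.0, 1.0], limit=200,
        )
        total = p + (1 - p) * q + cont
        assert total == pytest.approx(1.0, abs=1e-6)


class TestLogLikelihood:
    def test_empty_data_gives_zero(self):
        assert log_likelihood(FLAT, []) == 0.0

    def test_single_zero_at_origin(self):
        obs = [ProportionObservation(t=0, y=0.0, N=10)]
        assert log_likelihood(FLAT, obs) == pytest.approx(math.log(0.5))

    def test_matches_term_by_term_oracle(self):
        """Vectorized likelihood equals an independent per-observation sum
        using scipy's beta density directly."""
        rng = np.random.default_rng(8)
        params = _params(b0=0.8, b1=-0.05, a0=-0.4, a1=0.02, c0=-1.5, c1=0.01, phi=4.0)
        obs = []
        for _ in range(50):
            t = int(rng.integers(0, 10))
            u = rng.uniform()
            y = 0.0 if u < 0.4 else (1.0 if u < 0.5 else float(rng.uniform(0.01, 0.99)))
            obs.append(ProportionObservation(t=t, y=y, N=10))
        expected = 0.0
        for o in obs:
            p, q, mu = component_values(params, o.t)
            if o.y == 0.0:
                expected += math.log(p)
            elif o.y == 1.0:
                expected += math.log((1 - p) * q)
            else:
                expected += math.log(
                    (1 - p) * (1 - q)
                    * stats.beta.pdf(o.y, mu * params.phi, (1 - mu) * params.phi)
                )
        assert log_likelihood(params, obs) == pytest.approx(expected, rel=1e-10)
        t_arr, y_arr = pack_observations(obs)
        assert _SuffStats(t_arr, y_arr).loglik(params.to_vector()) == pytest.approx(
            expected, rel=1e-10
        )

    def test_invariant_to_observation_order(self):
        obs = [
            ProportionObservation(t=t, y=y, N=10)
            for t, y in [(0, 0.0), (3, 1.0), (5, 0.4), (9, 0.2)]
        ]
        assert log_likelihood(FLAT, obs) == pytest.approx(log_likelihood(FLAT, obs[::-1]))


class TestLogPrior:
    def test_coefficient_shift_matches_closed_form_normal_ratio(self):
        # precision 0.001: moving one coefficient 0 -> 10 costs 0.5*0.001*100
        delta = log_prior(_params(b0=10.0)) - log_prior(_params())
        assert delta == pytest.approx(-0.05)

    def test_phi_prior_mode(self):
        # gamma(0.01, 0.01) is monotone decreasing: smaller phi, higher prior
        priors = PriorSpec()
        assert log_prior(_params(phi=0.5), priors) > log_prior(_params(phi=5.0), priors)


class TestMarginalExpectedProportion:
    def test_degenerate_mixtures(self):
        all_zero = _params(b0=50.0)  # p ~ 1
        assert marginal_expected_proportion(all_zero, 0) == pytest.approx(0.0, abs=1e-12)
        all_one = _params(b0=-50.0, c0=50.0)  # p ~ 0, q ~ 1
        assert marginal_expected_proportion(all_one, 0) == pytest.approx(1.0, abs=1e-12)

    def test_against_monte_carlo_mixture(self):
        """Closed-form mean matches 1e6 draws from the mixture within 3 SE."""
        p, q, mu, phi = 0.6, 0.1, 0.3, 2.0
        params = _params(
            b0=float(np.log(p / (1 - p))),
            c0=float(np.log(q / (1 - q))),
            a0=float(np.log(mu / (1 - mu))),
            phi=phi,
        )
        expected = 0.4 * 0.1 + 0.4 * 0.9 * 0.3  # 0.148
        assert marginal_expected_proportion(params, 0) == pytest.approx(expected, abs=1e-9)
        rng = np.random.default_rng(3)
        n = 1_000_000
        u = rng.uniform(size=n)
        draws = np.where(
            u < p, 0.0, np.where(rng.uniform(size=n) < q, 1.0, rng.beta(mu * phi, (1 - mu) * phi, n))
        )
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - marginal_expected_proportion(params, 0)) < 3 * se

    @settings(max_examples=40, deadline=None)
    @given(
        st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2), st.floats(0.1, 1.0)
    )
    def test_monotone_in_components(self, b0, c0, a0, eps):
        """E[Y] rises with mu and q and falls with p, others held fixed."""
        base = _params(b0=b0, c0=c0, a0=a0)
        up_mu = _params(b0=b0, c0=c0, a0=a0 + eps)
        up_q = _params(b0=b0, c0=c0 + eps, a0=a0)
        up_p = _params(b0=b0 + eps, c0=c0, a0=a0)
        m = marginal_expected_proportion
        assert m(up_mu, 0) > m(base, 0)
        assert m(up_q, 0) > m(base, 0)
        assert m(up_p, 0) < m(base, 0)


class TestAnnualChange:
    def test_flat_model_has_zero_change(self):
        assert annual_change(FLAT) == 0.0

    def test_single_year_window_errors(self):
        with pytest.raises(ValueError):
            annual_change(FLAT, n_years=1)

    def test_equals_mean_of_successive_yearly_differences(self):
        params = _params(b0=1.0, b1=-0.07, a0=-0.5, a1=0.02, c0=-1.5, c1=-0.01)
        diffs = [
            marginal_expected_proportion(params, t + 1) - marginal_expected_proportion(params, t)
            for t in range(9)
        ]
        assert annual_change(params, 10) == pytest.approx(float(np.mean(diffs)))


def test_parameter_vector_roundtrip():
    params = _params(b0=1.2, b1=-0.07, a0=-0.9, a1=0.01, c0=-2.8, phi=5.0)
    for restored in (
        ZOIBParameters.from_vector(params.to_vector()),
        ZOIBParameters.from_dict(params.to_dict()),
    ):
        # phi round-trips through log space, so equality is to float precision
        assert restored.to_vector() == pytest.approx(params.to_vector(), rel=1e-12)


def test_nonpositive_phi_rejected():
    with pytest.raises(ValueError):
        _params(phi=0.0)
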