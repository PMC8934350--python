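"""Closed-form risk machinery: time scales, escape formulas, ERS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from levyrisk import (
    ModelParams,
    RiskPrediction,
    brownian_density_param,
    brownian_escape_log_probability,
    brownian_predictor,
    ers_band,
    ers_score,
    levy_predictor,
    levy_risk,
    levy_tail_probability,
    log_erfc,
    log_erfc_asymptotic,
    minimal_walk_length,
    t0_generations,
    total_generations,
)

COAD_T = math.log2(2e8) + 73 * 80  # 5867.58 stem-cell generations


def log_erfc_quadrature(z: float) -> float:
    """Independent oracle: ln Erfc(z) = -z^2 + ln(2/sqrt(pi)) + ln I(z),
    I(z) = int_0^inf exp(-s^2 - 2 z s) ds, a well-scaled integral."""
    val, _ = quad(lambda s: math.exp(-s * s - 2 * z * s), 0, np.inf)
    return -z * z + math.log(2 / math.sqrt(math.pi)) + math.log(val)


class TestTimeScales:
    def test_t0_continuous_values(self):
        assert t0_generations(2e8) == pytest.approx(27.575, abs=1e-3)
        assert int(t0_generations(2e8)) == 27
        assert round(t0_generations(1.22e9)) == 30
        assert t0_generations(2) == 1.0

    def test_t0_rejects_fractional_cell(self):
        with pytest.raises(ValueError):
            t0_generations(0.5)

    def test_total_generations(self):
        # lung: huge tissue but slow turnover -> development dominates
        assert 1.22e9 * 0 == 0
        assert total_generations(1.22e9, 0.07, 80) == pytest.approx(30.18 + 5.6, abs=0.01)
        assert total_generations(2e8, 73, 80) == pytest.approx(5867.58, abs=0.01)
        assert total_generations(2e8, 73, 0) == t0_generations(2e8)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            total_generations(1e8, 1.0, -1.0)


class TestMinimalWalkLength:
    @pytest.mark.parametrize(
        "xbar1, rn, rt, expected",
        [(155.89, 11.71, 28.53, 115.65), (137.37, 20.97, 31.66, 84.74), (100, 0, 0, 100)],
    )
    def test_values(self, xbar1, rn, rt, expected):
        assert minimal_walk_length(xbar1, rn, rt) == pytest.approx(expected, abs=1e-9)

    def test_overlapping_clouds_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            minimal_walk_length(10.0, 6.0, 6.0)


class TestBrownianFormulas:
    def test_density_param(self):
        assert brownian_density_param(1.0, 2.0) == 1.0
        assert brownian_density_param(0.0526, COAD_T) == pytest.approx(0.1232, abs=2e-4)

    @given(d=st.floats(0.01, 10), t=st.floats(0.1, 1e4))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_density_param_identity(self, d, t):
        assert brownian_density_param(d, t) * d * d * t == pytest.approx(2.0)

    def test_zero_walk_gives_certain_escape(self):
        assert brownian_escape_log_probability(1.0, 0.0, 1.0) == pytest.approx(0.0)

    def test_log_erfc_matches_quadrature(self):
        for z in [0.0, 0.5, 1.0, 3.0, 5.0, 10.0, 20.0, 30.0]:
            expected = log_erfc_quadrature(z)
            got = float(log_erfc(z))
            assert got == pytest.approx(expected, rel=1e-8, abs=1e-10)

    def test_asymptotic_form_agrees_at_moderate_z(self):
        # leading-order tail approximation within 2% at z = 5
        assert float(log_erfc(5.0)) == pytest.approx(
            float(log_erfc_asymptotic(5.0)), rel=0.02
        )

    def test_deep_underflow_regime_stays_finite(self):
        # COAD: z ~ 40.6, Erfc far below the smallest double
        lp = float(brownian_escape_log_probability(0.0526, 115.65, COAD_T))
        z = math.sqrt(2 / COAD_T) * 115.65 / 0.0526
        assert z == pytest.approx(40.6, abs=0.1)
        assert np.isfinite(lp)
        assert lp == pytest.approx(-z * z, rel=0.01)

    def test_escape_probability_monotone(self):
        # increasing in t and D, decreasing in R, always in (0, 1]
        ts = np.array([10.0, 100.0, 1000.0])
        lp_t = [float(brownian_escape_log_probability(0.05, 10.0, t)) for t in ts]
        assert lp_t == sorted(lp_t)
        lp_d = [float(brownian_escape_log_probability(d, 10.0, 100.0)) for d in (0.05, 0.1, 0.5)]
        assert lp_d == sorted(lp_d)
        lp_r = [float(brownian_escape_log_probability(0.05, r, 100.0)) for r in (5.0, 10.0, 20.0)]
        assert lp_r == sorted(lp_r, reverse=True)
        assert all(lp <= 0 for lp in lp_t + lp_d + lp_r)

    def test_predictor_values(self):
        assert brownian_predictor(1.0, 2.0, 4.0) == pytest.approx(-2.0)  # D*sqrt(t) = R
        assert float(brownian_predictor(0.0526, 115.65, COAD_T)) == pytest.approx(
            -1651.1, abs=0.5
        )

    def test_predictor_monotone_in_time(self):
        vals = brownian_predictor(0.05, 100.0, np.array([10.0, 100.0, 1000.0]))
        assert np.all(np.diff(vals) > 0)


class TestLevyFormulas:
    def test_tail_probability(self):
        assert levy_tail_probability(1.0, 1.0, nu=2.0) == 1.0
        assert levy_tail_probability(0.0526, 115.65, nu=2.0) == pytest.approx(
            4.548e-4, rel=1e-3
        )
        assert levy_tail_probability(0.1, 1.0, nu=3.0) == pytest.approx(0.01)

    @given(d=st.floats(0.01, 1.0), ratio=st.floats(1.0, 1e4))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_tail_probability_is_d_over_r_at_nu_two(self, d, ratio):
        assert levy_tail_probability(d, d * ratio, nu=2.0) == pytest.approx(1 / ratio)

    def test_tail_exponent_must_exceed_one(self):
        with pytest.raises(ValueError, match="nu"):
            levy_tail_probability(0.05, 100.0, nu=1.0)

    def test_predictor_values(self):
        assert levy_predictor(1.0, 5.0, 5.0) == pytest.approx(0.0)  # D*t = R
        assert float(levy_predictor(0.0526, 115.65, COAD_T)) == pytest.approx(0.98, abs=0.01)
        t_luad = total_generations(1.22e9, 0.07, 80)
        assert float(levy_predictor(0.0581, 99.75, t_luad)) == pytest.approx(-3.87, abs=0.01)

    @given(scale=st.floats(0.1, 100.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_predictors_invariant_under_common_rescaling(self, scale):
        """D and R carry the same units; both predictors are unit-free."""
        base_l = levy_predictor(0.05, 100.0, 500.0)
        base_b = brownian_predictor(0.05, 100.0, 500.0)
        assert levy_predictor(0.05 * scale, 100.0 * scale, 500.0) == pytest.approx(base_l)
        assert brownian_predictor(0.05 * scale, 100.0 * scale, 500.0) == pytest.approx(base_b)


class TestLevyRisk:
    def params(self, mu):
        return ModelParams(d_scale=0.05, r_walk=100.0, n_sc=1e8, m_sc=10.0, mu=mu)

    def test_zero_rate_zero_risk(self):
        assert levy_risk(self.params(0.0)) == 0.0

    def test_doubling_walk_length_halves_risk(self):
        r1 = levy_risk(self.params(1e-18))
        p2 = ModelParams(d_scale=0.05, r_walk=200.0, n_sc=1e8, m_sc=10.0, mu=1e-18)
        assert levy_risk(p2) == pytest.approx(r1 / 2)

    def test_missing_rate_instructs_caller(self):
        with pytest.raises(ValueError, match="mu"):
            levy_risk(self.params(None))

    def test_clamped_at_one_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert levy_risk(self.params(1.0)) == 1.0

    def test_ers_consistency_with_levy_risk(self):
        """mu' chosen so risk/N_sc = a_ref * t gives ERS = 1 by definition."""
        p = self.params(0.0)
        t = p.t_total
        mu = p.a_ref * t / ((p.d_scale / p.r_walk) * t)
        risk = levy_risk(self.params(mu))
        assert ers_score(risk, p.n_sc, p.m_sc) == pytest.approx(1.0)

    def test_tail_ratio_warning(self):
        with pytest.warns(UserWarning, match="dubious"):
            ModelParams(d_scale=10.0, r_walk=50.0, n_sc=1e8, m_sc=1.0)


class TestExtraRiskScore:
    def test_coad_value_in_normal_band(self):
        score = ers_score(0.04264, 2e8, 73.0)
        assert score == pytest.approx(1.82, abs=0.01)
        assert ers_band(score) == "normal"

    @given(factor=st.floats(0.1, 10.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_linear_in_risk(self, factor):
        base = ers_score(0.01, 1e8, 10.0)
        assert ers_score(0.01 * factor, 1e8, 10.0) == pytest.approx(base * factor, rel=1e-9)

    def test_band_stable_under_registry_dispersion(self, complete_table):
        """Perturbing risk by +-dev moves no tissue across a band edge,
        except tissues already sitting near an edge."""
        for rec in complete_table:
            mid = ers_score(rec.risk, rec.n_sc, rec.m_sc)
            lo = ers_score(max(rec.risk - rec.dev, 1e-12), rec.n_sc, rec.m_sc)
            hi = ers_score(min(rec.risk + rec.dev, 1 - 1e-12), rec.n_sc, rec.m_sc)
            near_edge = any(
                abs(mid - edge) / edge < max(rec.dev / rec.risk, 0.5)
                for edge in (1.0, 6.0)
            )
            if not near_edge:
                assert ers_band(lo) == ers_band(mid) == ers_band(hi)

    def test_rejects_invalid_risk(self):
        with pytest.raises(ValueError):
            ers_score(0.0, 1e8, 10.0)


def test_risk_prediction_requires_negative_response():
    with pytest.raises(ValueError, match="negative"):
        RiskPrediction(tissue="X", predictor=0.0, response=0.5, model="levy")
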