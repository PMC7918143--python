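"""Unit tests for the in vitro release model and the gamma calibration."""

import math

import numpy as np
import pytest

from ivring.release import (
    GammaDoseModel,
    InVitroReleaseParams,
    apply_inhibition,
    eval_cumulative_vitro,
    eval_cumulative_vivo,
    eval_rate_vitro,
    fit_gamma_polynomial,
    fit_vitro,
    higuchi_rate,
    solve_gamma,
)

from .conftest import DOSES, quadratic_ols_oracle


class TestInVitroReleaseParams:
    def test_b_is_mass_balance(self, vitro_params):
        for dose, p in vitro_params.items():
            assert p.P0 + p.A + p.B == pytest.approx(dose, abs=1e-9)

    def test_negative_fields_rejected(self):
        with pytest.raises(ValueError):
            InVitroReleaseParams(dose=125, P0=-1.0, A=26.1, alpha=0.08, beta=0.01)

    def test_p0_plus_a_exceeding_dose_rejected(self):
        with pytest.raises(ValueError):
            InVitroReleaseParams(dose=100, P0=60.0, A=50.0, alpha=0.08, beta=0.01)

    def test_alpha_must_exceed_beta(self):
        with pytest.raises(ValueError):
            InVitroReleaseParams(dose=125, P0=6.0, A=26.0, alpha=0.01, beta=0.08)


class TestEvalCumulativeVitro:
    def test_t0_gives_burst(self, vitro_params):
        for p in vitro_params.values():
            assert eval_cumulative_vitro(p, 0.0) == pytest.approx(p.P0, abs=1e-12)

    def test_infinite_time_gives_dose(self, vitro_params):
        p = vitro_params[125.0]
        assert eval_cumulative_vitro(p, 1e9) == pytest.approx(125.0, rel=1e-9)

    def test_value_at_24h(self, vitro_params):
        # oracle: direct high-precision evaluation of the curve
        p = vitro_params[125.0]
        expected = (
            p.P0
            + p.A * (1.0 - math.exp(-p.alpha * 24.0))
            + p.B * (1.0 - math.exp(-p.beta * 24.0))
        )
        assert expected == pytest.approx(54.0, abs=0.5)  # sanity on the oracle itself
        assert eval_cumulative_vitro(p, 24.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_nondecreasing(self, vitro_params):
        t = np.linspace(0.0, 500.0, 400)
        for p in vitro_params.values():
            y = eval_cumulative_vitro(p, t)
            assert np.all(np.diff(y) >= 0)
            assert np.all(y >= p.P0 - 1e-12)
            assert np.all(y <= p.dose + 1e-12)

    def test_negative_time_rejected(self, vitro_params):
        with pytest.raises(ValueError):
            eval_cumulative_vitro(vitro_params[125.0], -1.0)


class TestEvalRateVitro:
    def test_matches_finite_difference(self, vitro_params):
        # oracle: central finite difference of the cumulative curve
        p = vitro_params[125.0]
        h = 1e-4
        for t in (1.0, 24.0, 200.0):
            fd = (eval_cumulative_vitro(p, t + h) - eval_cumulative_vitro(p, t - h)) / (2 * h)
            assert eval_rate_vitro(p, t) == pytest.approx(fd, rel=1e-6)

    def test_decays_to_zero(self, vitro_params):
        assert eval_rate_vitro(vitro_params[125.0], 1e7) == pytest.approx(0.0, abs=1e-12)

    def test_zero_amplitudes_give_zero_rate(self):
        p = InVitroReleaseParams(dose=10.0, P0=10.0, A=0.0, alpha=0.08, beta=0.01)
        assert eval_rate_vitro(p, 5.0) == 0.0

    def test_nonpositive_time_rejected(self, vitro_params):
        with pytest.raises(ValueError):
            eval_rate_vitro(vitro_params[125.0], 0.0)


class TestApplyInhibition:
    def test_gamma_zero_identity(self, vitro_params):
        p = vitro_params[125.0]
        v = apply_inhibition(p, 0.0)
        t = np.linspace(0, 408, 50)
        np.testing.assert_allclose(
            eval_cumulative_vivo(v, t), eval_cumulative_vitro(p, t), atol=1e-12
        )

    def test_rates_divided(self, vitro_params):
        p = vitro_params[125.0]
        v = apply_inhibition(p, 5.437)
        assert v.alpha_vivo == pytest.approx(0.0843 / 6.437, rel=1e-12)
        assert v.beta_vivo == pytest.approx(0.013 / 6.437, rel=1e-12)
        assert (v.P0, v.A, v.B) == (p.P0, p.A, p.B)

    def test_large_gamma_tends_to_burst(self, vitro_params):
        p = vitro_params[125.0]
        v = apply_inhibition(p, 1e12)
        assert eval_cumulative_vivo(v, 408.0) == pytest.approx(p.P0, rel=1e-6)

    def test_negative_gamma_rejected(self, vitro_params):
        with pytest.raises(ValueError):
            apply_inhibition(vitro_params[125.0], -0.1)


class TestSolveGamma:
    def test_no_inhibition_boundary(self, vitro_params):
        p = vitro_params[125.0]
        res = solve_gamma(p, eval_cumulative_vitro(p, 408.0))
        assert res.gamma == 0.0
        assert res.boundary

    def test_amount_below_burst_rejected(self, vitro_params):
        p = vitro_params[125.0]
        with pytest.raises(ValueError):
            solve_gamma(p, p.P0 * 0.5)

    def test_round_trip_identity(self, vitro_params):
        # forward-evaluate at a known gamma, then solve back
        for p in vitro_params.values():
            for g in (0.5, 5.0, 80.0, 200.0):
                amount = eval_cumulative_vivo(apply_inhibition(p, g), 408.0)
                back = solve_gamma(p, amount).gamma
                assert back == pytest.approx(g, rel=1e-6)

    def test_residual_reported(self, vitro_params):
        res = solve_gamma(vitro_params[125.0], 84.40)
        assert abs(res.residual_mg) <= 1e-8


class TestFitVitro:
    def test_noise_free_recovery(self, vitro_params):
        p = vitro_params[375.0]
        t = np.concatenate([[1, 2, 4, 6, 7, 8], np.arange(24.0, 361.0, 24.0)])
        y = eval_cumulative_vitro(p, t)
        fit = fit_vitro([(t, y)], dose=375.0)
        q = fit.params
        assert q.P0 == pytest.approx(p.P0, rel=1e-6)
        assert q.A == pytest.approx(p.A, rel=1e-6)
        assert q.alpha == pytest.approx(p.alpha, rel=1e-6)
        assert q.beta == pytest.approx(p.beta, rel=1e-6)
        assert q.P0 + q.A + q.B == pytest.approx(375.0, abs=1e-9)

    def test_noisy_recovery_monte_carlo(self, vitro_params):
        # oracle: Monte-Carlo recovery; median error over seeds within 5%
        p = vitro_params[125.0]
        t = np.concatenate([[1, 2, 4, 6, 7, 8], np.arange(24.0, 361.0, 24.0)])
        errs = {k: [] for k in ("P0", "A", "alpha", "beta")}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            # clip at the charged dose: the fitter's contract rejects
            # physically impossible cumulative values above the dose
            profiles = [
                (t, np.minimum(eval_cumulative_vitro(p, t) + rng.normal(0, 1.13, t.size),
                               125.0))
                for _ in range(12)
            ]
            q = fit_vitro(profiles, dose=125.0).params
            for k in errs:
                errs[k].append(abs(getattr(q, k) / getattr(p, k) - 1.0))
        for k, v in errs.items():
            assert np.median(v) <= 0.05, f"{k}: median rel err {np.median(v):.3f}"

    def test_fix_p0(self, vitro_params):
        p = vitro_params[750.0]
        t = np.arange(24.0, 361.0, 24.0)  # no early samples: P0 not identifiable
        y = eval_cumulative_vitro(p, t)
        fit = fit_vitro([(t, y)], dose=750.0, fix_P0=9.45)
        assert fit.params.P0 == 9.45
        assert fit.fixed["P0"]
        assert "P0" not in fit.standard_errors

    def test_values_above_dose_rejected(self):
        t = np.arange(24.0, 200.0, 24.0)
        with pytest.raises(ValueError):
            fit_vitro([(t, np.full(t.size, 130.0))], dose=125.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_vitro([([24.0, 48.0], [10.0, 20.0])], dose=125.0)


class TestFitGammaPolynomial:
    def test_exact_linear_data(self):
        doses = [100.0, 300.0, 700.0, 1000.0]
        gammas = [1.0 + 0.01 * d for d in doses]
        m = fit_gamma_polynomial(doses, gammas)
        assert m.c0 == pytest.approx(1.0, abs=1e-10)
        assert m.c1 == pytest.approx(0.01, abs=1e-10)
        assert m.c2 == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(50, 2000, size=6)
        g = rng.uniform(1, 100, size=6)
        m = fit_gamma_polynomial(d, g)
        c = quadratic_ols_oracle(d, g)
        assert m.c0 == pytest.approx(c[0], abs=1e-10 * max(1, abs(c[0])))
        assert m.c1 == pytest.approx(c[1], rel=1e-9)
        assert m.c2 == pytest.approx(c[2], rel=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_polynomial([100, 200], [1, 2])

    def test_published_pairs(self, gamma_by_dose):
        m = fit_gamma_polynomial(list(DOSES), [gamma_by_dose[d] for d in DOSES])
        assert m.c0 == pytest.approx(2.116, abs=5e-4)
        assert m.c1 == pytest.approx(0.020, abs=5e-4)
        assert m.c2 == pytest.approx(2e-5, abs=5e-7)


class TestGammaDoseModel:
    def test_negative_prediction_rejected(self):
        m = GammaDoseModel(c0=-10.0, c1=0.001, c2=0.0)
        with pytest.raises(ValueError):
            m.gamma(100.0)

    def test_callable(self, gamma_poly):
        assert gamma_poly(125.0) == gamma_poly.gamma(125.0)


class TestHiguchiRate:
    def test_exact_sqrt_data(self):
        t_h = np.arange(24.0, 361.0, 24.0)
        y = 50.0 * np.sqrt(t_h / 24.0)
        res = higuchi_rate(t_h, y)
        assert res.rate_mg_per_sqrt_day == pytest.approx(50.0, rel=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery(self):
        # oracle: closed-form through-origin OLS slope and its SE
        t_h = np.arange(24.0, 361.0, 24.0)
        x = np.sqrt(t_h / 24.0)
        rng = np.random.default_rng(3)
        y = 50.0 * x + rng.normal(0, 1.0, x.size)
        slope_oracle = float(np.sum(x * y) / np.sum(x * x))
        se = 1.0 / math.sqrt(float(np.sum(x * x)))
        res = higuchi_rate(t_h, y)
        assert res.rate_mg_per_sqrt_day == pytest.approx(slope_oracle, rel=1e-12)
        assert abs(res.rate_mg_per_sqrt_day - 50.0) <= 3 * se

    def test_poor_fit_flagged_by_r2(self):
        t_h = np.arange(24.0, 241.0, 24.0)
        y = np.full(t_h.size, 30.0)  # constant profile: not sqrt-like
        res = higuchi_rate(t_h, y)
        assert res.r_squared < 0.95

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            higuchi_rate([], [])
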