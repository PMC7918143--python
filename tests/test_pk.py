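"""Unit tests for the structural PK solver against independent oracles."""

import numpy as np
import pytest

from ivring.pk import (
    ConcentrationProfile,
    PKParams,
    mass_balance,
    predict_concentration,
    predict_concentration_many,
)
from ivring.release import InVitroReleaseParams, apply_inhibition, eval_cumulative_vivo

from .conftest import bateman_oracle, ode_conc_oracle


class TestPKParams:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            PKParams(kabs_p0=0.0, kabs=0.2, kel=0.02, v_f=3450, k12=0.03, k21=0.03)


class TestConcentrationProfile:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationProfile(times=np.array([0.0, 1.0]), conc=np.array([1.0]))

    def test_descending_times_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationProfile(times=np.array([2.0, 1.0]), conc=np.array([1.0, 2.0]))


class TestPredictConcentration:
    def test_zero_at_t0(self, typical_pk, release_125):
        prof = predict_concentration(typical_pk, release_125, [0.0, 1.0])
        assert prof.conc[0] == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_volume(self, typical_pk, release_125, schedule):
        from dataclasses import replace

        c1 = predict_concentration(typical_pk, release_125, schedule).conc
        c2 = predict_concentration(replace(typical_pk, v_f=2 * typical_pk.v_f),
                                   release_125, schedule).conc
        np.testing.assert_allclose(c2, c1 / 2, rtol=1e-12)

    def test_bateman_limit(self, typical_pk):
        # one-compartment limit: A=B=0, negligible transfer
        p = InVitroReleaseParams(dose=6.62, P0=6.62, A=0.0, alpha=0.0843, beta=0.013)
        release = apply_inhibition(p, 0.0)
        pk = PKParams(kabs_p0=typical_pk.kabs_p0, kabs=typical_pk.kabs,
                      kel=typical_pk.kel, v_f=typical_pk.v_f, k12=1e-12, k21=1e-12)
        times = [1.0, 24.0, 200.0]
        expected = bateman_oracle(6.62, typical_pk.kabs_p0, typical_pk.kel,
                                  typical_pk.v_f, times)
        got = predict_concentration(pk, release, times).conc
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_against_stiff_ode_oracle_typical(self, typical_pk, release_125, schedule):
        expected = ode_conc_oracle(typical_pk, release_125, schedule)
        got = predict_concentration(typical_pk, release_125, schedule).conc
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)

    def test_against_stiff_ode_oracle_random(self):
        # 100 random positive parameter sets
        rng = np.random.default_rng(42)
        times = np.array([0.5, 2.0, 8.0, 24.0, 96.0, 408.0])
        for _ in range(100):
            dose = rng.uniform(50, 2000)
            P0 = rng.uniform(0.01, 0.1) * dose
            A = rng.uniform(0.05, 0.5) * dose
            beta = rng.uniform(1e-4, 5e-3)
            alpha = beta * rng.uniform(2.0, 50.0)
            p = InVitroReleaseParams(dose=dose, P0=P0, A=A, alpha=alpha, beta=beta)
            release = apply_inhibition(p, rng.uniform(0.0, 100.0))
            pk = PKParams(
                kabs_p0=rng.uniform(0.01, 2.0), kabs=rng.uniform(0.01, 1.0),
                kel=rng.uniform(1e-3, 0.2), v_f=rng.uniform(500, 10000),
                k12=rng.uniform(1e-3, 0.5), k21=rng.uniform(1e-3, 0.5),
            )
            expected = ode_conc_oracle(pk, release, times)
            got = predict_concentration(pk, release, times).conc
            np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)

    def test_rate_collision_handled(self, typical_pk, release_125, schedule):
        # force kabs equal to the slow release rate exactly
        pk = PKParams(kabs_p0=typical_pk.kabs_p0, kabs=release_125.beta_vivo,
                      kel=typical_pk.kel, v_f=typical_pk.v_f,
                      k12=typical_pk.k12, k21=typical_pk.k21)
        got = predict_concentration(pk, release_125, schedule).conc
        assert np.all(np.isfinite(got))
        expected = ode_conc_oracle(pk, release_125, schedule)
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)

    def test_superposition_in_amplitudes(self, typical_pk, schedule):
        base = InVitroReleaseParams(dose=125.0, P0=6.62, A=26.1, alpha=0.0843, beta=0.013)
        only_a = InVitroReleaseParams(dose=6.62 + 26.1, P0=6.62, A=26.1,
                                      alpha=0.0843, beta=0.013)
        only_b = InVitroReleaseParams(dose=6.62 + base.B, P0=6.62, A=0.0,
                                      alpha=0.0843, beta=0.013)
        g = 5.437
        full = predict_concentration(typical_pk, apply_inhibition(base, g), schedule).conc
        part_a = predict_concentration(typical_pk, apply_inhibition(only_a, g), schedule).conc
        part_b = predict_concentration(typical_pk, apply_inhibition(only_b, g), schedule).conc
        burst = predict_concentration(
            typical_pk,
            apply_inhibition(InVitroReleaseParams(dose=6.62, P0=6.62, A=0.0,
                                                  alpha=0.0843, beta=0.013), g),
            schedule,
        ).conc
        np.testing.assert_allclose(full, part_a + part_b - burst, rtol=1e-9, atol=1e-12)

    def test_nonnegative_states(self, typical_pk, release_125):
        t = np.linspace(0, 450, 200)
        conc = predict_concentration(typical_pk, release_125, t).conc
        assert np.all(conc >= -1e-12)


class TestPredictConcentrationMany:
    def test_matches_scalar_path(self, typical_pk, release_125, schedule):
        single = predict_concentration(typical_pk, release_125, schedule).conc
        many = predict_concentration_many(
            release_125.P0, release_125.A, release_125.B,
            np.full(3, release_125.alpha_vivo), np.full(3, release_125.beta_vivo),
            typical_pk.kabs_p0, typical_pk.kabs, typical_pk.kel,
            typical_pk.v_f, typical_pk.k12, typical_pk.k21, schedule,
        )
        assert many.shape == (3, len(schedule))
        for row in many:
            np.testing.assert_allclose(row, single, rtol=1e-12)


class TestMassBalance:
    def test_all_in_depot_at_t0(self, typical_pk, release_125):
        mb = mass_balance(typical_pk, release_125, 0.0)
        assert mb.depot_p0 == pytest.approx(release_125.P0, rel=1e-12)
        assert mb.depot == pytest.approx(0.0, abs=1e-12)
        assert mb.central == pytest.approx(0.0, abs=1e-12)

    def test_balance_holds(self, typical_pk, vitro_params, gamma_by_dose):
        release = apply_inhibition(vitro_params[375.0], gamma_by_dose[375.0])
        for t in (1.0, 24.0, 200.0, 408.0):
            mb = mass_balance(typical_pk, release, t)
            assert mb.total_in_body_or_eliminated == pytest.approx(mb.released, rel=1e-6)

    def test_eliminated_matches_quadrature_oracle(self, typical_pk, vitro_params,
                                                  gamma_by_dose):
        # oracle: integrate Kel * Ac(t) with fixed quadrature over [0, 408]
        from scipy.integrate import quad

        release = apply_inhibition(vitro_params[375.0], gamma_by_dose[375.0])

        def central_mg(t):
            prof = predict_concentration(typical_pk, release, [t])
            return prof.conc[0] * typical_pk.v_f / 1000.0

        integral, _ = quad(lambda t: typical_pk.kel * central_mg(t), 0, 408, limit=200)
        mb = mass_balance(typical_pk, release, 408.0)
        assert mb.eliminated == pytest.approx(integral, rel=1e-6)

    def test_long_time_all_eliminated(self, typical_pk, release_125):
        mb = mass_balance(typical_pk, release_125, 1e6)
        assert mb.eliminated == pytest.approx(release_125.dose, rel=1e-6)
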