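"""Shared fixtures: parameter sets and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ivring.pk import PKParams
from ivring.release import InVitroReleaseParams, apply_inhibition
from ivring.synthetic import (
    GAMMA_BY_DOSE,
    GAMMA_POLY,
    SERUM_SCHEDULE_H,
    TYPICAL_PK,
    VITRO_PARAMS,
    default_population,
)

DOSES = (125.0, 375.0, 750.0, 1500.0)


@pytest.fixture(scope="session")
def vitro_params() -> dict[float, InVitroReleaseParams]:
    return dict(VITRO_PARAMS)


@pytest.fixture(scope="session")
def typical_pk() -> PKParams:
    return TYPICAL_PK


@pytest.fixture(scope="session")
def gamma_by_dose() -> dict[float, float]:
    return dict(GAMMA_BY_DOSE)


@pytest.fixture(scope="session")
def gamma_poly():
    return GAMMA_POLY


@pytest.fixture(scope="session")
def schedule() -> np.ndarray:
    return np.asarray(SERUM_SCHEDULE_H, dtype=float)


@pytest.fixture(scope="session")
def pop():
    return default_population()


@pytest.fixture(scope="session")
def release_125(vitro_params, gamma_by_dose):
    return apply_inhibition(vitro_params[125.0], gamma_by_dose[125.0])


# ---------------------------------------------------------------------------
# Independent oracles (no code under test)
# ---------------------------------------------------------------------------

def ode_conc_oracle(pk: PKParams, release, times, rtol=1e-10, atol=1e-13) -> np.ndarray:
    """Stiff ODE integration of the structural model (independent of ivring.pk).

    States: immediate-release depot, slow depot, central, peripheral.  The
    bi-exponential release rate enters the slow depot as a forcing term.
    """
    from scipy.integrate import solve_ivp

    P0, A, B = release.P0, release.A, release.B
    av, bv = release.alpha_vivo, release.beta_vivo

    def rhs(t, x):
        d0, d, ac, ap = x
        rate_in = A * av * np.exp(-av * t) + B * bv * np.exp(-bv * t)
        return [
            -pk.kabs_p0 * d0,
            rate_in - pk.kabs * d,
            pk.kabs_p0 * d0 + pk.kabs * d - (pk.kel + pk.k12) * ac + pk.k21 * ap,
            pk.k12 * ac - pk.k21 * ap,
        ]

    t = np.asarray(times, dtype=float)
    t_span = (0.0, float(t.max()) if t.size else 0.0)
    sol = solve_ivp(rhs, t_span, [P0, 0.0, 0.0, 0.0], t_eval=t, method="LSODA",
                    rtol=rtol, atol=atol)
    assert sol.success
    return 1000.0 * sol.y[2] / pk.v_f


def bateman_oracle(amount, ka, kel, v, times) -> np.ndarray:
    """Closed-form one-compartment first-order absorption concentration."""
    t = np.asarray(times, dtype=float)
    return 1000.0 * amount * ka / v * (np.exp(-kel * t) - np.exp(-ka * t)) / (ka - kel)


def quadratic_ols_oracle(x, y) -> np.ndarray:
    """Normal-equations solution of an unweighted quadratic regression."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x, x * x])
    return np.linalg.solve(X.T @ X, X.T @ y)
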