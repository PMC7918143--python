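"""In vitro release model for progesterone vaginal rings and its in vivo mapping.

The in vitro cumulative release is modelled as an immediate burst ``P0``
followed by two first-order phases::

    P(t) = P0 + A * (1 - exp(-alpha * t)) + B * (1 - exp(-beta * t))

with the slow fraction constrained by mass balance, ``B = dose - P0 - A``.
In vivo, saturation of the small vaginal-fluid volume slows the release;
this is captured by a single non-negative inhibition factor ``gamma`` that
divides both exponential rates by ``(1 + gamma)`` while leaving the burst
and the phase amplitudes unchanged.  ``gamma`` is calibrated per dose by
matching the model's cumulative in vivo release at ring removal to the
amount actually released (charged dose minus residual assayed in the ring),
and its dose dependence is summarised by a quadratic polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "InVitroReleaseParams",
    "InVivoReleaseParams",
    "GammaDoseModel",
    "GammaSolveResult",
    "VitroFitResult",
    "HiguchiResult",
    "eval_cumulative_vitro",
    "eval_rate_vitro",
    "eval_cumulative_vivo",
    "apply_inhibition",
    "solve_gamma",
    "fit_vitro",
    "fit_gamma_polynomial",
    "higuchi_rate",
]


@dataclass(frozen=True)
class InVitroReleaseParams:
    """Parameters of the burst + bi-exponential in vitro release curve.

    Amounts are in mg, rates in 1/h.  The slow-phase amplitude ``B`` is
    derived (``dose - P0 - A``), never free.
    """

    dose: float
    P0: float
    A: float
    alpha: float
    beta: float
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dose", "P0", "A", "alpha", "beta", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.P0 + self.A > self.dose + 1e-9:
            raise ValueError("P0 + A must not exceed dose (B would be negative)")
        if not self.alpha > self.beta:
            raise ValueError("alpha (fast rate) must exceed beta (slow rate)")

    @property
    def B(self) -> float:
        """Slow-phase amplitude in mg, by mass balance."""
        return self.dose - self.P0 - self.A


@dataclass(frozen=True)
class InVivoReleaseParams:
    """In vitro parameters with the saturation inhibition applied.

    ``alpha_vivo = alpha / (1 + gamma)`` and likewise for ``beta_vivo``;
    ``gamma = 0`` recovers the in vitro curve exactly.
    """

    base: InVitroReleaseParams
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")

    @property
    def alpha_vivo(self) -> float:
        return self.base.alpha / (1.0 + self.gamma)

    @property
    def beta_vivo(self) -> float:
        return self.base.beta / (1.0 + self.gamma)

    @property
    def dose(self) -> float:
        return self.base.dose

    @property
    def P0(self) -> float:
        return self.base.P0

    @property
    def A(self) -> float:
        return self.base.A

    @property
    def B(self) -> float:
        return self.base.B


@dataclass(frozen=True)
class GammaDoseModel:
    """Quadratic map from charged dose (mg) to the inhibition factor gamma."""

    c0: float
    c1: float
    c2: float
    se: tuple[float, float, float] | None = None
    residuals: tuple[float, ...] | None = None

    def gamma(self, dose: float) -> float:
        g = self.c0 + self.c1 * dose + self.c2 * dose * dose
        if g < 0:
            raise ValueError(f"gamma model predicts negative gamma at dose {dose} mg")
        return g

    def __call__(self, dose: float) -> float:
        return self.gamma(dose)


def _check_times(t, positive: bool = False):
    t = np.asarray(t, dtype=float)
    if positive:
        if np.any(t <= 0):
            raise ValueError("t must be strictly positive")
    elif np.any(t < 0):
        raise ValueError("t must be non-negative")
    return t


def eval_cumulative_vitro(params: InVitroReleaseParams, t):
    """Cumulative in vitro release (mg) at time(s) ``t`` (h)."""
    t = _check_times(t)
    out = (
        params.P0
        + params.A * (-np.expm1(-params.alpha * t))
        + params.B * (-np.expm1(-params.beta * t))
    )
    return out if out.ndim else float(out)


def eval_rate_vitro(params: InVitroReleaseParams, t):
    """Continuous part of the in vitro release rate (mg/h) at ``t > 0``.

    The burst is an impulse at t=0 and is represented elsewhere as an
    initial depot condition, never as a numerical spike.
    """
    t = _check_times(t, positive=True)
    out = params.A * params.alpha * np.exp(-params.alpha * t) + params.B * params.beta * np.exp(
        -params.beta * t
    )
    return out if out.ndim else float(out)


def apply_inhibition(params: InVitroReleaseParams, gamma: float) -> InVivoReleaseParams:
    """Slow both release rates by ``1/(1+gamma)``; amplitudes unchanged."""
    return InVivoReleaseParams(base=params, gamma=float(gamma))


def eval_cumulative_vivo(params: InVivoReleaseParams, t):
    """Cumulative in vivo release (mg) at time(s) ``t`` (h)."""
    t = _check_times(t)
    out = (
        params.P0
        + params.A * (-np.expm1(-params.alpha_vivo * t))
        + params.B * (-np.expm1(-params.beta_vivo * t))
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class GammaSolveResult:
    """Root of the end-of-study mass-balance equation for gamma."""

    gamma: float
    boundary: bool  # True when the observed amount already exceeds the in vitro curve
    residual_mg: float

    def __float__(self) -> float:
        return self.gamma


def solve_gamma(
    params: InVitroReleaseParams,
    observed_amount: float,
    t_end: float = 408.0,
    gamma_max: float = 1e8,
) -> GammaSolveResult:
    """Calibrate the inhibition factor against an observed released amount.

    Finds the unique ``gamma >= 0`` such that the cumulative in vivo release
    at ``t_end`` equals ``observed_amount`` (mg), by Brent's method on
    ``[0, gamma_max]``.  The left-hand side is strictly decreasing in gamma,
    from the in vitro value at gamma=0 down to ``P0`` as gamma grows, so the
    root is unique whenever ``P0 < observed_amount < P_vitro(t_end)``.
    """
    if observed_amount <= params.P0:
        raise ValueError(
            f"observed amount {observed_amount} mg does not exceed the burst "
            f"P0={params.P0} mg; no finite gamma can match it"
        )
    vitro_end = eval_cumulative_vitro(params, t_end)
    if observed_amount >= vitro_end:
        # In vivo released at least as much as in vitro: no inhibition.
        resid = eval_cumulative_vivo(apply_inhibition(params, 0.0), t_end) - observed_amount
        return GammaSolveResult(gamma=0.0, boundary=True, residual_mg=float(resid))

    def f(g: float) -> float:
        return eval_cumulative_vivo(apply_inhibition(params, g), t_end) - observed_amount

    gamma = optimize.brentq(f, 0.0, gamma_max, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    resid = f(gamma)
    if abs(resid) > 1e-8:
        raise RuntimeError(f"gamma root residual {resid:.3e} mg exceeds 1e-8 mg tolerance")
    return GammaSolveResult(gamma=float(gamma), boundary=False, residual_mg=float(resid))


@dataclass(frozen=True)
class VitroFitResult:
    params: InVitroReleaseParams
    standard_errors: dict[str, float]
    fixed: dict[str, bool]
    residuals: np.ndarray = field(repr=False)
    n_obs: int = 0

    @property
    def residual_sd(self) -> float:
        return self.params.residual_sd


def _pool_profiles(profiles) -> tuple[np.ndarray, np.ndarray]:
    ts, ys = [], []
    for t, y in profiles:
        ts.append(np.asarray(t, dtype=float))
        ys.append(np.asarray(y, dtype=float))
    return np.concatenate(ts), np.concatenate(ys)


def fit_vitro(
    profiles: Sequence[tuple[Sequence[float], Sequence[float]]],
    dose: float,
    fix_P0: float | None = None,
) -> VitroFitResult:
    """Pooled nonlinear least-squares fit of the in vitro release curve.

    ``profiles`` is a sequence of per-ring ``(time_h, cumulative_mg)`` pairs;
    all rings of a dose are pooled into one objective (inter-ring variability
    is negligible for these rings).  When no samples earlier than 24 h exist
    the burst ``P0`` is not identifiable and must be supplied via ``fix_P0``.

    Returns least-squares estimates of (P0, A, alpha, beta) with the additive
    residual SD and delta-method standard errors; B is derived by mass
    balance.
    """
    t, y = _pool_profiles(profiles)
    if t.size < 6 and len(profiles) < 2:
        raise ValueError("need at least 2 rings or 6 pooled time points")
    if np.any(y < 0) or np.any(y > dose * (1 + 1e-9)):
        raise ValueError("cumulative values must lie in [0, dose]")
    order = np.argsort(t)
    t, y = t[order], y[order]

    free = ["P0", "A", "alpha", "beta"] if fix_P0 is None else ["A", "alpha", "beta"]

    def unpack(x):
        if fix_P0 is None:
            P0, A, alpha, beta = x
        else:
            P0 = fix_P0
            A, alpha, beta = x
        return P0, A, alpha, beta

    def resid(x):
        P0, A, alpha, beta = unpack(x)
        B = dose - P0 - A
        pred = P0 + A * (-np.expm1(-alpha * t)) + B * (-np.expm1(-beta * t))
        return pred - y

    # Crude but robust starting values from the data shape.
    y_end = float(y[t == t.max()].mean())
    p0_guess = max(float(y[t == t.min()].mean()) * 0.5, 1e-3)
    a_guess = max(0.2 * y_end, 1e-2)
    x0 = [a_guess, 0.05, 0.005] if fix_P0 is not None else [p0_guess, a_guess, 0.05, 0.005]
    lo = [0.0] * len(x0)
    hi = [dose, 1.0, 1.0] if fix_P0 is not None else [dose, dose, 1.0, 1.0]

    sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"in vitro fit did not converge: {sol.message}")
    P0, A, alpha, beta = unpack(sol.x)
    # Canonical labelling: alpha is the fast phase.  The model is symmetric
    # under (alpha, A) <-> (beta, B), so relabel rather than fail.
    B = dose - P0 - A
    if alpha < beta:
        alpha, beta = beta, alpha
        A, B = B, A
    if alpha == beta:
        raise RuntimeError("degenerate fit: alpha == beta (non-identifiable phases)")

    dof = max(t.size - len(free), 1)
    sd = float(np.sqrt(np.sum(sol.fun**2) / dof))
    J = sol.jac
    JTJ = J.T @ J
    if np.linalg.cond(JTJ) > 1e12:
        raise RuntimeError("non-identifiable fit: singular Jacobian (condition > 1e12)")
    cov = sd**2 * np.linalg.inv(JTJ)
    se = dict(zip(free, np.sqrt(np.diag(cov))))

    params = InVitroReleaseParams(dose=dose, P0=P0, A=A, alpha=alpha, beta=beta, residual_sd=sd)
    fixed = {"P0": fix_P0 is not None}
    return VitroFitResult(params=params, standard_errors=se, fixed=fixed, residuals=sol.fun, n_obs=t.size)


def fit_gamma_polynomial(doses: Sequence[float], gammas: Sequence[float]) -> GammaDoseModel:
    """Ordinary least-squares quadratic for gamma as a function of dose (mg)."""
    d = np.asarray(doses, dtype=float)
    g = np.asarray(gammas, dtype=float)
    if d.size != g.size:
        raise ValueError("doses and gammas must have equal length")
    if d.size < 3:
        raise ValueError("need at least 3 (dose, gamma) pairs for a quadratic")
    X = np.vander(d, 3, increasing=True)
    coef, _, _, _ = np.linalg.lstsq(X, g, rcond=None)
    resid = g - X @ coef
    dof = d.size - 3
    if dof > 0:
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        se = tuple(np.sqrt(np.diag(cov)))
    else:
        se = None
    return GammaDoseModel(
        c0=float(coef[0]), c1=float(coef[1]), c2=float(coef[2]),
        se=se, residuals=tuple(resid),
    )


@dataclass(frozen=True)
class HiguchiResult:
    """Matrix-release rate: slope of cumulative release on sqrt(time in days)."""

    rate_mg_per_sqrt_day: float
    r_squared: float


def higuchi_rate(times_h: Sequence[float], cumulative_mg: Sequence[float]) -> HiguchiResult:
    """Release rate in mg/day^0.5 by intercept-free regression on sqrt(days).

    Uses every supplied point; a poor square-root-of-time fit is reported
    through R^2 rather than rejected.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(cumulative_mg, dtype=float)
    if t.size == 0:
        raise ValueError("empty profile")
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive")
    x = np.sqrt(t / 24.0)
    slope = float(np.sum(x * y) / np.sum(x * x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))  # uncentred: regression through the origin
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return HiguchiResult(rate_mg_per_sqrt_day=slope, r_squared=r2)
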