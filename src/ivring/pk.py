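"""Two-compartment serum PK driven by the in vivo ring release.

The progesterone released by the ring follows two parallel absorption
paths: the burst amount ``P0`` sits in its own depot and is absorbed with
rate ``Kabs_P0``; the bi-exponentially released remainder accumulates in a
second depot absorbed with the slower rate ``Kabs``.  Disposition is a
linear two-compartment model with elimination ``Kel`` from the central
compartment and inter-compartmental rates ``K12``/``K21``.

Because the release itself is a sum of exponentials, the entire system is
linear time-invariant and is solved exactly by eigendecomposition of the
seven-state matrix (two un-released ring states, two depots, central,
peripheral, eliminated).  The solver is vectorised over subjects, which is
what makes the population layer (MCMC-based estimation, virtual trials)
fast enough to run routinely.

Units: amounts mg, volume L, time h; concentration is reported in ng/mL
via ``1000 * Ac / (V/F)`` (0.001 mg/L = 1 ng/mL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .release import InVivoReleaseParams

__all__ = [
    "PKParams",
    "ConcentrationProfile",
    "MassBalance",
    "predict_concentration",
    "predict_concentration_many",
    "mass_balance",
]

# Multiplicative nudge applied to absorption/release rates when two system
# eigenvalues collide (the matrix would be defective); small enough to be
# far below any data-driven resolution.
_RATE_EPS = 1e-9

# State indexing for the linear system.
_RING_FAST, _RING_SLOW, _DEPOT_P0, _DEPOT, _CENTRAL, _PERIPH, _ELIM = range(7)


@dataclass(frozen=True)
class PKParams:
    """Structural PK parameters (all rates 1/h, volume L, strictly positive)."""

    kabs_p0: float
    kabs: float
    kel: float
    v_f: float
    k12: float
    k21: float

    def __post_init__(self) -> None:
        for name in ("kabs_p0", "kabs", "kel", "v_f", "k12", "k21"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ConcentrationProfile:
    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and conc must have the same shape")
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0):
            raise ValueError("times must be non-negative and ascending")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)


def _disposition_eigenvalues(kel, k12, k21):
    """Eigenvalues (positive magnitudes) of the two-compartment disposition."""
    s = kel + k12 + k21
    disc = np.sqrt(s * s - 4.0 * kel * k21)
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    return lam1, lam2


def _separate_rates(av, bv, k0, ka, kel, k12, k21):
    """Nudge the four free rates so all system eigenvalues are distinct.

    The system eigenvalues are {-av, -bv, -k0, -ka, -lam1, -lam2, 0}; a
    collision makes the matrix defective and the eigenvector solve
    ill-conditioned.  Each colliding free rate is scaled by (1 + 1e-9 * k),
    an unobservable perturbation.
    """
    av, bv, k0, ka = (np.array(x, dtype=float, copy=True) for x in (av, bv, k0, ka))
    lam1, lam2 = _disposition_eigenvalues(kel, k12, k21)
    free = [av, bv, k0, ka]
    for i, rate in enumerate(free):
        bump = 1
        while True:
            others = [f for j, f in enumerate(free) if j != i] + [lam1, lam2]
            clash = np.zeros(rate.shape, dtype=bool)
            for o in others:
                scale = np.maximum(np.abs(rate), np.abs(o))
                clash |= np.abs(rate - o) <= 16 * _RATE_EPS * scale
            if not np.any(clash):
                break
            rate[clash] *= 1.0 + _RATE_EPS * bump
            bump += 1
            if bump > 64:  # pragma: no cover - pathological inputs only
                raise RuntimeError("could not separate coincident rate constants")
    return free[0], free[1], free[2], free[3]


def _build_matrices(av, bv, k0, ka, kel, k12, k21):
    n = av.shape[0]
    M = np.zeros((n, 7, 7))
    M[:, _RING_FAST, _RING_FAST] = -av
    M[:, _RING_SLOW, _RING_SLOW] = -bv
    M[:, _DEPOT_P0, _DEPOT_P0] = -k0
    M[:, _DEPOT, _RING_FAST] = av
    M[:, _DEPOT, _RING_SLOW] = bv
    M[:, _DEPOT, _DEPOT] = -ka
    M[:, _CENTRAL, _DEPOT_P0] = k0
    M[:, _CENTRAL, _DEPOT] = ka
    M[:, _CENTRAL, _CENTRAL] = -(kel + k12)
    M[:, _CENTRAL, _PERIPH] = k21
    M[:, _PERIPH, _CENTRAL] = k12
    M[:, _PERIPH, _PERIPH] = -k21
    M[:, _ELIM, _CENTRAL] = kel
    return M


def _solve_states(P0, A, B, av, bv, k0, ka, kel, k12, k21, times):
    """Exact states (n_subjects, n_times, 7) of the stacked linear systems."""
    arrs = [np.atleast_1d(np.asarray(x, dtype=float)) for x in (P0, A, B, av, bv, k0, ka, kel, k12, k21)]
    n = max(a.shape[0] for a in arrs)
    P0, A, B, av, bv, k0, ka, kel, k12, k21 = (np.broadcast_to(a, (n,)) for a in arrs)
    av, bv, k0, ka = _separate_rates(av, bv, k0, ka, kel, k12, k21)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    M = _build_matrices(av, bv, k0, ka, kel, k12, k21)
    w, V = np.linalg.eig(M)  # (n, 7), (n, 7, 7)
    x0 = np.zeros((n, 7))
    x0[:, _RING_FAST] = A
    x0[:, _RING_SLOW] = B
    x0[:, _DEPOT_P0] = P0
    coef = np.linalg.solve(V, x0[..., None])[..., 0]  # (n, 7)

    E = np.exp(w[:, None, :] * times[None, :, None])  # (n, m, 7)
    states = np.einsum("nij,nmj->nmi", V, coef[:, None, :] * E).real
    if not np.all(np.isfinite(states)):
        raise FloatingPointError("non-finite state in PK solution")
    return states


def _conc_many(P0, A, B, av, bv, k0, ka, kel, v_f, k12, k21, times):
    states = _solve_states(P0, A, B, av, bv, k0, ka, kel, k12, k21, times)
    v = np.broadcast_to(np.atleast_1d(np.asarray(v_f, dtype=float)), (states.shape[0],))
    return 1000.0 * states[:, :, _CENTRAL] / v[:, None]


def predict_concentration(pk: PKParams, release: InVivoReleaseParams, times) -> ConcentrationProfile:
    """Serum concentration (ng/mL) at the requested times for one subject."""
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    conc = _conc_many(
        release.P0, release.A, release.B,
        release.alpha_vivo, release.beta_vivo,
        pk.kabs_p0, pk.kabs, pk.kel, pk.v_f, pk.k12, pk.k21,
        t,
    )[0]
    return ConcentrationProfile(times=t, conc=conc)


def predict_concentration_many(
    release_P0, release_A, release_B, alpha_vivo, beta_vivo,
    kabs_p0, kabs, kel, v_f, k12, k21, times,
) -> np.ndarray:
    """Vectorised concentration matrix (n_subjects, n_times) in ng/mL.

    Scalar arguments broadcast; per-subject arrays must share one length.
    This is the workhorse behind population simulation and estimation.
    """
    return _conc_many(release_P0, release_A, release_B, alpha_vivo, beta_vivo,
                      kabs_p0, kabs, kel, v_f, k12, k21, times)


@dataclass(frozen=True)
class MassBalance:
    """Drug amounts (mg) by location at one time point."""

    depot_p0: float
    depot: float
    central: float
    peripheral: float
    eliminated: float
    released: float  # cumulative in vivo release P_vivo(t)

    @property
    def total_in_body_or_eliminated(self) -> float:
        return self.depot_p0 + self.depot + self.central + self.peripheral + self.eliminated


def mass_balance(pk: PKParams, release: InVivoReleaseParams, t: float) -> MassBalance:
    """Account for every mg released by time ``t``.

    The sum of both depots, both disposition compartments and the
    cumulatively eliminated amount equals the cumulative in vivo release —
    the linear system conserves mass exactly, so any discrepancy measures
    numerical error only.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    from .release import eval_cumulative_vivo

    s = _solve_states(
        release.P0, release.A, release.B,
        release.alpha_vivo, release.beta_vivo,
        pk.kabs_p0, pk.kabs, pk.kel, pk.k12, pk.k21,
        [float(t)],
    )[0, 0]
    return MassBalance(
        depot_p0=float(s[_DEPOT_P0]),
        depot=float(s[_DEPOT]),
        central=float(s[_CENTRAL]),
        peripheral=float(s[_PERIPH]),
        eliminated=float(s[_ELIM]),
        released=float(eval_cumulative_vivo(release, t)),
    )
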