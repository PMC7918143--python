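"""In vitro profile comparison (f1/f2) and virtual bioequivalence trials.

The model-independent difference factor f1 (percent relative error between
two release curves) and similarity factor f2 (a log-reciprocal-square-root
transform of the mean squared difference) compare a test batch against a
reference batch; the regulatory sameness window is f1 in [0, 15] and f2 in
[50, 100].

When a Level-A IVIVC is in place, a virtual bioequivalence trial replaces
the clinical study: two independent simulated populations receive rings
whose in vivo release is predicted from each batch's in vitro curve, and
the exposure ratio F = AUC_test / AUC_ref with its 90% confidence interval
is judged against the 0.80-1.25 acceptance range.  Simulating independent
arms treats intra-individual variability as equal to inter-individual
variability — a conservative assumption in the absence of crossover data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .evaluation import auc_trapezoid
from .pk import ConcentrationProfile
from .population import Arm, PopulationParams, simulate_study
from .release import InVitroReleaseParams

__all__ = ["f1", "f2", "BatchComparison", "compare_batches", "BEResult", "virtual_be_trial"]

F1_LIMIT = 15.0
F2_LIMIT = 50.0
BE_RANGE = (0.80, 1.25)


def _check_profiles(reference, test):
    r = np.asarray(reference, dtype=float)
    t = np.asarray(test, dtype=float)
    if r.shape != t.shape or r.ndim != 1:
        raise ValueError("reference and test must be 1-D arrays of equal length")
    if r.size < 1:
        raise ValueError("profiles must contain at least one point")
    return r, t


def f1(reference, test) -> float:
    """Difference factor: percent relative error between two release curves.

    Not symmetric — the reference batch normalises the error.
    """
    r, t = _check_profiles(reference, test)
    denom = np.abs(r).sum()
    if denom == 0:
        raise ValueError("all-zero reference profile")
    return float(np.abs(r - t).sum() / denom * 100.0)


def f2(reference, test) -> float:
    """Similarity factor: 50*log10(100 / sqrt(1 + mean squared difference)).

    Symmetric in its arguments; equals 100 exactly for identical profiles
    and decreases as the pointwise squared deviation grows.
    """
    r, t = _check_profiles(reference, test)
    msd = float(np.mean((r - t) ** 2))
    return float(50.0 * math.log10(100.0 / math.sqrt(1.0 + msd)))


@dataclass(frozen=True)
class BatchComparison:
    f1: float
    f2: float
    f1_pass: bool
    f2_pass: bool
    n_points: int
    units: str

    @property
    def passes(self) -> bool:
        return self.f1_pass and self.f2_pass


def compare_batches(ref_profiles, test_profiles, timepoints=None, units: str = "mg") -> BatchComparison:
    """Apply both FDA profile-comparison criteria to two batches.

    ``ref_profiles`` / ``test_profiles`` are 2-D arrays (ring x time) of
    cumulative release sampled at shared time points; replicate rings are
    averaged into the batch-mean curves compared by f1/f2.  ``units``
    records whether the inputs are mg or percent-of-label (both are
    accepted; the choice is echoed in the result).
    """
    r = np.atleast_2d(np.asarray(ref_profiles, dtype=float))
    t = np.atleast_2d(np.asarray(test_profiles, dtype=float))
    if r.shape[1] != t.shape[1] or r.shape[1] == 0:
        raise ValueError("batches share no common time points")
    r_mean, t_mean = r.mean(axis=0), t.mean(axis=0)
    v1, v2 = f1(r_mean, t_mean), f2(r_mean, t_mean)
    return BatchComparison(
        f1=v1, f2=v2, f1_pass=v1 <= F1_LIMIT, f2_pass=v2 >= F2_LIMIT,
        n_points=r.shape[1], units=units,
    )


@dataclass(frozen=True)
class BEResult:
    """Virtual bioequivalence outcome for a parallel two-arm simulation."""

    F: float                     # ratio of arm means of AUC(0-408)
    ci90: tuple[float, float]
    n_per_arm: int
    seed: int | None
    method: str                  # 'welch-log' or 'bootstrap'
    auc_geomean_ref: float
    auc_geomean_test: float
    passes: bool


def _welch_log_ci(log_ref: np.ndarray, log_test: np.ndarray, level: float = 0.90) -> tuple[float, float]:
    n1, n2 = log_test.size, log_ref.size
    d = log_test.mean() - log_ref.mean()
    v1, v2 = log_test.var(ddof=1) / n1, log_ref.var(ddof=1) / n2
    se = math.sqrt(v1 + v2)
    if se == 0.0:
        return (math.exp(d), math.exp(d))
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    tcrit = stats.t.ppf(0.5 + level / 2, df)
    return (math.exp(d - tcrit * se), math.exp(d + tcrit * se))


def virtual_be_trial(
    pop: PopulationParams,
    ref_vitro: InVitroReleaseParams,
    test_vitro: InVitroReleaseParams,
    dose: float | None = None,
    n_per_arm: int = 500,
    rng_seed: int | None = None,
    schedule=None,
    t_end: float = 408.0,
    method: str = "welch-log",
    arm_seeds: tuple[int, int] | None = None,
    n_boot: int = 2000,
) -> BEResult:
    """Simulate a parallel virtual BE trial and judge the 0.80-1.25 window.

    Each arm is an independent population at the nominal ``dose``; each
    arm's in vivo release applies the dose-level inhibition factor to its
    own batch's in vitro rates.  F is the ratio of arithmetic mean AUCs
    (test over reference); the 90% CI is a Welch interval on log AUC by
    default, or a percentile bootstrap of the arithmetic-mean ratio.
    """
    if n_per_arm < 2:
        raise ValueError("n_per_arm must be >= 2")
    if dose is None:
        dose = ref_vitro.dose
    if not math.isclose(ref_vitro.dose, test_vitro.dose, rel_tol=1e-9):
        raise ValueError("reference and test batches must share the nominal dose")
    if schedule is None:
        from .synthetic import SERUM_SCHEDULE_H

        schedule = SERUM_SCHEDULE_H
    if arm_seeds is None:
        ss = np.random.SeedSequence(rng_seed)
        s_ref, s_test = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    else:
        s_ref, s_test = arm_seeds

    def arm_aucs(vitro: InVitroReleaseParams, seed: int) -> np.ndarray:
        ds = simulate_study(pop, [Arm(dose=dose, batch="arm", n=n_per_arm, vitro=vitro)],
                            schedule, rng_seed=seed, with_residual=True)
        return np.array([
            auc_trapezoid(ConcentrationProfile(times=s.times, conc=s.conc), t_end)
            for s in ds.subjects
        ])

    auc_ref = arm_aucs(ref_vitro, s_ref)
    auc_test = arm_aucs(test_vitro, s_test)
    F = float(auc_test.mean() / auc_ref.mean())

    # AUCs are positive in practice (additive noise is small relative to
    # exposure); guard the log transforms anyway.
    pos_ref, pos_test = np.maximum(auc_ref, 1e-12), np.maximum(auc_test, 1e-12)
    if method == "welch-log":
        ci = _welch_log_ci(np.log(pos_ref), np.log(pos_test))
    elif method == "bootstrap":
        rng = np.random.default_rng(rng_seed)
        ratios = np.empty(n_boot)
        for b in range(n_boot):
            rb = rng.choice(auc_ref, auc_ref.size, replace=True).mean()
            tb = rng.choice(auc_test, auc_test.size, replace=True).mean()
            ratios[b] = tb / rb
        ci = (float(np.quantile(ratios, 0.05)), float(np.quantile(ratios, 0.95)))
    else:
        raise ValueError("method must be 'welch-log' or 'bootstrap'")

    passes = bool(BE_RANGE[0] <= ci[0] and ci[1] <= BE_RANGE[1])
    return BEResult(
        F=F, ci90=(float(ci[0]), float(ci[1])), n_per_arm=n_per_arm, seed=rng_seed,
        method=method,
        auc_geomean_ref=float(np.exp(np.mean(np.log(pos_ref)))),
        auc_geomean_test=float(np.exp(np.mean(np.log(pos_test)))),
        passes=passes,
    )
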