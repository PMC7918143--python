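"""Level-A IVIVC predictability metrics: AUC, Cmax, %PE, FDA pass rules.

Internal predictability asks how well the fully identified model describes
the data it was built on: each subject's concentration profile is
predicted from the in vitro release curve of their dose, and the percent
prediction error

    %PE = (observed - predicted) / observed * 100

is computed on AUC(0-t) over a grid of times and on Cmax.  The regulatory
criteria for extended-release products are an average absolute %PE of at
most 10% with every dose/release-rate at most 15%.  External
predictability repeats the exercise on a dose held out of model building.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pk import ConcentrationProfile, PKParams, predict_concentration
from .population import (
    PopulationParams,
    SAEMSettings,
    StudyDataset,
    estimate_population,
    vpc_bands,
)
from .release import (
    GammaDoseModel,
    InVitroReleaseParams,
    apply_inhibition,
    fit_gamma_polynomial,
    solve_gamma,
)

__all__ = [
    "auc_trapezoid",
    "cmax",
    "percent_pe",
    "PredictabilityReport",
    "internal_predictability",
    "ExternalReport",
    "external_predictability",
    "FDA_AVERAGE_LIMIT",
    "FDA_INDIVIDUAL_LIMIT",
]

FDA_AVERAGE_LIMIT = 10.0     # percent, average absolute PE
FDA_INDIVIDUAL_LIMIT = 15.0  # percent, per dose/release rate


def auc_trapezoid(profile: ConcentrationProfile, t_end: float) -> float:
    """Linear-trapezoid AUC (ng*h/mL) on the observation grid up to ``t_end``.

    ``t_end`` must be a sampled time; no extrapolation is performed.  The
    integral runs over the sampled grid only (a single point has zero
    area); observed and predicted metrics are always computed on the same
    grid, so prediction errors are unaffected by the grid convention.
    """
    t, c = profile.times, profile.conc
    hit = np.isclose(t, t_end, rtol=1e-9, atol=1e-9)
    if not hit.any():
        raise ValueError(f"t_end={t_end} h is not a sampled time (no extrapolation)")
    k = int(np.nonzero(hit)[0][-1])
    if k == 0:
        return 0.0
    return float(np.trapezoid(c[: k + 1], t[: k + 1]))


def cmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """Maximum concentration and its time; ties resolved to the earliest time."""
    if profile.times.size == 0:
        raise ValueError("empty profile")
    i = int(np.argmax(profile.conc))  # argmax returns the first maximum
    return float(profile.conc[i]), float(profile.times[i])


def percent_pe(observed: float, predicted: float) -> float:
    """Signed percent prediction error, (obs - pred) / obs * 100."""
    if observed == 0:
        raise ValueError("observed value must be nonzero")
    return (observed - predicted) / observed * 100.0


@dataclass
class PredictabilityReport:
    """Absolute %PE per dose and on average, with the FDA pass flags."""

    auc_pe: pd.DataFrame         # index: dose (+ 'average' row); columns: AUC horizon times
    cmax_pe: pd.Series           # index: dose (+ 'average')
    auc_pass: bool
    cmax_pass: bool
    mode: str                    # 'individual' or 'population' predictions
    per_subject: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def passes(self) -> bool:
        return self.auc_pass and self.cmax_pass


def _fda_pass(per_dose: np.ndarray, average: float) -> bool:
    return bool(average <= FDA_AVERAGE_LIMIT and np.all(per_dose <= FDA_INDIVIDUAL_LIMIT))


def _predict_subject(subject, pop: PopulationParams, vitro: InVitroReleaseParams, mode: str) -> ConcentrationProfile:
    if mode == "individual":
        if subject.true_pk is None or subject.true_gamma is None:
            raise ValueError(
                f"subject {subject.id} has no individual parameter estimates; "
                "use mode='population'"
            )
        pk, gamma = subject.true_pk, subject.true_gamma
    elif mode == "population":
        pk = pop.theta
        gamma = pop.gamma_model.gamma(subject.dose)
    else:
        raise ValueError("mode must be 'individual' or 'population'")
    release = apply_inhibition(vitro, gamma)
    return predict_concentration(pk, release, subject.times)


def internal_predictability(
    data: StudyDataset,
    pop: PopulationParams,
    vitro_by_dose: Mapping[float, InVitroReleaseParams],
    auc_times: Sequence[float] | None = None,
    mode: str = "individual",
) -> PredictabilityReport:
    """Per-subject prediction errors on AUC(0-t) and Cmax, FDA-aggregated.

    ``mode='individual'`` uses each subject's individual parameters (when
    the dataset carries them, e.g. simulation truth or posterior modes);
    ``mode='population'`` uses typical values only.  Absolute %PE is
    averaged across subjects within a dose, then across doses.
    """
    for s in data.subjects:
        if s.dose not in vitro_by_dose:
            raise KeyError(f"no in vitro parameters for dose {s.dose} mg")
    if auc_times is None:
        auc_times = [t for t in data.subjects[0].times if t >= 24.0]
    auc_times = list(auc_times)

    rows = []
    for s in data.subjects:
        obs = ConcentrationProfile(times=s.times, conc=s.conc)
        pred = _predict_subject(s, pop, vitro_by_dose[s.dose], mode)
        rec = {"subject_id": s.id, "dose": s.dose}
        for t_end in auc_times:
            rec[f"auc_{t_end:g}"] = percent_pe(auc_trapezoid(obs, t_end), auc_trapezoid(pred, t_end))
        rec["cmax"] = percent_pe(cmax(obs)[0], cmax(pred)[0])
        rows.append(rec)
    per_subject = pd.DataFrame(rows)

    by_dose = per_subject.drop(columns="subject_id").abs().groupby(per_subject["dose"]).mean()
    auc_cols = [f"auc_{t:g}" for t in auc_times]
    auc_pe = by_dose[auc_cols].copy()
    auc_pe.loc["average"] = auc_pe.mean(axis=0)
    cmax_pe = by_dose["cmax"].copy()
    cmax_pe.loc["average"] = cmax_pe.mean()

    dose_rows = [d for d in auc_pe.index if d != "average"]
    final_col = auc_cols[-1]
    auc_pass = _fda_pass(auc_pe.loc[dose_rows, final_col].to_numpy(), float(auc_pe.loc["average", final_col]))
    cmax_pass = _fda_pass(cmax_pe.loc[dose_rows].to_numpy(), float(cmax_pe.loc["average"]))
    return PredictabilityReport(
        auc_pe=auc_pe, cmax_pe=cmax_pe, auc_pass=auc_pass, cmax_pass=cmax_pass,
        mode=mode, per_subject=per_subject,
    )


@dataclass
class ExternalReport:
    """Hold-out dose evaluation: %PE on mean exposure plus a VPC overlay."""

    auc_pe: pd.Series            # absolute %PE on the mean AUC(0-t), per horizon
    cmax_pe: float               # absolute %PE on the mean Cmax
    gamma_model: GammaDoseModel  # re-fitted on training doses only
    pop: PopulationParams        # re-estimated on the training set
    vpc: pd.DataFrame            # simulated bands at the test dose
    observed_coverage: float     # fraction of test observations inside the 90% band
    passes: bool


def external_predictability(
    train: StudyDataset,
    test: StudyDataset,
    test_vitro: InVitroReleaseParams,
    train_vitro_by_dose: Mapping[float, InVitroReleaseParams],
    n_sim: int = 500,
    auc_times: Sequence[float] | None = None,
    settings: SAEMSettings | None = None,
    rng_seed: int | None = None,
) -> ExternalReport:
    """Train/hold-out workflow for external predictability.

    Re-calibrates the dose->gamma polynomial on the training doses only
    (from each dose's mean released amount), re-estimates the population
    model on the training subjects, simulates ``n_sim`` subjects at the
    held-out dose from its in vitro curve, and reports absolute %PE on the
    mean AUC(0-t) and mean Cmax of the held-out arm, plus VPC coverage.
    """
    test_doses = {s.dose for s in test.subjects}
    if len(test_doses) != 1:
        raise ValueError("test set must contain a single dose")
    test_dose = test_doses.pop()
    train_doses = sorted({s.dose for s in train.subjects})
    if test_dose in train_doses:
        raise ValueError(f"test dose {test_dose} mg present in the training set")

    # gamma per training dose from mean end-of-study released amounts
    gammas = []
    for d in train_doses:
        amounts = [s.released_amount for s in train.subjects if s.dose == d]
        gammas.append(solve_gamma(train_vitro_by_dose[d], float(np.mean(amounts))).gamma)
    gamma_model = fit_gamma_polynomial(train_doses, gammas)

    fit = estimate_population(train, train_vitro_by_dose, gamma_model, settings=settings)
    pop = fit.params

    schedule = test.subjects[0].times
    bands = vpc_bands(pop, test_dose, test_vitro, schedule, n_sim=max(n_sim, 100), rng_seed=rng_seed)

    # simulate the held-out arm and compare mean exposure metrics
    from .population import Arm, simulate_study

    sim = simulate_study(pop, [Arm(dose=test_dose, batch="sim", n=n_sim, vitro=test_vitro)],
                         schedule, rng_seed=rng_seed, with_residual=True)
    if auc_times is None:
        auc_times = [t for t in schedule if t >= 264.0]
    auc_times = list(auc_times)

    def mean_metrics(ds: StudyDataset):
        aucs = {t: [] for t in auc_times}
        cmaxes = []
        for s in ds.subjects:
            prof = ConcentrationProfile(times=s.times, conc=s.conc)
            for t_end in auc_times:
                aucs[t_end].append(auc_trapezoid(prof, t_end))
            cmaxes.append(cmax(prof)[0])
        return {t: float(np.mean(v)) for t, v in aucs.items()}, float(np.mean(cmaxes))

    obs_auc, obs_cmax = mean_metrics(test)
    sim_auc, sim_cmax = mean_metrics(sim)
    auc_pe = pd.Series(
        {t: abs(percent_pe(obs_auc[t], sim_auc[t])) for t in auc_times}, name="abs_pe_mean_auc"
    )
    cmax_pe = abs(percent_pe(obs_cmax, sim_cmax))

    lo = np.interp(schedule, bands["time_h"], bands["q05"])
    hi = np.interp(schedule, bands["time_h"], bands["q95"])
    inside = [
        np.mean((s.conc >= lo) & (s.conc <= hi)) for s in test.subjects
    ]
    coverage = float(np.mean(inside))

    passes = bool(auc_pe.max() <= FDA_AVERAGE_LIMIT and cmax_pe <= FDA_AVERAGE_LIMIT)
    return ExternalReport(
        auc_pe=auc_pe, cmax_pe=float(cmax_pe), gamma_model=gamma_model, pop=pop,
        vpc=bands, observed_coverage=coverage, passes=passes,
    )
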