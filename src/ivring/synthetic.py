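"""Bundled study fixtures and synthetic data generators.

No public accession exists for the ring release or clinical PK data, so the
package carries the published summary parameters as fixtures and generates
synthetic datasets with the statistical structure the analysis assumes:
pooled in vitro release curves with additive assay noise, and a clinical
study with log-normal between-subject variability on the PK parameters and
the release-inhibition factor, additive residual error on both observation
streams, and the original arm sizes and sampling schedules.

What the generator emulates — and what it does not — is discussed in the
methods note; briefly, it reproduces the model's own data-generating
process, so tests built on it probe self-consistency (calibration,
round-trip recovery, coverage), not model misspecification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pk import PKParams
from .release import GammaDoseModel, InVitroReleaseParams, eval_cumulative_vitro
from .population import Arm, PopulationParams, StudyDataset, simulate_study

__all__ = [
    "VITRO_PARAMS",
    "IN_VIVO_RELEASED_MG",
    "IN_VITRO_RELEASED_MG",
    "GAMMA_BY_DOSE",
    "GAMMA_POLY",
    "TYPICAL_PK",
    "OMEGA",
    "VAR_CONC",
    "VAR_AMOUNT",
    "POPULATION_PARAMS",
    "CLINICAL_ARMS",
    "SERUM_SCHEDULE_H",
    "HIGUCHI_RATES",
    "FIXTURE_SOURCES",
    "invitro_schedule",
    "default_population",
    "gen_invitro_dataset",
    "gen_clinical_dataset",
]

# ---------------------------------------------------------------------------
# Fixtures: published summary parameters of the progesterone-ring study.
# The 375 mg burst is carried as 9.45 mg (the value the slow-phase
# amplitudes are consistent with, and the value the higher doses were fixed
# to), not the 9.5 mg shown rounded in the parameter table.
# ---------------------------------------------------------------------------

VITRO_PARAMS: Mapping[float, InVitroReleaseParams] = {
    125.0: InVitroReleaseParams(dose=125.0, P0=6.62, A=26.1, alpha=0.0843, beta=0.013, residual_sd=1.13),
    375.0: InVitroReleaseParams(dose=375.0, P0=9.45, A=59.1, alpha=0.0846, beta=0.0059, residual_sd=2.84),
    750.0: InVitroReleaseParams(dose=750.0, P0=9.45, A=130.0, alpha=0.0721, beta=0.00361, residual_sd=6.55),
    1500.0: InVitroReleaseParams(dose=1500.0, P0=9.45, A=318.0, alpha=0.0656, beta=0.0033, residual_sd=10.5),
}

#: Mean progesterone released in vivo by ring removal (mg), per dose.
IN_VIVO_RELEASED_MG: Mapping[float, float] = {125.0: 84.40, 375.0: 117.82, 750.0: 119.30, 1500.0: 121.00}

#: Mean progesterone released in vitro over the 15-day test (mg), per dose.
IN_VITRO_RELEASED_MG: Mapping[float, float] = {125.0: 114.0, 375.0: 346.40, 750.0: 582.04, 1500.0: 1129.62}

#: Calibrated inhibition factors per dose.
GAMMA_BY_DOSE: Mapping[float, float] = {125.0: 5.437, 375.0: 11.643, 750.0: 29.219, 1500.0: 77.601}

#: Quadratic dose -> gamma map (dose in mg).
GAMMA_POLY = GammaDoseModel(c0=2.116, c1=0.020, c2=2e-5)

#: Typical (population) PK parameter values.
TYPICAL_PK = PKParams(kabs_p0=0.7180, kabs=0.1990, kel=0.0241, v_f=3450.0, k12=0.0259, k21=0.0264)

#: Inter-individual variances of the log-scale random effects.
OMEGA: Mapping[str, float] = {
    "gamma": 0.0579, "kabs_p0": 0.2770, "kel": 0.0092,
    "v_f": 0.0596, "k12": 0.1570, "k21": 3.8600,
}

VAR_CONC = 0.2040    # additive residual variance, concentration scale (ng/mL)^2
VAR_AMOUNT = 0.0002  # additive residual variance, released-amount scale (mg)^2

#: Clinical arm design: (dose mg, batch, n subjects) — 44 ring subjects
#: across two studies (8+8 at 125/375 in one, 10+10+10 at 375/750/1500 in
#: the other).
CLINICAL_ARMS: tuple[Arm, ...] = (
    Arm(dose=125.0, batch="A", n=8, vitro=VITRO_PARAMS[125.0]),
    Arm(dose=375.0, batch="B", n=8, vitro=VITRO_PARAMS[375.0]),
    Arm(dose=375.0, batch="B", n=10, vitro=VITRO_PARAMS[375.0]),
    Arm(dose=750.0, batch="C", n=10, vitro=VITRO_PARAMS[750.0]),
    Arm(dose=1500.0, batch="D", n=10, vitro=VITRO_PARAMS[1500.0]),
)

#: Serum sampling schedule (h post ring insertion).
SERUM_SCHEDULE_H: tuple[float, ...] = (
    0.5, 1, 2, 3, 4, 6, 8, 12, 18, 24, 36, 48, 72, 96, 120, 144, 168, 216, 264, 312, 380, 408,
)

#: Reported matrix-release (Higuchi) rates, mg/day^0.5, per dose/batch.
HIGUCHI_RATES: Mapping[float, float] = {125.0: 44.3, 375.0: 91.7, 750.0: 145.4, 1500.0: 273.1}

#: Provenance of each fixture (descriptive origin, for manifests/reports).
FIXTURE_SOURCES: Mapping[str, str] = {
    "VITRO_PARAMS": "pooled in vitro release-curve fits per dose (burst fixed at the 375 mg value for 750/1500 mg)",
    "IN_VIVO_RELEASED_MG": "mean released amount assayed at ring removal, end of clinical study",
    "IN_VITRO_RELEASED_MG": "mean cumulative amount at the end of the 15-day in vitro release test",
    "GAMMA_BY_DOSE": "per-dose inhibition factors calibrated against end-of-study released amounts",
    "GAMMA_POLY": "ordinary least-squares quadratic through the per-dose inhibition factors",
    "TYPICAL_PK": "population PK typical values estimated from the two clinical studies",
    "OMEGA": "inter-individual log-scale variances from the population fit",
    "VAR_CONC": "additive residual variance of the serum-concentration stream",
    "VAR_AMOUNT": "additive residual variance of the released-amount stream (as printed; see methods note caveat)",
    "CLINICAL_ARMS": "treatment-group design of the two clinical studies",
    "SERUM_SCHEDULE_H": "serum sampling schedule of the clinical studies",
    "HIGUCHI_RATES": "square-root-of-time release rates of the tested ring batches",
}

#: Early sampling points (h) available only for the two lower doses.
_EARLY_POINTS_H: tuple[float, ...] = (1, 2, 4, 6, 7, 8)


def invitro_schedule(dose: float) -> np.ndarray:
    """In vitro sampling times (h): daily to 360 h, plus early points below 375 mg+."""
    base = np.arange(24.0, 361.0, 24.0)
    if dose <= 375.0:
        return np.concatenate([np.array(_EARLY_POINTS_H, dtype=float), base])
    return base


def default_population() -> PopulationParams:
    """Population parameters at the published estimates."""
    return PopulationParams(
        theta=TYPICAL_PK,
        gamma_model=GAMMA_POLY,
        omega=dict(OMEGA),
        var_conc=VAR_CONC,
        var_amount=VAR_AMOUNT,
    )


def gen_invitro_dataset(
    params: InVitroReleaseParams,
    n_rings: int,
    schedule: Sequence[float] | None = None,
    noise_sd: float | None = None,
    rng_seed: int | None = None,
    batch: str = "S",
) -> pd.DataFrame:
    """Synthetic per-ring cumulative release observations.

    Each ring's curve is the pooled release model plus independent additive
    Gaussian assay error (``noise_sd`` defaults to the dose's fitted residual
    SD); noise-induced local non-monotonicity is measurement error and is
    kept, but values are truncated to the physically admissible range
    [0, dose] so every generated dataset satisfies the fitting contract.
    Columns: ring_id, batch, dose_mg, time_h, cumulative_mg.
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    rng = np.random.default_rng(rng_seed)
    t = np.asarray(schedule if schedule is not None else invitro_schedule(params.dose), dtype=float)
    sd = params.residual_sd if noise_sd is None else float(noise_sd)
    clean = eval_cumulative_vitro(params, t)
    rows = []
    for ring in range(1, n_rings + 1):
        y = clean + rng.normal(0.0, sd, size=t.shape) if sd > 0 else clean.copy()
        np.clip(y, 0.0, params.dose, out=y)
        rows.append(pd.DataFrame({
            "ring_id": ring, "batch": batch, "dose_mg": params.dose,
            "time_h": t, "cumulative_mg": y,
        }))
    return pd.concat(rows, ignore_index=True)


def gen_clinical_dataset(
    design: Sequence[Arm] | None = None,
    pop: PopulationParams | None = None,
    schedule: Sequence[float] | None = None,
    rng_seed: int | None = None,
    with_residual: bool = True,
) -> StudyDataset:
    """Synthetic clinical study (concentrations + released amounts).

    Defaults reproduce the original design: the five arms (8/8/10/10/10
    subjects at 125/375/375/750/1500 mg), the serum sampling schedule, and
    the published population parameters.
    """
    design = tuple(design) if design is not None else CLINICAL_ARMS
    pop = pop if pop is not None else default_population()
    schedule = tuple(schedule) if schedule is not None else SERUM_SCHEDULE_H
    return simulate_study(pop, design, schedule, rng_seed=rng_seed, with_residual=with_residual)
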