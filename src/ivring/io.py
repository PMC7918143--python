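"""CSV readers/writers, parameter files and run manifests.

All tabular artifacts are plain CSV with a header; parameter sets travel
as JSON and every stochastic run writes a manifest (inputs, seeds,
decision flags) sufficient to reproduce it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .population import StudyDataset, Subject
from .release import InVitroReleaseParams, VitroFitResult

__all__ = [
    "read_invitro_csv",
    "write_invitro_csv",
    "read_concentration_csv",
    "write_concentration_csv",
    "read_amounts_csv",
    "write_amounts_csv",
    "read_study",
    "write_study",
    "write_vitro_params",
    "read_vitro_params",
    "write_manifest",
    "read_config",
]

_INVITRO_COLS = ["ring_id", "batch", "dose_mg", "time_h", "cumulative_mg"]
_CONC_COLS = ["subject_id", "dose_mg", "batch", "time_h", "conc_ng_ml"]
_AMOUNT_COLS = ["subject_id", "dose_mg", "removal_time_h", "released_mg"]


def _read_table(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in numeric:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric values in column '{col}' at row(s) {rows}")
        df[col] = pd.to_numeric(df[col])
    return df


def read_invitro_csv(path) -> pd.DataFrame:
    return _read_table(path, _INVITRO_COLS, ["dose_mg", "time_h", "cumulative_mg"])


def write_invitro_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=_INVITRO_COLS)


def read_concentration_csv(path) -> pd.DataFrame:
    df = _read_table(path, _CONC_COLS, ["dose_mg", "time_h", "conc_ng_ml"])
    dup = df.duplicated(subset=["subject_id", "time_h"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise ValueError(f"{path}: duplicate (subject_id, time_h) at row(s) {rows}")
    return df


def write_concentration_csv(data: StudyDataset, path) -> None:
    data.concentration_frame().to_csv(path, index=False, columns=_CONC_COLS)


def read_amounts_csv(path) -> pd.DataFrame:
    return _read_table(path, _AMOUNT_COLS, ["dose_mg", "removal_time_h", "released_mg"])


def write_amounts_csv(data: StudyDataset, path) -> None:
    data.amount_frame().to_csv(path, index=False, columns=_AMOUNT_COLS)


def write_study(data: StudyDataset, conc_path, amounts_path) -> None:
    write_concentration_csv(data, conc_path)
    write_amounts_csv(data, amounts_path)


def read_study(conc_path, amounts_path) -> StudyDataset:
    """Assemble a study dataset from its two CSV streams."""
    conc = read_concentration_csv(conc_path)
    amounts = read_amounts_csv(amounts_path).set_index("subject_id")
    subjects = []
    for sid, grp in conc.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_h")
        if sid not in amounts.index:
            raise ValueError(f"subject {sid} has concentrations but no released amount")
        rec = amounts.loc[sid]
        subjects.append(Subject(
            id=str(sid), dose=float(grp["dose_mg"].iloc[0]), batch=str(grp["batch"].iloc[0]),
            times=grp["time_h"].to_numpy(float), conc=grp["conc_ng_ml"].to_numpy(float),
            released_amount=float(rec["released_mg"]), removal_time=float(rec["removal_time_h"]),
        ))
    return StudyDataset(subjects=subjects)


def write_vitro_params(result: VitroFitResult | InVitroReleaseParams, path) -> None:
    if isinstance(result, VitroFitResult):
        p, se, fixed = result.params, result.standard_errors, result.fixed
    else:
        p, se, fixed = result, {}, {}
    payload = {
        "dose_mg": p.dose, "P0_mg": p.P0, "A_mg": p.A, "B_mg": p.B,
        "alpha_per_h": p.alpha, "beta_per_h": p.beta, "residual_sd_mg": p.residual_sd,
        "fixed_flags": fixed, "standard_errors": se,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_vitro_params(path) -> InVitroReleaseParams:
    d = json.loads(Path(path).read_text())
    return InVitroReleaseParams(
        dose=d["dose_mg"], P0=d["P0_mg"], A=d["A_mg"],
        alpha=d["alpha_per_h"], beta=d["beta_per_h"],
        residual_sd=d.get("residual_sd_mg", 0.0),
    )


def write_manifest(path, **entries) -> None:
    """Write a YAML manifest of a run: inputs, seeds, decisions in effect."""

    def clean(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, Mapping):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        return v

    Path(path).write_text(yaml.safe_dump({k: clean(v) for k, v in entries.items()}, sort_keys=False))


def read_config(path) -> dict:
    """Flat key/value configuration file (YAML subset)."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
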