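"""Tidy CSV readers/writers and YAML configuration handling.

Formats (all UTF-8, header row mandatory, "." decimal separator):

* **traces** — one row per sample: subject_id, side, speed_mode,
  hand_present, trial_index, time_s, angle_deg, force_N, emg_mv (optional,
  empty allowed);
* **swe** — one row per image: subject_id, side, angle_deg, trial, image,
  vs_mps, mu_kpa;
* **clinical** — one row per subject: subject_id, sex, affected_side, fma, mas;
* **ground truth** — one row per subject/side/parameter, for recovery tests.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .simulate import (CohortParams, MechParams, SideDistribution,
                       SubjectRecord, SweProfileParams)
from .trace import TraceSeries, Trial, TrialMeta, TrialSet

TRACE_COLUMNS = ["subject_id", "side", "speed_mode", "hand_present",
                 "trial_index", "time_s", "angle_deg", "force_N", "emg_mv"]


def trials_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject trial sets into the tidy trace table."""
    parts = []
    for rec in records:
        for side, ts in rec.trials.items():
            for tr in ts.trials:
                n = tr.trace.n
                part = pd.DataFrame({
                    "subject_id": np.repeat(tr.meta.subject_id, n),
                    "side": np.repeat(side, n),
                    "speed_mode": np.repeat(tr.meta.speed_mode, n),
                    "hand_present": np.repeat(tr.meta.hand_present, n),
                    "trial_index": np.repeat(tr.meta.trial_index, n),
                    "time_s": tr.trace.time,
                    "angle_deg": tr.trace.angle,
                    "force_N": tr.trace.force,
                    "emg_mv": tr.trace.emg if tr.trace.emg is not None
                    else np.full(n, np.nan),
                })
                parts.append(part)
    if not parts:
        raise DataError("no trials to write")
    return pd.concat(parts, ignore_index=True)


def write_traces_csv(records: Iterable[SubjectRecord], path) -> None:
    trials_to_frame(records).to_csv(path, index=False)


def read_traces_csv(path) -> dict:
    """Load a tidy trace CSV into ``{(subject_id, side): TrialSet}``."""
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise DataError(f"trace CSV missing columns: {sorted(missing)}")
    out: dict[tuple[str, str], TrialSet] = {}
    keys = ["subject_id", "side", "speed_mode", "hand_present", "trial_index"]
    for (sid, side, mode, hand, idx), g in df.groupby(keys, sort=True):
        g = g.sort_values("time_s")
        emg = None
        if "emg_mv" in g.columns and g["emg_mv"].notna().all():
            emg = g["emg_mv"].to_numpy()
        trace = TraceSeries(time=g["time_s"].to_numpy(),
                            angle=g["angle_deg"].to_numpy(),
                            force=g["force_N"].to_numpy(), emg=emg)
        meta = TrialMeta(subject_id=str(sid), side=str(side), speed_mode=str(mode),
                         hand_present=bool(hand), trial_index=int(idx))
        out.setdefault((str(sid), str(side)), TrialSet()).trials.append(
            Trial(meta=meta, trace=trace))
    return out


def write_swe_csv(records: Iterable[SubjectRecord], path) -> None:
    pd.concat([rec.swe for rec in records], ignore_index=True).to_csv(path, index=False)


def read_swe_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def clinical_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {"subject_id": rec.subject_id, "sex": rec.sex,
         "affected_side": rec.affected_side, "fma": rec.fma, "mas": rec.mas}
        for rec in records
    ])


def write_clinical_csv(records: Iterable[SubjectRecord], path) -> None:
    clinical_frame(records).to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"mas": str})
    missing = {"subject_id", "fma", "mas"} - set(df.columns)
    if missing:
        raise DataError(f"clinical CSV missing columns: {sorted(missing)}")
    return df


def ground_truth_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for side, (mech, swe_p) in rec.params.items():
            for f in dataclasses.fields(MechParams):
                rows.append((rec.subject_id, side, f.name, getattr(mech, f.name)))
            for f in dataclasses.fields(SweProfileParams):
                rows.append((rec.subject_id, side, f.name, getattr(swe_p, f.name)))
    return pd.DataFrame(rows, columns=["subject_id", "side", "param", "value"])


def write_ground_truth_csv(records: Iterable[SubjectRecord], path) -> None:
    ground_truth_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


def cohort_params_to_dict(cp: CohortParams) -> dict:
    def side_dict(sd: SideDistribution) -> dict:
        return {
            "mech_mean": dataclasses.asdict(sd.mech_mean),
            "mech_sd": dict(sd.mech_sd),
            "swe_mean": dataclasses.asdict(sd.swe_mean),
            "swe_sd": dict(sd.swe_sd),
        }
    return {
        "n_subjects": cp.n_subjects,
        "seed": cp.seed,
        "fma_coupling": cp.fma_coupling,
        "fma_noise_sd": cp.fma_noise_sd,
        "paretic": side_dict(cp.paretic),
        "non_paretic": side_dict(cp.non_paretic),
    }


def cohort_params_from_dict(d: dict) -> CohortParams:
    try:
        def side(sd: dict) -> SideDistribution:
            return SideDistribution(
                mech_mean=MechParams(**sd.get("mech_mean", {})),
                mech_sd=dict(sd.get("mech_sd", {})),
                swe_mean=SweProfileParams(**sd.get("swe_mean", {})),
                swe_sd=dict(sd.get("swe_sd", {})),
            )
        return CohortParams(
            paretic=side(d["paretic"]),
            non_paretic=side(d["non_paretic"]),
            n_subjects=int(d.get("n_subjects", 15)),
            fma_coupling=float(d.get("fma_coupling", 6.0)),
            fma_noise_sd=float(d.get("fma_noise_sd", 12.0)),
            seed=int(d.get("seed", 0)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid cohort configuration: {exc}") from exc


def load_cohort_config(path) -> CohortParams:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError("cohort config must be a YAML mapping")
    return cohort_params_from_dict(data)


def save_cohort_config(cp: CohortParams, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cohort_params_to_dict(cp), fh, sort_keys=True)
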