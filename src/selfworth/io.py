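"""CSV / JSON serialization of trial logs, symptoms and parameters.

Trial logs use a long/tidy CSV (one row per trial) with columns
subject_id, trial, rater_id, group, choice, feedback, probe, rating;
choice and rating cells are empty where absent.  All files are UTF-8,
comma-separated, "." decimal, header mandatory.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cognition import ChoiceParams, SelfWorthParams
from .task import TrialLog

__all__ = [
    "TRIAL_COLUMNS",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials",
    "read_trials",
    "write_symptoms",
    "read_symptoms",
    "write_params",
    "read_params",
]

TRIAL_COLUMNS = ["subject_id", "trial", "rater_id", "group", "choice", "feedback", "probe", "rating"]
PARAM_KEYS = ("eta", "beta", "v0_hi", "v0_lo", "w0", "w1", "gamma", "sigma")


def trials_to_frame(logs: list[TrialLog]) -> pd.DataFrame:
    frames = []
    for log in logs:
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": log.subject_id,
                    "trial": log.trial,
                    "rater_id": log.rater_id,
                    "group": log.group,
                    "choice": log.choice,
                    "feedback": log.feedback,
                    "probe": log.probe.astype(int),
                    "rating": log.rating,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_trials(df: pd.DataFrame) -> list[TrialLog]:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown columns: {extra}", stacklevel=2)
    rating = pd.to_numeric(df["rating"], errors="coerce")
    bad = rating.notna() & ((rating < 0) | (rating > 1))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"rating {rating.iloc[row]} outside [0, 1] at data row {row + 1}"
        )
    logs = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial")
        try:
            logs.append(
                TrialLog(
                    subject_id=str(sid),
                    trial=sub["trial"].to_numpy(dtype=int),
                    rater_id=sub["rater_id"].to_numpy(),
                    group=sub["group"].to_numpy(dtype=int),
                    feedback=pd.to_numeric(sub["feedback"]).to_numpy(dtype=float),
                    probe=sub["probe"].to_numpy(dtype=bool),
                    choice=pd.to_numeric(sub["choice"], errors="coerce").to_numpy(dtype=float),
                    rating=pd.to_numeric(sub["rating"], errors="coerce").to_numpy(dtype=float),
                )
            )
        except ValueError as exc:
            raise ValueError(f"invalid trial log for subject {sid!r}: {exc}") from exc
    return logs


def write_trials(logs: list[TrialLog], path: str | Path) -> None:
    trials_to_frame(logs).to_csv(path, index=False)


def read_trials(path: str | Path) -> list[TrialLog]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input file: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"no trial rows in {path}")
    return frame_to_trials(df)


def write_symptoms(symptoms: pd.DataFrame, path: str | Path) -> None:
    symptoms.to_csv(path, index=False)


def read_symptoms(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise ValueError("symptoms CSV must have a subject_id column")
    if df.empty:
        raise ValueError(f"no symptom rows in {path}")
    return df


def write_params(choice: ChoiceParams, worth: SelfWorthParams | None, path: str | Path) -> None:
    payload = {"eta": choice.eta, "beta": choice.beta, "v0_hi": choice.v0_hi, "v0_lo": choice.v0_lo}
    if worth is not None:
        payload.update(w0=worth.w0, w1=worth.w1, gamma=worth.gamma, sigma=worth.sigma)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_params(path: str | Path) -> tuple[ChoiceParams, SelfWorthParams | None]:
    data = json.loads(Path(path).read_text())
    unknown = set(data) - set(PARAM_KEYS)
    if unknown:
        warnings.warn(f"ignoring unknown parameter keys: {sorted(unknown)}", stacklevel=2)
    choice = ChoiceParams(eta=data["eta"], beta=data["beta"], v0_hi=data["v0_hi"], v0_lo=data["v0_lo"])
    worth = None
    if "w0" in data:
        worth = SelfWorthParams(w0=data["w0"], w1=data["w1"], gamma=data["gamma"], sigma=data["sigma"])
    return choice, worth
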