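"""File formats, trial segmentation, and run configuration.

Plain-CSV formats (UTF-8, header row, '.' decimal, coordinates in cm with
the origin at the tablet's lower-left corner, y up):

* **pen-sample CSV** — ``participant_id, t_s, x_cm, y_cm, pen_down``:
  the raw recording stream; segmented into trials by pen lifts longer
  than 500 ms.
* **trajectory CSV** — ``participant_id, trial, t_s, x_cm, y_cm``:
  per-trial trajectories.
* **trial-summary CSV** — ``participant_id, trial, radius_cm, target_cm,
  rel_error, rewarded, aspect_ratio, path_length_cm, is_circular``.
* **participants CSV** — ``participant_id, group, age, handedness,
  language``.
* **participant-summary CSV** — one row per participant with every
  derived outcome measure; missing medians are empty fields.

Numeric fields are serialized at 6 significant digits, which makes the
native write-read round trip stable at that precision.  Readers are
table-driven by a *dialect descriptor* (a mapping of canonical field
names to file columns plus unit scaling) so that adapting to a foreign
layout is data, not code; only the "native" descriptor ships built in.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import RawTrajectory, TrialGeometry
from .metrics import ParticipantSummary, Session
from .task_engine import TrialRecord

__all__ = [
    "LIFT_THRESHOLD_S",
    "SchemaError",
    "ConfigurationError",
    "RunConfig",
    "load_config",
    "config_hash",
    "register_dialect",
    "segment_trials",
    "read_pen_samples",
    "write_trajectories",
    "read_trajectories",
    "write_trial_summaries",
    "read_sessions",
    "write_participants",
    "write_summaries",
    "read_summaries",
    "write_results",
]

logger = logging.getLogger("circledraw")

#: Pen lifts longer than this many seconds end a trial.
LIFT_THRESHOLD_S = 0.5

#: Significant digits for serialized floats.
FLOAT_DIGITS = 6


class SchemaError(ValueError):
    """A file does not match the expected schema."""


class ConfigurationError(ValueError):
    """A configuration file or dialect request is invalid."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of an analysis or simulation run."""

    initial_target_cm: float = 4.3
    multiplier: float = 2.0
    n_baseline_trials: int = 5
    n_trials: int = 80
    window_size: int = 10
    order_index: int = 5
    cold_start_threshold: float = 1.0
    recompute_errors_on_target_switch: bool = True
    lift_threshold_s: float = LIFT_THRESHOLD_S
    n_agents: int = 100
    agent_params: str = "reference"  # named set in learner_sim
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a JSON run configuration."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a JSON object")
    return RunConfig.from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of a configuration, for run provenance logs."""
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Dialects
# ---------------------------------------------------------------------------

_NATIVE_TRIAL_COLUMNS = {
    "participant_id": "participant_id",
    "trial": "trial",
    "radius_cm": "radius_cm",
    "target_cm": "target_cm",
    "rel_error": "rel_error",
    "rewarded": "rewarded",
    "aspect_ratio": "aspect_ratio",
    "path_length_cm": "path_length_cm",
    "is_circular": "is_circular",
}

#: Registered dialect descriptors for the trial-summary reader.  A
#: descriptor maps canonical field names to file columns and gives the
#: multiplicative factor converting length units to cm.
_DIALECTS: dict[str, dict] = {
    "native": {"columns": dict(_NATIVE_TRIAL_COLUMNS), "length_scale": 1.0},
}


def register_dialect(name: str, descriptor: Union[dict, str, Path]) -> None:
    """Register a trial-summary dialect descriptor (dict or JSON file).

    The descriptor must contain ``columns`` (canonical -> file column)
    and may contain ``length_scale`` (units-to-cm factor, default 1).
    """
    if not isinstance(descriptor, dict):
        with open(descriptor, encoding="utf-8") as fh:
            descriptor = json.load(fh)
    if "columns" not in descriptor:
        raise ConfigurationError("dialect descriptor needs a 'columns' mapping")
    missing = set(_NATIVE_TRIAL_COLUMNS) - set(descriptor["columns"])
    if missing:
        raise ConfigurationError(f"dialect descriptor misses fields: {sorted(missing)}")
    _DIALECTS[name] = {
        "columns": dict(descriptor["columns"]),
        "length_scale": float(descriptor.get("length_scale", 1.0)),
    }


def _get_dialect(name: str) -> dict:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown dialect {name!r}; registered: {sorted(_DIALECTS)}. "
            "Foreign layouts (e.g. a deposited data set) require a descriptor "
            "registered via register_dialect()."
        ) from None


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_trials(
    t: Sequence[float],
    x: Sequence[float],
    y: Sequence[float],
    pen_down: Sequence[bool],
    lift_threshold: float = LIFT_THRESHOLD_S,
) -> list[RawTrajectory]:
    """Split a pen-sample stream into per-trial trajectories.

    A trial starts when the pen touches the tablet and ends once it is
    lifted for *longer than* ``lift_threshold`` seconds (strict): shorter
    lifts are merged into the same trial.  The lift duration is the time
    between consecutive pen-down samples, which also covers recordings
    that simply stop sampling while the pen is in the air.  Pen-up
    samples are dropped; runs shorter than two samples are discarded.
    An empty stream yields an empty list.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    down = np.asarray(pen_down, dtype=bool)
    if not (len(t) == len(x) == len(y) == len(down)):
        raise SchemaError("pen-sample arrays must have equal length")
    if len(t) == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise SchemaError("pen-sample times must be nondecreasing")

    idx = np.flatnonzero(down)
    if len(idx) == 0:
        return []
    # a new trial starts wherever the pen was away strictly longer than
    # the threshold (strict: an exactly-threshold lift still merges)
    breaks = np.flatnonzero(np.diff(t[idx]) > lift_threshold)
    out: list[RawTrajectory] = []
    for run in np.split(idx, breaks + 1):
        if len(run) >= 2:
            out.append(RawTrajectory(t=t[run], x=x[run], y=y[run]))
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _fmt(v: float) -> str:
    if isinstance(v, float) and math.isnan(v):
        return ""
    return f"{v:.{FLOAT_DIGITS}g}"


def read_pen_samples(path: Union[str, Path]) -> pd.DataFrame:
    """Read a pen-sample CSV; validates schema and time ordering."""
    df = pd.read_csv(path)
    _check_columns(df, ["participant_id", "t_s", "x_cm", "y_cm", "pen_down"], path)
    for pid, grp in df.groupby("participant_id"):
        dt = np.diff(grp["t_s"].to_numpy(dtype=float))
        if np.any(dt < 0):
            row = int(grp.index[np.flatnonzero(dt < 0)[0] + 1]) + 2  # header + 1-base
            raise SchemaError(f"{path}, line {row}: time goes backwards for {pid!r}")
    return df


def write_trajectories(
    path: Union[str, Path],
    trials: Sequence[RawTrajectory],
    participant_id: str,
    mode: str = "w",
) -> None:
    """Write per-trial trajectories as CSV (appendable across participants)."""
    frames = [
        pd.DataFrame(
            {
                "participant_id": participant_id,
                "trial": i,
                "t_s": traj.t,
                "x_cm": traj.x,
                "y_cm": traj.y,
            }
        )
        for i, traj in enumerate(trials, start=1)
    ]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, mode=mode, header=(mode == "w"),
              float_format=f"%.{FLOAT_DIGITS}g")


def read_trajectories(
    path: Union[str, Path],
) -> dict[str, list[RawTrajectory]]:
    """Read a trajectory CSV into per-participant ordered trial lists."""
    df = pd.read_csv(path)
    _check_columns(df, ["participant_id", "trial", "t_s", "x_cm", "y_cm"], path)
    out: dict[str, list[RawTrajectory]] = {}
    for pid, grp in df.groupby("participant_id", sort=False):
        trials = []
        for _, tg in grp.groupby("trial", sort=True):
            trials.append(
                RawTrajectory(
                    t=tg["t_s"].to_numpy(dtype=float),
                    x=tg["x_cm"].to_numpy(dtype=float),
                    y=tg["y_cm"].to_numpy(dtype=float),
                )
            )
        out[str(pid)] = trials
    return out


def write_trial_summaries(
    path: Union[str, Path], sessions: Sequence[Session]
) -> None:
    """Write one trial-summary row per trial across sessions."""
    rows = []
    for s in sessions:
        for rec in s.trials:
            g = rec.geometry
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "trial": rec.index,
                    "radius_cm": _fmt(rec.radius),
                    "target_cm": _fmt(rec.target_radius),
                    "rel_error": _fmt(rec.relative_error),
                    "rewarded": int(rec.rewarded),
                    "aspect_ratio": _fmt(g.aspect_ratio) if g else "",
                    "path_length_cm": _fmt(g.path_length) if g else "",
                    "is_circular": int(g.is_circular) if g else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_participants(path: Union[str, Path], sessions: Sequence[Session]) -> None:
    """Write the participant-metadata CSV for a collection of sessions."""
    pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "group": s.group,
                "age": s.age,
                "handedness": s.handedness,
                "language": s.language,
            }
            for s in sessions
        ]
    ).to_csv(path, index=False)


def read_sessions(
    path: Union[str, Path],
    participants: Optional[Union[str, Path]] = None,
    dialect: str = "native",
) -> list[Session]:
    """Read a trial-summary CSV (plus optional metadata) into sessions.

    ``dialect`` selects a registered descriptor mapping the file's
    columns to the canonical schema.  Without a participants CSV every
    session gets placeholder adult metadata.  Geometry fields present in
    the summary (aspect ratio, path length, circularity) are restored;
    quantities not part of the schema (centers) read back as NaN.
    """
    desc = _get_dialect(dialect)
    cols = desc["columns"]
    scale = desc["length_scale"]
    df = pd.read_csv(path)
    _check_columns(df, list(cols.values()), path)

    meta: dict[str, dict] = {}
    if participants is not None:
        pdf = pd.read_csv(participants)
        _check_columns(
            pdf, ["participant_id", "group", "age", "handedness", "language"], participants
        )
        meta = {
            str(r.participant_id): {
                "group": str(r.group),
                "age": int(r.age),
                "handedness": str(r.handedness),
                "language": str(r.language),
            }
            for r in pdf.itertuples()
        }

    sessions: list[Session] = []
    for pid, grp in df.groupby(cols["participant_id"], sort=False):
        grp = grp.sort_values(cols["trial"])
        records = []
        for ln, row in grp.iterrows():
            try:
                aspect = row[cols["aspect_ratio"]]
                has_geom = pd.notna(aspect)
                geom = None
                if has_geom:
                    geom = TrialGeometry(
                        center=(math.nan, math.nan),
                        radius=float(row[cols["radius_cm"]]) * scale,
                        aspect_ratio=float(aspect),
                        path_length=float(row[cols["path_length_cm"]]) * scale,
                        start_end_distance=math.nan,
                        is_circular=bool(int(row[cols["is_circular"]])),
                    )
                records.append(
                    TrialRecord(
                        index=int(row[cols["trial"]]),
                        radius=float(row[cols["radius_cm"]]) * scale,
                        target_radius=float(row[cols["target_cm"]]) * scale,
                        relative_error=float(row[cols["rel_error"]]),
                        rewarded=bool(int(row[cols["rewarded"]])),
                        geometry=geom,
                    )
                )
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}, line {int(ln) + 2}: bad value ({exc})"
                ) from exc
        m = meta.get(
            str(pid),
            {"group": "adult", "age": 30, "handedness": "right", "language": "dutch"},
        )
        sessions.append(Session(participant_id=str(pid), trials=records, **m))
    return sessions


_SUMMARY_FIELDS = [
    "participant_id",
    "group",
    "age",
    "baseline_radius",
    "fraction_learned",
    "median_ratio_after_reward",
    "median_ratio_after_no_reward",
    "success_frequency",
    "pct_noncircular",
    "excluded",
]


def write_summaries(
    path: Union[str, Path], summaries: Sequence[ParticipantSummary]
) -> None:
    """Write the participant-summary CSV (missing medians as empty)."""
    rows = []
    for s in summaries:
        row = dataclasses.asdict(s)
        for k, v in row.items():
            if isinstance(v, float):
                row[k] = _fmt(v)
        row["excluded"] = int(s.excluded)
        rows.append(row)
    pd.DataFrame(rows, columns=_SUMMARY_FIELDS).to_csv(path, index=False)


def read_summaries(path: Union[str, Path]) -> pd.DataFrame:
    """Read a participant-summary CSV into a DataFrame."""
    df = pd.read_csv(path)
    _check_columns(df, _SUMMARY_FIELDS, path)
    df["excluded"] = df["excluded"].astype(bool)
    return df


def write_results(path: Union[str, Path], results: dict) -> None:
    """Write an analysis-results JSON (sorted keys, 2-space indent)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")
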