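"""File formats: model YAML, trajectory / observation CSV, scan-spec YAML.

All files are plain text: UTF-8 CSV with a mandatory header row and '.'
decimals, YAML for configuration, JSON for machine-readable reports.
Write-then-read round trips preserve values to full float precision.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ModelValidationError
from .fitting import ConditionObs, GridRange, ObservationSet, ScanSpec
from .model import GrowthTransitionModel
from .simulate import Trajectory
from .synthetic import SortingDesign

__all__ = [
    "read_model",
    "write_model",
    "bundled_model",
    "write_trajectory",
    "read_trajectory",
    "write_observations",
    "read_observations",
    "read_scan_spec",
    "read_design",
]

TRAJECTORY_COLUMNS = ["time_days", "phenotype", "count", "fraction"]
OBSERVATION_COLUMNS = ["condition", "time_days", "phenotype", "fraction"]


def _load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ModelValidationError(f"file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ModelValidationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ModelValidationError(f"{path} does not contain a mapping")
    return data


def read_model(path) -> GrowthTransitionModel:
    """Read a growth-transition model from its YAML schema.

    ``{"labels": [...], "growth": {label: rate},
    "transitions": {"from->to": rate}}``; omitted transitions are zero,
    unknown labels and malformed keys are hard errors.
    """
    return GrowthTransitionModel.from_dict(_load_yaml(path))


def write_model(model: GrowthTransitionModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def bundled_model(name: str) -> GrowthTransitionModel:
    """A model shipped with the package (``"sum159"`` or ``"sum149"``)."""
    ref = resources.files("phenokin.data") / f"{name.lower()}.yaml"
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ModelValidationError(f"no bundled model named {name!r}") from None
    return GrowthTransitionModel.from_dict(yaml.safe_load(text))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as tidy CSV (time_days, phenotype, count,
    fraction)."""
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    """Read a tidy trajectory CSV back into a Trajectory."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ModelValidationError(f"trajectory file missing columns {missing}")
    if df.empty:
        return Trajectory(labels=(), times=np.empty(0),
                          counts=np.empty((0, 0)), fractions=np.empty((0, 0)))
    labels = tuple(df["phenotype"].drop_duplicates())
    times = np.asarray(df["time_days"].drop_duplicates(), dtype=float)
    m, nt = len(labels), times.size
    if len(df) != m * nt:
        raise ModelValidationError(
            f"trajectory file is not a complete grid: {len(df)} rows for "
            f"{nt} times x {m} phenotypes"
        )
    counts = df["count"].to_numpy(float).reshape(nt, m)
    fractions = df["fraction"].to_numpy(float).reshape(nt, m)
    bad = np.abs(fractions.sum(axis=1) - 1.0) > 1e-6
    if np.any(bad):
        t = times[np.flatnonzero(bad)[0]]
        raise ModelValidationError(
            f"fractions at time {t} sum to {fractions[bad][0].sum():.6g}, "
            "expected 1"
        )
    return Trajectory(labels=labels, times=times, counts=counts,
                      fractions=fractions)


def write_observations(obs: ObservationSet, path) -> None:
    """Write an observation set as tidy CSV (condition, time_days,
    phenotype, fraction); the day-0 row holds each condition's initial
    composition."""
    rows = []
    for cond in obs.conditions:
        for i, lab in enumerate(obs.labels):
            rows.append((cond.name, 0.0, lab, cond.x0[i]))
        for t_idx, t in enumerate(cond.times):
            for i, lab in enumerate(obs.labels):
                rows.append((cond.name, t, lab, cond.fractions[t_idx, i]))
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


def read_observations(path) -> ObservationSet:
    """Read a tidy observations CSV.

    Day-0 rows are required for every condition and become its initial
    composition; later rows are the fitted observations.  Every composition
    must lie on the simplex within 1e-6.
    """
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ModelValidationError(f"observations file missing columns {missing}")
    if df.empty:
        raise ModelValidationError("observations file has no rows")
    labels = tuple(df["phenotype"].drop_duplicates())
    conditions = []
    for name, group in df.groupby("condition", sort=False):
        piv = group.pivot_table(index="time_days", columns="phenotype",
                                values="fraction", sort=True)
        piv = piv.reindex(columns=list(labels))
        if piv.isna().any().any():
            raise ModelValidationError(
                f"condition {name!r} has missing phenotype rows"
            )
        times = piv.index.to_numpy(float)
        if times.size == 0 or times[0] != 0.0:
            raise ModelValidationError(
                f"condition {name!r} has no day-0 composition"
            )
        fr = piv.to_numpy(float)
        conditions.append(
            ConditionObs(name=str(name), x0=fr[0], times=times[1:],
                         fractions=fr[1:])
        )
    return ObservationSet(labels=labels, conditions=tuple(conditions))


def read_scan_spec(path) -> ScanSpec:
    """Read a scan specification YAML.

    Schema::

        labels: [A, B, ...]
        params:
          "g:A": 0.7                   # fixed
          "k:A->B": {min: 0, max: 1, step: 0.05}   # scanned
        feasibility:
          eigen_sign: positive         # positive | negative | none
          require_survivable: false
        objective: sse                 # sse | l1
    """
    data = _load_yaml(path)
    if "labels" not in data or "params" not in data:
        raise ModelValidationError("scan spec requires 'labels' and 'params'")
    params = {}
    for name, v in data["params"].items():
        if isinstance(v, dict):
            try:
                params[name] = GridRange(float(v["min"]), float(v["max"]),
                                         float(v["step"]))
            except KeyError as exc:
                raise ModelValidationError(
                    f"parameter {name!r} range needs min/max/step"
                ) from exc
        else:
            params[name] = float(v)
    feas = data.get("feasibility") or {}
    sign = feas.get("eigen_sign", "positive")
    if sign in ("none", "None"):
        sign = None
    return ScanSpec(
        labels=tuple(data["labels"]),
        params=params,
        eigen_sign=sign,
        require_survivable=bool(feas.get("require_survivable", False)),
        objective=data.get("objective", "sse"),
    )


def read_design(path) -> SortingDesign:
    """Read a sorting-experiment design YAML
    (``timepoints``, optional ``starts``/``purity``/``include_counts``)."""
    data = _load_yaml(path)
    if "timepoints" not in data:
        raise ModelValidationError("design requires 'timepoints'")
    return SortingDesign(
        timepoints=tuple(data["timepoints"]),
        starts=tuple(data["starts"]) if data.get("starts") else None,
        purity=float(data.get("purity", 1.0)),
        include_counts=bool(data.get("include_counts", False)),
    )
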