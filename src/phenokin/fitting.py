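"""Parameter estimation by exhaustive grid scanning.

The inverse problem — recover growth and transition rates from sorted-start
composition time courses — is solved the way it is posed experimentally: a
Cartesian grid over the free rates is evaluated exhaustively against the
observed fraction compositions, keeping only candidates that pass the
feasibility criteria (coexistence requires all eigenvalue real parts to
share a sign; optionally every phenotype must be independently survivable).

The objective is the summed squared difference between simulated and
observed fraction vectors over all conditions and timepoints (an L1 variant
is available).  Day-0 compositions define the initial condition of each
sorted culture and are not fitted.

Because fraction data are invariant under a uniform shift of all growth
rates (``T -> T + cI`` rescales every count by the same factor), absolute
growth rates are not identifiable from compositions alone; the fit reports
this degeneracy unless total-count fold-change observations are supplied.

Scans are deterministic: the grid is enumerated in lexicographic order and
ties are broken toward the lexicographically smallest parameter tuple, so
the result is independent of chunking and worker count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.linalg import expm

from .errors import InfeasibleScanError, ModelValidationError
from .model import GrowthTransitionModel, build_system_matrix
from .multistate import _validate_simplex
from .simulate import integrate

__all__ = [
    "GridRange",
    "ScanSpec",
    "ConditionObs",
    "ObservationSet",
    "FitResult",
    "objective",
    "feasibility_filter",
    "grid_scan",
]

logger = logging.getLogger(__name__)

_CHUNK = 65536


@dataclass(frozen=True)
class GridRange:
    """Inclusive scan range ``min, min+step, ..., <= max``."""

    min: float
    max: float
    step: float

    def __post_init__(self):
        if not (math.isfinite(self.min) and math.isfinite(self.max)
                and math.isfinite(self.step)):
            raise ModelValidationError(f"non-finite grid range {self}")
        if self.min > self.max:
            raise ModelValidationError(f"grid range has min > max: {self}")
        if self.step <= 0:
            raise ModelValidationError(f"grid step must be positive: {self}")

    def values(self) -> np.ndarray:
        n = int(math.floor((self.max - self.min) / self.step + 1e-9)) + 1
        # round to kill accumulation error so on-grid truths compare exactly
        return np.round(self.min + self.step * np.arange(n), 12)


def _parse_param(name: str, labels: Sequence[str]):
    """Return ('g', i) or ('k', i, j) for a parameter name."""
    if name.startswith("g:"):
        lab = name[2:].strip()
        if lab not in labels:
            raise ModelValidationError(f"unknown label in parameter {name!r}")
        return ("g", labels.index(lab))
    if name.startswith("k:"):
        parts = name[2:].split("->")
        if len(parts) != 2:
            raise ModelValidationError(
                f"malformed parameter {name!r}; expected 'k:A->B'"
            )
        a, b = (p.strip() for p in parts)
        for lab in (a, b):
            if lab not in labels:
                raise ModelValidationError(f"unknown label in parameter {name!r}")
        if a == b:
            raise ModelValidationError(f"self-transition parameter {name!r}")
        return ("k", labels.index(a), labels.index(b))
    raise ModelValidationError(
        f"parameter {name!r} must start with 'g:' or 'k:'"
    )


@dataclass(frozen=True)
class ScanSpec:
    """Grid-scan specification.

    ``params`` maps parameter names (``"g:<label>"`` or ``"k:<A>-><B>"``) to
    either a fixed float or a :class:`GridRange`.  Every growth rate and
    every transition rate of the model must be named (transitions omitted
    entirely default to a fixed 0).  Feasibility: ``eigen_sign`` restricts
    candidates to all-positive ("positive") or all-negative ("negative")
    eigenvalue real parts, or no restriction (``None``);
    ``require_survivable`` additionally demands every phenotype's growth
    exceed its conversion outflow.
    """

    labels: tuple
    params: Mapping
    eigen_sign: str | None = "positive"
    require_survivable: bool = False
    objective: str = "sse"

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ModelValidationError("need at least 2 phenotype labels")
        if self.eigen_sign not in (None, "positive", "negative"):
            raise ModelValidationError(
                f"eigen_sign must be 'positive', 'negative' or None, "
                f"got {self.eigen_sign!r}"
            )
        if self.objective not in ("sse", "l1"):
            raise ModelValidationError(
                f"objective must be 'sse' or 'l1', got {self.objective!r}"
            )
        params = dict(self.params)
        for name, v in params.items():
            _parse_param(name, self.labels)
            if not isinstance(v, GridRange):
                params[name] = float(v)
        for lab in self.labels:
            if f"g:{lab}" not in params:
                raise ModelValidationError(f"missing parameter 'g:{lab}'")
        object.__setattr__(self, "params", params)

    @property
    def scanned(self) -> list:
        return [n for n, v in self.params.items() if isinstance(v, GridRange)]

    @property
    def fixed(self) -> dict:
        return {n: v for n, v in self.params.items()
                if not isinstance(v, GridRange)}

    @property
    def grid_size(self) -> int:
        n = 1
        for name in self.scanned:
            n *= self.params[name].values().size
        return n

    def model_from(self, values: Mapping) -> GrowthTransitionModel:
        """Build the model for one assignment of the scanned parameters."""
        m = len(self.labels)
        g = np.zeros(m)
        k = np.zeros((m, m))
        assignment = {**self.fixed, **dict(values)}
        for name, v in assignment.items():
            parsed = _parse_param(name, self.labels)
            if parsed[0] == "g":
                g[parsed[1]] = v
            else:
                k[parsed[1], parsed[2]] = v
        return GrowthTransitionModel(labels=self.labels, growth=g, transitions=k)


@dataclass(frozen=True)
class ConditionObs:
    """Observations for one sorted-start condition.

    ``x0`` is the day-0 composition (the initial condition, not a fitted
    point); ``times`` are the strictly positive observation days with one
    simplex ``fractions`` row each.  ``fold_changes``, if given, are total
    cell counts relative to day 0 at the same times.
    """

    name: str
    x0: np.ndarray
    times: np.ndarray
    fractions: np.ndarray
    fold_changes: np.ndarray | None = None

    def __post_init__(self):
        x0 = _validate_simplex(self.x0, atol=1e-6).copy()
        t = np.asarray(self.times, dtype=float)
        fr = np.asarray(self.fractions, dtype=float)
        if t.ndim != 1 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ModelValidationError(
                f"condition {self.name!r}: observation times must be "
                "positive and strictly increasing"
            )
        if fr.shape != (t.size, x0.size):
            raise ModelValidationError(
                f"condition {self.name!r}: fractions shape {fr.shape} does "
                f"not match {(t.size, x0.size)}"
            )
        for row in fr:
            _validate_simplex(row, atol=1e-6)
        for arr in (x0, t, fr):
            arr.setflags(write=False)
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", fr)
        if self.fold_changes is not None:
            fc = np.asarray(self.fold_changes, dtype=float)
            if fc.shape != t.shape or np.any(fc <= 0):
                raise ModelValidationError(
                    f"condition {self.name!r}: fold_changes must be positive "
                    "and aligned with the observation times"
                )
            fc.setflags(write=False)
            object.__setattr__(self, "fold_changes", fc)


@dataclass(frozen=True)
class ObservationSet:
    """Fraction observations across sorted-start conditions."""

    labels: tuple
    conditions: tuple

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        conds = tuple(self.conditions)
        if not conds:
            raise ModelValidationError("observation set has no conditions")
        m = len(self.labels)
        for c in conds:
            if c.x0.size != m:
                raise ModelValidationError(
                    f"condition {c.name!r} has {c.x0.size} phenotypes, "
                    f"expected {m}"
                )
        object.__setattr__(self, "conditions", conds)

    @property
    def has_counts(self) -> bool:
        return any(c.fold_changes is not None for c in self.conditions)


def objective(model: GrowthTransitionModel, obs: ObservationSet,
              metric: str = "sse") -> float:
    """Misfit of a candidate model against the observations.

    Sum over conditions and timepoints of squared (or absolute, for
    ``metric='l1'``) differences between simulated and observed fraction
    vectors; exactly zero iff the simulation matches every observation.
    """
    if metric not in ("sse", "l1"):
        raise ModelValidationError(f"unknown metric {metric!r}")
    if tuple(model.labels) != tuple(obs.labels):
        raise ModelValidationError(
            f"model labels {model.labels} do not match observation labels "
            f"{obs.labels}"
        )
    total = 0.0
    for cond in obs.conditions:
        traj = integrate(model, cond.x0, cond.times)
        diff = traj.fractions - cond.fractions
        if metric == "sse":
            total += float(np.sum(diff * diff))
        else:
            total += float(np.sum(np.abs(diff)))
    return total


@dataclass(frozen=True)
class FeasibilityCriteria:
    eigen_sign: str | None = "positive"
    require_survivable: bool = False


def feasibility_filter(model: GrowthTransitionModel,
                       criteria: FeasibilityCriteria | None = None) -> bool:
    """True iff the model passes the configured coexistence criteria."""
    if criteria is None:
        criteria = FeasibilityCriteria()
    T = build_system_matrix(model).T
    tol = 1e-12 * max(1.0, np.linalg.norm(T, 1))
    re = np.linalg.eigvals(T).real
    if criteria.eigen_sign == "positive" and not np.all(re > tol):
        return False
    if criteria.eigen_sign == "negative" and not np.all(re < -tol):
        return False
    if criteria.require_survivable:
        if not np.all((model.outflow == 0) | (model.growth > model.outflow)):
            return False
    return True


@dataclass(frozen=True)
class FitResult:
    """Outcome of a grid scan."""

    best_params: dict
    best_model: GrowthTransitionModel
    objective_value: float
    shortlist: list
    diagnostics: dict = field(default_factory=dict)


def _prepare_arrays(spec: ScanSpec, obs: ObservationSet):
    m = len(spec.labels)
    base_T = np.zeros((m, m))
    base_G = np.zeros(m)
    base_out = np.zeros(m)
    for name, v in spec.fixed.items():
        parsed = _parse_param(name, spec.labels)
        if parsed[0] == "g":
            base_T[parsed[1], parsed[1]] += v
            base_G[parsed[1]] += v
        else:
            i, j = parsed[1], parsed[2]
            base_T[j, i] += v
            base_T[i, i] -= v
            base_out[i] += v
    scan_effects = []
    for name in spec.scanned:
        parsed = _parse_param(name, spec.labels)
        scan_effects.append(parsed)
    times = sorted({float(t) for c in obs.conditions for t in c.times})
    cond_data = [
        (c.x0, {float(t): c.fractions[i] for i, t in enumerate(c.times)})
        for c in obs.conditions
    ]
    return base_T, base_G, base_out, scan_effects, times, cond_data


def _evaluate_chunk(start, stop, axes, base_T, base_G, base_out, scan_effects,
                    times, cond_data, eigen_sign, require_survivable, metric,
                    shortlist_size):
    m = base_T.shape[0]
    idx = np.unravel_index(np.arange(start, stop),
                           tuple(a.size for a in axes))
    n = stop - start
    vals = np.empty((n, len(axes)))
    for d, a in enumerate(axes):
        vals[:, d] = a[idx[d]]
    T = np.broadcast_to(base_T, (n, m, m)).copy()
    G = np.broadcast_to(base_G, (n, m)).copy()
    out = np.broadcast_to(base_out, (n, m)).copy()
    for d, parsed in enumerate(scan_effects):
        v = vals[:, d]
        if parsed[0] == "g":
            i = parsed[1]
            T[:, i, i] += v
            G[:, i] += v
        else:
            i, j = parsed[1], parsed[2]
            T[:, j, i] += v
            T[:, i, i] -= v
            out[:, i] += v

    tol = 1e-12 * np.maximum(1.0, np.abs(T).sum(axis=1).max(axis=1))
    re = np.linalg.eigvals(T).real
    feasible = np.ones(n, dtype=bool)
    violations = {}
    if eigen_sign == "positive":
        ok = np.all(re > tol[:, None], axis=1)
        violations["eigen_sign"] = int(np.count_nonzero(~ok))
        feasible &= ok
    elif eigen_sign == "negative":
        ok = np.all(re < -tol[:, None], axis=1)
        violations["eigen_sign"] = int(np.count_nonzero(~ok))
        feasible &= ok
    if require_survivable:
        ok = np.all((out == 0) | (G > out), axis=1)
        violations["survivability"] = int(np.count_nonzero(~ok))
        feasible &= ok

    n_feas = int(np.count_nonzero(feasible))
    if n_feas == 0:
        return None, [], 0, violations
    Tf = T[feasible]
    obj = np.zeros(n_feas)
    for t in times:
        M = expm(Tf * t)
        for x0, frames in cond_data:
            target = frames.get(t)
            if target is None:
                continue
            counts = M @ x0
            fr = counts / counts.sum(axis=1, keepdims=True)
            diff = fr - target
            if metric == "sse":
                obj += np.sum(diff * diff, axis=1)
            else:
                obj += np.sum(np.abs(diff), axis=1)

    feas_pos = np.flatnonzero(feasible)
    # flat index order is lexicographic in the parameter tuple, so the first
    # minimum is the lexicographically smallest tie
    k = min(shortlist_size, n_feas)
    part = np.argpartition(obj, k - 1)[:k]
    part = part[np.lexsort((feas_pos[part], obj[part]))]
    shortlist = [
        (float(obj[i]), tuple(vals[feas_pos[i]])) for i in part
    ]
    best = shortlist[0]
    return best, shortlist, n_feas, violations


def grid_scan(spec: ScanSpec, obs: ObservationSet, *, n_jobs: int = 1,
              shortlist_size: int = 10, chunk_size: int = _CHUNK) -> FitResult:
    """Exhaustively evaluate the scan grid and return the best fit.

    The full Cartesian grid is enumerated (size logged before execution),
    infeasible candidates are excluded, and the remaining ones are scored
    with the configured objective.  The result is deterministic and
    independent of ``n_jobs`` and ``chunk_size``; ties are broken toward the
    lexicographically smallest parameter tuple.

    Raises
    ------
    InfeasibleScanError
        If no grid point passes the feasibility criteria (the per-criterion
        rejection counts are attached).
    """
    if tuple(spec.labels) != tuple(obs.labels):
        raise ModelValidationError(
            f"scan labels {spec.labels} do not match observation labels "
            f"{obs.labels}"
        )
    axes = [spec.params[name].values() for name in spec.scanned]
    total = spec.grid_size
    logger.info("grid scan: %d parameters, %d grid points", len(axes), total)
    if total == 0:
        raise ModelValidationError("scan grid is empty")
    base_T, base_G, base_out, scan_effects, times, cond_data = _prepare_arrays(
        spec, obs
    )
    bounds = list(range(0, total, chunk_size)) + [total]
    jobs = (
        delayed(_evaluate_chunk)(
            bounds[i], bounds[i + 1], axes, base_T, base_G, base_out,
            scan_effects, times, cond_data, spec.eigen_sign,
            spec.require_survivable, spec.objective, shortlist_size,
        )
        for i in range(len(bounds) - 1)
    )
    results = Parallel(n_jobs=n_jobs, prefer="threads")(jobs)

    n_feasible = 0
    violations = {}
    merged = []
    for best, shortlist, nf, viol in results:
        n_feasible += nf
        for key, v in viol.items():
            violations[key] = violations.get(key, 0) + v
        merged.extend(shortlist)
    if n_feasible == 0:
        raise InfeasibleScanError(
            f"no feasible grid point among {total}; rejections: {violations}",
            violation_counts=violations,
        )
    merged.sort(key=lambda item: (item[0], item[1]))
    merged = merged[:shortlist_size]
    best_obj, best_tuple = merged[0]
    names = spec.scanned
    best_params = {n: float(v) for n, v in zip(names, best_tuple)}
    best_model = spec.model_from(best_params)
    shortlist = [
        ({n: float(v) for n, v in zip(names, tup)}, float(o))
        for o, tup in merged
    ]
    diagnostics = {
        "grid_size": total,
        "n_feasible": n_feasible,
        "violation_counts": violations,
        "eigenvalues": np.sort(
            np.linalg.eigvals(build_system_matrix(best_model).T).real
        )[::-1].tolist(),
        "growth_scale_identifiable": obs.has_counts,
    }
    return FitResult(
        best_params=best_params,
        best_model=best_model,
        objective_value=float(best_obj),
        shortlist=shortlist,
        diagnostics=diagnostics,
    )
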