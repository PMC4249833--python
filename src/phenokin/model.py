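"""Growth–transition models and their spectral analysis.

A population of ``m`` interconverting cell phenotypes with per-phenotype net
growth rates ``g_i`` (birth minus death, 1/day) and directed first-order
conversion rates ``k_ij`` (phenotype ``i`` to phenotype ``j``, 1/day) evolves
linearly::

    dN/dt = T N,      T = G + K,

where ``G = diag(g)`` and ``K`` is a Markov-generator-like part whose columns
sum to zero (conversions conserve cells).  ``T`` has nonnegative off-diagonal
entries (a Metzler matrix), so for irreducible transition structure the
Perron–Frobenius theorem applies to ``T + cI``: the leading eigenvalue is
real and simple and its eigenvector is strictly positive.  Normalised to the
simplex, that eigenvector is the stationary composition — the subpopulation
fractions every positive initial condition relaxes to — while the leading
eigenvalue is the asymptotic exponential growth rate of the whole population.

Only the net growth rate enters the model: birth and death are not separately
identifiable from bulk culture and are deliberately not represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConvergenceError, ModelValidationError

__all__ = [
    "GrowthTransitionModel",
    "SystemMatrix",
    "SpectralSummary",
    "RegimeReport",
    "SurvivabilityFlag",
    "build_system_matrix",
    "spectral_summary",
    "stationary_composition",
    "classify_regime",
    "survivability",
]

#: Default multiplier operationalising the qualitative "much larger than".
DEFAULT_DOMINANCE_FACTOR = 10.0


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))
        raise ModelValidationError(
            f"{name} contains non-finite entries at index {bad[0].tolist()}"
        )
    return arr


@dataclass(frozen=True)
class GrowthTransitionModel:
    """Phenotype labels, net growth rates and directed transition rates.

    Parameters
    ----------
    labels : tuple of str
        Ordered phenotype names, length ``m >= 2``.
    growth : array of shape (m,)
        Net growth rate per phenotype (1/day); may be negative.
    transitions : array of shape (m, m)
        ``transitions[i, j]`` is the conversion rate from phenotype ``i`` to
        phenotype ``j`` (1/day).  Nonnegative, zero diagonal.
    """

    labels: tuple
    growth: np.ndarray
    transitions: np.ndarray

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        m = len(labels)
        if m < 2:
            raise ModelValidationError(f"need at least 2 phenotypes, got {m}")
        if len(set(labels)) != m:
            raise ModelValidationError(f"duplicate phenotype labels in {labels}")
        g = _as_float_array(self.growth, "growth")
        if g.shape != (m,):
            raise ModelValidationError(
                f"growth has shape {g.shape}, expected ({m},)"
            )
        k = _as_float_array(self.transitions, "transitions")
        if k.shape != (m, m):
            raise ModelValidationError(
                f"transitions has shape {k.shape}, expected ({m}, {m})"
            )
        neg = np.argwhere(k < 0)
        if neg.size:
            i, j = neg[0]
            raise ModelValidationError(
                f"negative transition rate k({labels[i]}->{labels[j]}) = {k[i, j]}"
            )
        diag = np.flatnonzero(np.diagonal(k))
        if diag.size:
            i = diag[0]
            raise ModelValidationError(
                f"self-transition k({labels[i]}->{labels[i]}) must be 0"
            )
        g = g.copy()
        k = k.copy()
        g.setflags(write=False)
        k.setflags(write=False)
        object.__setattr__(self, "growth", g)
        object.__setattr__(self, "transitions", k)

    @property
    def m(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ModelValidationError(
                f"unknown phenotype {label!r}; known labels: {list(self.labels)}"
            ) from None

    @property
    def outflow(self) -> np.ndarray:
        """Total conversion rate out of each phenotype, ``sum_j k_ij``."""
        return self.transitions.sum(axis=1)

    def with_growth_shift(self, c: float) -> "GrowthTransitionModel":
        """Return a copy with ``c`` added to every net growth rate."""
        return replace(self, growth=self.growth + float(c))

    @classmethod
    def two_state(cls, g_x, g_y, k_xy=0.0, k_yx=0.0, labels=("X", "Y")):
        k = np.array([[0.0, k_xy], [k_yx, 0.0]], dtype=float)
        return cls(labels=tuple(labels), growth=np.array([g_x, g_y], float),
                   transitions=k)

    @classmethod
    def from_dict(cls, spec: Mapping) -> "GrowthTransitionModel":
        """Build a model from the documented mapping schema.

        ``{"labels": [...], "growth": {label: rate},
        "transitions": {"from->to": rate}}``.  Omitted transitions default
        to zero; unknown labels are a hard error.
        """
        try:
            labels = tuple(str(l) for l in spec["labels"])
        except (KeyError, TypeError):
            raise ModelValidationError("model schema requires a 'labels' list")
        growth_map = spec.get("growth")
        if not isinstance(growth_map, Mapping):
            raise ModelValidationError("model schema requires a 'growth' mapping")
        missing = [l for l in labels if l not in growth_map]
        if missing:
            raise ModelValidationError(f"growth rate missing for {missing}")
        unknown = [l for l in growth_map if l not in labels]
        if unknown:
            raise ModelValidationError(f"growth given for unknown labels {unknown}")
        g = np.array([float(growth_map[l]) for l in labels])
        m = len(labels)
        k = np.zeros((m, m))
        idx = {l: i for i, l in enumerate(labels)}
        for key, rate in (spec.get("transitions") or {}).items():
            parts = str(key).split("->")
            if len(parts) != 2:
                raise ModelValidationError(
                    f"malformed transition key {key!r}; expected 'from->to'"
                )
            a, b = (p.strip() for p in parts)
            for lab in (a, b):
                if lab not in idx:
                    raise ModelValidationError(
                        f"transition {key!r} refers to unknown label {lab!r}"
                    )
            if a == b:
                raise ModelValidationError(
                    f"self-transition {key!r} is not allowed"
                )
            k[idx[a], idx[b]] = float(rate)
        return cls(labels=labels, growth=g, transitions=k)

    def to_dict(self) -> dict:
        trans = {
            f"{self.labels[i]}->{self.labels[j]}": float(self.transitions[i, j])
            for i in range(self.m)
            for j in range(self.m)
            if i != j and self.transitions[i, j] != 0.0
        }
        return {
            "labels": list(self.labels),
            "growth": {l: float(g) for l, g in zip(self.labels, self.growth)},
            "transitions": trans,
        }


@dataclass(frozen=True)
class SystemMatrix:
    """The system matrix ``T = G + K`` and its two parts.

    ``G`` is the diagonal growth part; ``K`` carries the conversions, with
    ``K[j, i] = k(i -> j)`` for ``j != i`` and ``K[i, i] = -sum_j k(i -> j)``
    so every column of ``K`` sums to zero (flux conservation: conversion
    moves cells between phenotypes without creating or destroying them).
    Columns act on phenotypes: column ``i`` of ``T`` carries the outflow of
    phenotype ``i``.
    """

    labels: tuple
    T: np.ndarray
    G: np.ndarray
    K: np.ndarray

    @property
    def m(self) -> int:
        return len(self.labels)


def build_system_matrix(model: GrowthTransitionModel) -> SystemMatrix:
    """Assemble ``T = G + K`` from a validated model."""
    m = model.m
    G = np.diag(model.growth)
    K = model.transitions.T.copy()
    np.fill_diagonal(K, -model.outflow)
    T = G + K
    for arr in (T, G, K):
        arr.setflags(write=False)
    return SystemMatrix(labels=model.labels, T=T, G=G, K=K)


def _coerce_system_matrix(sm) -> SystemMatrix:
    if isinstance(sm, GrowthTransitionModel):
        return build_system_matrix(sm)
    if not isinstance(sm, SystemMatrix):
        raise ModelValidationError(
            f"expected SystemMatrix or GrowthTransitionModel, got {type(sm).__name__}"
        )
    T = np.asarray(sm.T, float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ModelValidationError(f"system matrix must be square, got {T.shape}")
    if not np.all(np.isfinite(T)):
        raise ModelValidationError("system matrix contains non-finite entries")
    return sm


def _sign_tolerance(T: np.ndarray) -> float:
    # DD-5 style: eigenvalue sign decisions relative to the matrix 1-norm.
    return 1e-12 * max(1.0, np.linalg.norm(T, 1))


def is_irreducible(T: np.ndarray) -> bool:
    """True if the off-diagonal support of ``T`` is strongly connected."""
    A = (np.abs(T) > 0).astype(np.int8)
    np.fill_diagonal(A, 0)
    n, _ = connected_components(csr_matrix(A), directed=True, connection="strong")
    return n == 1


@dataclass(frozen=True)
class SpectralSummary:
    """Eigenstructure of a system matrix.

    ``eigenvalues`` are sorted by descending real part; ``lambda_max`` is the
    real part of the leading one (for irreducible models it is exactly real);
    ``leading_composition`` is the leading right eigenvector rescaled to the
    probability simplex; ``spectral_gap`` is the real-part separation of the
    first two eigenvalues.  ``fallback_used`` marks compositions obtained by
    long-time integration instead of the eigenvector (degenerate or reducible
    cases).
    """

    eigenvalues: np.ndarray
    lambda_max: float
    leading_composition: np.ndarray
    spectral_gap: float
    irreducible: bool
    fallback_used: bool = False


def _integration_fallback(T: np.ndarray, gap: float) -> np.ndarray:
    # DD-3: evolve a uniform positive start far past the mixing time and
    # renormalise.  Shift by the dominant diagonal so the exponential stays
    # finite.
    m = T.shape[0]
    horizon = 200.0 / gap if gap > 1e-8 else 200.0
    shift = float(np.max(np.real(np.linalg.eigvals(T))))
    x = np.full(m, 1.0 / m)
    # step in chunks so expm arguments stay well scaled
    n_steps = max(1, int(np.ceil(horizon / 50.0)))
    step = expm((T - shift * np.eye(m)) * (horizon / n_steps))
    for _ in range(n_steps):
        x = step @ x
        s = x.sum()
        if s <= 0 or not np.isfinite(s):
            raise ConvergenceError(
                "integration fallback for the stationary composition diverged"
            )
        x = x / s
    return np.clip(x, 0.0, None) / np.clip(x, 0.0, None).sum()


def spectral_summary(sm, *, fallback: bool = True) -> SpectralSummary:
    """Eigen-decompose a system matrix and extract the leading mode.

    For irreducible off-diagonal structure the leading eigenvalue is real and
    simple and its eigenvector strictly positive (Perron–Frobenius applied to
    the shifted nonnegative matrix), so the stationary composition is read
    directly from the eigenvector.  Otherwise — or when the leading mode is
    numerically degenerate — the composition falls back to long-time
    integration and ``fallback_used`` is set.
    """
    sm = _coerce_system_matrix(sm)
    T = np.asarray(sm.T, float)
    tol = _sign_tolerance(T)
    w, V = np.linalg.eig(T)
    order = np.lexsort((-w.imag, -w.real))
    w_sorted = w[order]
    irr = is_irreducible(T)
    gap = float(w_sorted[0].real - w_sorted[1].real)

    lead = order[0]
    degenerate = abs(w_sorted[0].imag) > tol or gap <= tol
    comp = None
    used_fallback = False
    if not degenerate or irr:
        v = np.real(V[:, lead])
        s = v.sum()
        if abs(s) > 0:
            v = v / s
        v = np.where(np.abs(v) < tol, 0.0, v)
        if np.all(v >= 0) and v.sum() > 0:
            comp = v / v.sum()
    if comp is None:
        if not fallback:
            raise ConvergenceError(
                "leading eigenmode is degenerate or non-positive; enable the "
                "integration fallback to obtain a composition"
            )
        comp = _integration_fallback(T, gap)
        used_fallback = True

    comp = comp / comp.sum()
    comp.setflags(write=False)
    w_sorted.setflags(write=False)
    return SpectralSummary(
        eigenvalues=w_sorted,
        lambda_max=float(w_sorted[0].real),
        leading_composition=comp,
        spectral_gap=gap,
        irreducible=irr,
        fallback_used=used_fallback,
    )


def stationary_composition(sm, *, fallback: bool = True) -> np.ndarray:
    """The simplex composition every strictly positive start converges to.

    For irreducible models this is the Perron eigenvector of ``T`` rescaled
    to sum to one; it is a fixed point of the normalised dynamics.  Reducible
    models with an ambiguous leading mode raise unless ``fallback`` is set,
    in which case the long-time integrated composition is returned.
    """
    sm = _coerce_system_matrix(sm)
    summary = spectral_summary(sm, fallback=fallback)
    if not summary.irreducible and not fallback:
        raise ConvergenceError(
            "reducible transition structure: the leading mode may be "
            "ambiguous; use the integration fallback"
        )
    return summary.leading_composition


@dataclass(frozen=True)
class SurvivabilityFlag:
    """Whether a phenotype persists on its own or rides on backflow."""

    independent: bool
    strongly_independent: bool
    growth: float
    outflow: float


def survivability(
    model: GrowthTransitionModel,
    dominance_factor: float = DEFAULT_DOMINANCE_FACTOR,
) -> dict:
    """Flag each phenotype as independent or derivative.

    Phenotype ``i`` is *independent* when its net growth exceeds its total
    conversion outflow (strict comparison), i.e. it would persist with the
    backflow from other phenotypes switched off; with zero outflow it cannot
    be a derivative of anything and is independent by construction.
    ``strongly_independent`` applies the dominance factor to the qualitative
    "growth much larger than conversions" judgment.
    """
    if dominance_factor <= 0:
        raise ModelValidationError("dominance_factor must be positive")
    out = {}
    for i, label in enumerate(model.labels):
        g = float(model.growth[i])
        o = float(model.outflow[i])
        independent = o == 0.0 or g > o
        strong = o == 0.0 or g > dominance_factor * o
        out[label] = SurvivabilityFlag(
            independent=independent,
            strongly_independent=strong,
            growth=g,
            outflow=o,
        )
    return out


@dataclass(frozen=True)
class RegimeReport:
    """Population regime classification from eigenvalue signs.

    ``regime`` is one of ``coexistent_growth`` (all eigenvalue real parts
    positive: every subpopulation grows, at a common asymptotic rate),
    ``coexistent_extinction`` (all negative: joint extinction),
    ``derived_survival`` (mixed signs: at least one phenotype persists only
    through backflow), or ``blurred_single_type`` (conversions dominate
    growth for every phenotype so strongly that the population acts as a
    single type with a mean growth rate).  ``marginal`` is set — and
    ``regime`` left ``None`` — when an eigenvalue sits at zero within
    tolerance.
    """

    regime: str | None
    survivability: dict
    det_T: float | None
    dominance_factor: float
    marginal: bool = False
    eigenvalues: np.ndarray = field(default=None, repr=False)


def classify_regime(
    model: GrowthTransitionModel,
    dominance_factor: float = DEFAULT_DOMINANCE_FACTOR,
) -> RegimeReport:
    """Classify the long-term population regime.

    Sign pattern of the eigenvalue real parts decides between coexistent
    growth, coexistent extinction and derived survival; when every
    phenotype's conversion outflow exceeds ``dominance_factor`` times its
    net growth the distinction between phenotypes is blurred and the
    population is reported as a single effective type (this takes precedence
    over the sign-based label).  For two phenotypes the determinant of ``T``
    is reported: the eigenvalues share a sign iff ``det T > 0``.
    """
    if dominance_factor <= 0:
        raise ModelValidationError("dominance_factor must be positive")
    sm = build_system_matrix(model)
    summary = spectral_summary(sm)
    re = summary.eigenvalues.real
    tol = _sign_tolerance(sm.T)
    surv = survivability(model, dominance_factor)

    marginal = bool(np.any(np.abs(re) <= tol))
    # conversions dominate when outflow dwarfs the growth-rate magnitude
    blurred = bool(
        np.all(model.outflow > dominance_factor * np.abs(model.growth))
        and np.all(model.outflow > 0)
    )
    if marginal:
        regime = None
    elif blurred:
        regime = "blurred_single_type"
    elif np.all(re > tol):
        regime = "coexistent_growth"
    elif np.all(re < -tol):
        regime = "coexistent_extinction"
    else:
        regime = "derived_survival"

    det = float(np.linalg.det(sm.T)) if model.m == 2 else None
    return RegimeReport(
        regime=regime,
        survivability=surv,
        det_T=det,
        dominance_factor=float(dominance_factor),
        marginal=marginal,
        eigenvalues=summary.eigenvalues,
    )
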