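"""Closed-form kinetics of the two-phenotype model.

With subpopulations ``X`` and ``Y`` (net growth ``g_X``, ``g_Y``; conversions
``k_XY``, ``k_YX``), the ratio ``r = N_X / N_Y`` obeys the Riccati equation::

    dr/dt = k_YX + Delta * r - k_XY * r**2,
    Delta = (g_X - g_Y) - (k_XY - k_YX),

whose nonnegative fixed point is ``r* = (Delta + S) / (2 k_XY)`` with
``S = sqrt(Delta**2 + 4 k_XY k_YX)``.  ``S`` sets the relaxation timescale
(re-equilibration takes on the order of ``1/S``), and the sign of ``Delta``
splits the kinetics into two shapes: for ``Delta > 0`` the rate from a pure-Y
start rises to a maximum at ``r_peak = Delta / (2 k_XY)`` before falling
(sigmoidal time course); for ``Delta <= 0`` the rate decreases monotonically
(simple exponential saturation).  When growth differences dominate
(``Delta > 0`` large) composition shifts are selection-like; when transition
differences dominate they are induction-like — the same equation covers both.

The quadratic factorises as ``dr/dt = -k_XY (r - r+)(r - r-)`` with roots
``r± = (Delta ± S) / (2 k_XY)``, giving the explicit time course used by
:func:`time_of_ratio` and :func:`ratio_at_time`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateModelError, ModelValidationError
from .model import GrowthTransitionModel

__all__ = [
    "TwoStateParams",
    "RatioKinetics",
    "ratio_rate",
    "steady_ratio",
    "time_of_ratio",
    "ratio_at_time",
    "kinetic_shape",
    "population_growth_rate",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Rates of the two-phenotype model (all 1/day)."""

    g_x: float
    g_y: float
    k_xy: float = 0.0
    k_yx: float = 0.0

    def __post_init__(self):
        vals = (self.g_x, self.g_y, self.k_xy, self.k_yx)
        if not all(math.isfinite(v) for v in vals):
            raise ModelValidationError(f"non-finite rate in {vals}")
        if self.k_xy < 0 or self.k_yx < 0:
            raise ModelValidationError(
                f"transition rates must be nonnegative, got "
                f"k_xy={self.k_xy}, k_yx={self.k_yx}"
            )

    @property
    def delta(self) -> float:
        """Net drift ``(g_X - g_Y) - (k_XY - k_YX)``."""
        return (self.g_x - self.g_y) - (self.k_xy - self.k_yx)

    @property
    def discriminant(self) -> float:
        """``S = sqrt(Delta^2 + 4 k_XY k_YX)``; ``1/S`` is the relaxation time."""
        return math.sqrt(self.delta**2 + 4.0 * self.k_xy * self.k_yx)

    def roots(self) -> tuple:
        """Both fixed points ``(r-, r+)`` of the ratio equation.

        Requires ``k_XY > 0``; the nonpositive root ``r-`` is diagnostic
        only — count ratios live on ``r >= 0``.
        """
        if self.k_xy == 0:
            raise DegenerateModelError(
                "k_xy = 0: the ratio equation is not quadratic"
            )
        s = self.discriminant
        return (
            (self.delta - s) / (2.0 * self.k_xy),
            (self.delta + s) / (2.0 * self.k_xy),
        )

    def to_model(self, labels=("X", "Y")) -> GrowthTransitionModel:
        return GrowthTransitionModel.two_state(
            self.g_x, self.g_y, self.k_xy, self.k_yx, labels=labels
        )


@dataclass(frozen=True)
class RatioKinetics:
    """Summary of the ratio re-equilibration kinetics."""

    r_star: float
    discriminant: float
    timescale: float
    r_peak: float
    max_rate: float
    shape: str  # "sigmoidal" | "saturating"


def ratio_rate(r: float, p: TwoStateParams) -> float:
    """Instantaneous drift ``dr/dt`` of the ratio ``r = N_X/N_Y``."""
    if r < 0:
        raise ModelValidationError(f"ratio must be nonnegative, got {r}")
    return p.k_yx + p.delta * r - p.k_xy * r * r


def steady_ratio(p: TwoStateParams, *, allow_degenerate: bool = False) -> float:
    """The stable fixed ratio ``r* = (Delta + S) / (2 k_XY)``.

    Always the nonnegative root of the Riccati quadratic; it coincides with
    the X:Y component ratio of the leading eigenvector of the 2x2 system
    matrix.  With ``k_XY = 0`` the quadratic degenerates: the ratio diverges
    whenever ``Delta >= 0`` keeps feeding X, and the finite or absorbing
    answers for the remaining cases are returned only on explicit opt-in.
    """
    if p.k_xy > 0:
        return (p.delta + p.discriminant) / (2.0 * p.k_xy)
    # degenerate family: dr/dt = k_yx + delta * r is affine
    if not allow_degenerate:
        raise DegenerateModelError(
            "k_xy = 0: steady ratio is degenerate (X never converts to Y); "
            "pass allow_degenerate=True for the limiting answer"
        )
    if p.delta < 0:
        return p.k_yx / (-p.delta)
    if p.delta == 0 and p.k_yx == 0:
        return 0.0  # no coupling at all; any starting ratio persists
    return math.inf


def _log_progress(r, r_minus, r_plus, r0) -> float:
    # signed cross-ratio entering the partial-fraction integral
    num = (r - r_minus) * (r0 - r_plus)
    den = (r - r_plus) * (r0 - r_minus)
    if den == 0 or num / den <= 0:
        raise ModelValidationError(
            f"ratio {r} is not reachable from {r0}: the trajectory cannot "
            f"cross the fixed point r* = {r_plus}"
        )
    return math.log(num / den)


def time_of_ratio(r0: float, r: float, p: TwoStateParams) -> float:
    """Time (days) for the ratio trajectory from ``r0`` to reach ``r``.

    Closed form from partial fractions::

        t = (1/S) * ln[ (r - r-)(r0 - r+) / ((r - r+)(r0 - r-)) ]

    Both ratios must lie strictly on the same side of ``r*`` — trajectories
    are monotone and never cross the fixed point; requests across it raise.
    A target "behind" the start returns the (negative) algebraic time.
    """
    for name, val in (("r0", r0), ("r", r)):
        if val < 0:
            raise ModelValidationError(f"{name} must be nonnegative, got {val}")
    if p.k_xy == 0:
        raise DegenerateModelError("k_xy = 0: use the affine/degenerate forms")
    if r == r0:
        return 0.0
    s = p.discriminant
    if s == 0.0:
        # double root at r* = 0 (requires delta = 0 and k_yx = 0)
        if r0 == 0.0 or r == 0.0:
            raise ModelValidationError(
                f"ratio {r} is not reachable from {r0} in finite time "
                "(double-root case decays to 0 only asymptotically)"
            )
        return (1.0 / r - 1.0 / r0) / p.k_xy
    r_minus, r_plus = p.roots()
    if (r0 - r_plus) * (r - r_plus) <= 0:
        raise ModelValidationError(
            f"r0={r0} and r={r} straddle the fixed point r*={r_plus}"
        )
    return _log_progress(r, r_minus, r_plus, r0) / s


def ratio_at_time(r0: float, t: float, p: TwoStateParams) -> float:
    """Ratio after time ``t`` starting from ``r0`` (inverse of time_of_ratio)."""
    if r0 < 0:
        raise ModelValidationError(f"r0 must be nonnegative, got {r0}")
    if p.k_xy == 0:
        raise DegenerateModelError("k_xy = 0: use the affine/degenerate forms")
    s = p.discriminant
    if s == 0.0:
        return r0 / (1.0 + p.k_xy * r0 * t)
    r_minus, r_plus = p.roots()
    if r0 == r_plus:
        return r_plus
    c = (r0 - r_plus) / (r0 - r_minus)
    e = c * math.exp(-s * t)
    return (r_plus - r_minus * e) / (1.0 - e)


def kinetic_shape(p: TwoStateParams) -> RatioKinetics:
    """Classify the re-equilibration kinetics and its extremal rate.

    For ``Delta > 0`` the drift peaks at ``r_peak = Delta / (2 k_XY)`` with
    ``max rate = k_YX + Delta^2 / (4 k_XY)`` — the time course from a pure-Y
    start is sigmoidal.  For ``Delta <= 0`` the drift on ``r >= 0`` is
    maximal at the boundary ``r = 0`` (rate ``k_YX``) and decreases
    monotonically — exponential saturation.
    """
    if p.k_xy <= 0:
        raise DegenerateModelError("kinetic_shape requires k_xy > 0")
    d = p.delta
    s = p.discriminant
    if d > 0:
        r_peak = d / (2.0 * p.k_xy)
        max_rate = p.k_yx + d * d / (4.0 * p.k_xy)
        shape = "sigmoidal"
    else:
        r_peak = 0.0
        max_rate = p.k_yx
        shape = "saturating"
    return RatioKinetics(
        r_star=steady_ratio(p),
        discriminant=s,
        timescale=math.inf if s == 0 else 1.0 / s,
        r_peak=r_peak,
        max_rate=max_rate,
        shape=shape,
    )


def population_growth_rate(p: TwoStateParams) -> float:
    """Asymptotic exponential growth rate of the total population.

    Equals the growth of the stationary mixture,
    ``(g_X r* + g_Y) / (r* + 1)`` (conversions conserve total mass, so only
    growth contributes), which coincides with the leading eigenvalue of the
    2x2 system matrix.  Degenerate couplings fall back to the eigenvalue.
    """
    if p.k_xy > 0:
        r = steady_ratio(p)
        if math.isfinite(r):
            return (p.g_x * r + p.g_y) / (r + 1.0)
    # decoupled or one-way models: read the answer off the triangular matrix
    sm = p.to_model()
    from .model import build_system_matrix  # local to avoid cycle at import

    return float(np.max(np.linalg.eigvals(build_system_matrix(sm).T).real))
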