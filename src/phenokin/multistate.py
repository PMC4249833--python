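"""m-phenotype generalisation: spectral modes and fraction dynamics.

The linear count dynamics ``dN/dt = T N`` induce, for the subpopulation
fractions ``x_i = N_i / sum_j N_j``, the nonlinear (replicator-like) system

    dx/dt = T x - (g . x) x,

since the conversion part of ``T`` conserves total mass and only growth
changes it (``1' T x = g . x``).  The stationary composition of the linear
system — the leading eigenvector on the simplex — is exactly the interior
fixed point of this fraction ODE; setting ``dx/dt = 0`` gives a coupled
quadratic system with no general closed form, solved here by a damped Newton
iteration on the simplex.

The general linear solution is a sum of eigenmodes,
``N(t) = sum_i A_i v_i exp(lambda_i t)``, with coefficients fixed by the
initial counts; :func:`mode_decomposition` exposes it for diagonalisable
system matrices, reducing to the familiar two-term form when ``m = 2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConvergenceError,
    DefectiveMatrixError,
    ModelValidationError,
)
from .model import (
    GrowthTransitionModel,
    build_system_matrix,
    stationary_composition,
)

__all__ = [
    "FractionState",
    "ModeDecomposition",
    "fraction_rhs",
    "stationary_fractions_numeric",
    "mode_decomposition",
    "fractions_to_ratios",
    "ratios_to_fractions",
]

SIMPLEX_ATOL = 1e-9


def _validate_simplex(x, m=None, atol=SIMPLEX_ATOL) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ModelValidationError(f"fraction vector must be 1-D, got {x.shape}")
    if m is not None and x.shape[0] != m:
        raise ModelValidationError(
            f"fraction vector has length {x.shape[0]}, expected {m}"
        )
    if not np.all(np.isfinite(x)):
        raise ModelValidationError("fraction vector contains non-finite entries")
    if np.any(x < -atol):
        raise ModelValidationError(f"negative fraction in {x}")
    if abs(x.sum() - 1.0) > atol:
        raise ModelValidationError(
            f"fractions sum to {x.sum():.12g}, expected 1 within {atol}"
        )
    return x


@dataclass(frozen=True)
class FractionState:
    """A point on the probability simplex of subpopulation fractions."""

    x: np.ndarray

    def __post_init__(self):
        x = _validate_simplex(self.x).copy()
        x.setflags(write=False)
        object.__setattr__(self, "x", x)


def _coerce_fractions(x, m=None) -> np.ndarray:
    if isinstance(x, FractionState):
        x = x.x
    return _validate_simplex(x, m)


def fraction_rhs(x, model: GrowthTransitionModel) -> np.ndarray:
    """Time derivative of the subpopulation fractions, ``T x - (g.x) x``.

    The result is tangent to the simplex (components sum to zero) and
    vanishes exactly at the stationary composition.
    """
    x = _coerce_fractions(x, model.m)
    T = build_system_matrix(model).T
    Tx = T @ x
    total = float(model.growth @ x)  # equals 1' T x by flux conservation
    return Tx - total * x


def stationary_fractions_numeric(
    model: GrowthTransitionModel,
    x0=None,
    *,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> np.ndarray:
    """Interior fixed point of the fraction ODE by damped Newton iteration.

    Solves ``T x = (g.x) x`` on the simplex starting from ``x0`` (default:
    uniform composition).  The m-th (dependent) equation is replaced by the
    normalisation constraint; steps are halved until the residual decreases
    and iterates stay essentially nonnegative.  Agrees with the leading
    eigenvector composition for irreducible models.

    Raises
    ------
    ConvergenceError
        If the residual has not dropped below ``tol`` after ``max_iter``
        iterations; the achieved residual is attached.
    """
    m = model.m
    if x0 is None:
        x = np.full(m, 1.0 / m)
    else:
        x = _coerce_fractions(x0, m).copy()
    T = build_system_matrix(model).T
    g = model.growth
    tol_scaled = tol * max(1.0, np.linalg.norm(T, 1))

    def residual(x):
        F = T @ x - (g @ x) * x
        F[-1] = x.sum() - 1.0
        return F

    def newton(x, budget):
        F = residual(x)
        best = float(np.linalg.norm(F))
        for _ in range(budget):
            if best <= tol:
                break
            J = T - (g @ x) * np.eye(m) - np.outer(x, g)
            J[-1, :] = 1.0
            try:
                step = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(J, -F, rcond=None)[0]
            lam = 1.0
            for _ in range(40):
                x_new = x + lam * step
                if np.all(x_new > -1e-13):
                    x_try = np.clip(x_new, 0.0, None)
                    x_try = x_try / x_try.sum()
                    norm_new = float(np.linalg.norm(residual(x_try)))
                    if norm_new < best:
                        x, best = x_try, norm_new
                        F = residual(x)
                        break
                lam *= 0.5
            else:
                break  # no productive step found
        return x, best

    x, best = newton(x, max_iter)
    if best > tol_scaled:
        # damped Newton can stall far from the interior fixed point; restart
        # from a mixed composition obtained by evolving the fractions for a
        # few relaxation times (fractions are shift-invariant, so shift the
        # leading eigenvalue to zero first)
        from scipy.linalg import expm  # local import, cold path

        re = np.sort(np.linalg.eigvals(T).real)
        lam_max, gap = re[-1], max(re[-1] - re[-2], 1e-3)
        warm = expm((T - lam_max * np.eye(m)) * (40.0 / gap)) @ np.full(
            m, 1.0 / m
        )
        warm = np.clip(warm, 0.0, None)
        x, best = newton(warm / warm.sum(), max_iter)
    if best > tol_scaled:
        raise ConvergenceError(
            f"Newton iteration stalled at residual {best:.3e}",
            residual=best,
        )
    x = np.clip(x, 0.0, None)
    return x / x.sum()


@dataclass(frozen=True)
class ModeDecomposition:
    """Spectral-mode solution ``N(t) = sum_i A_i v_i exp(lambda_i t)``.

    ``eigenvectors[:, i]`` is the mode shape ``v_i`` for ``eigenvalues[i]``;
    ``coefficients[i]`` is the weight ``A_i`` fixed by the initial counts.
    """

    labels: tuple
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    coefficients: np.ndarray

    def reconstruct(self, times) -> np.ndarray:
        """Counts on a time grid, shape ``(len(times), m)`` (real part)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        phases = np.exp(np.outer(t, self.eigenvalues))  # (nt, m)
        counts = (phases * self.coefficients) @ self.eigenvectors.T
        return np.real(counts)


def mode_decomposition(model: GrowthTransitionModel, N0) -> ModeDecomposition:
    """Expand an initial count vector over the eigenmodes of ``T``.

    Raises
    ------
    DefectiveMatrixError
        If the eigenvector basis is numerically singular (defective or
        near-defective matrix); propagate with the integrator instead.
    """
    N0 = np.asarray(N0, dtype=float)
    if N0.shape != (model.m,):
        raise ModelValidationError(
            f"N0 has shape {N0.shape}, expected ({model.m},)"
        )
    if not np.all(np.isfinite(N0)):
        raise ModelValidationError("N0 contains non-finite entries")
    T = build_system_matrix(model).T
    w, V = np.linalg.eig(T)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise DefectiveMatrixError(
            f"eigenvector basis is ill-conditioned (cond={cond:.2e}); "
            "use simulate.integrate instead",
            residual=float(cond),
        )
    order = np.lexsort((-w.imag, -w.real))
    w, V = w[order], V[:, order]
    A = np.linalg.solve(V, N0.astype(complex))
    return ModeDecomposition(
        labels=model.labels, eigenvalues=w, eigenvectors=V, coefficients=A
    )


def fractions_to_ratios(x, ref_index: int = 0) -> np.ndarray:
    """Ratio-to-reference view ``rho_i = x_i / x_ref`` (ref entry is 1)."""
    x = np.asarray(x, dtype=float)
    if x[ref_index] <= 0:
        raise ModelValidationError(
            f"reference fraction x[{ref_index}] must be positive, got "
            f"{x[ref_index]}"
        )
    return x / x[ref_index]


def ratios_to_fractions(rho, ref_index: int = 0) -> np.ndarray:
    """Inverse of :func:`fractions_to_ratios`."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or rho[ref_index] != 1.0:
        raise ModelValidationError(
            "ratio vector must be nonnegative with the reference entry equal "
            f"to 1, got {rho}"
        )
    return rho / rho.sum()
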