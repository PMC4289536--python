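"""Principal eigenvalue of the single-kernel dispersal-growth operator.

The linearization of the growth-dispersal map at zero density is the
positive compact operator ``(L n)(x) = R * integral K(x - y) n(y) dy`` on
the habitat.  Its spectral radius -- the principal eigenvalue ``lambda_1``
-- decides persistence: the population grows when ``lambda_1 > 1``.

Two independent routes are provided:

* :func:`build_nystrom` / :func:`principal_eigenpair` -- quadrature
  (Nystrom) discretization and a dominant-eigenpair solve;
* :func:`eigen_bvp_single` -- the equivalent two-point boundary-value
  problem.  Because the kernel is the Green's function of a second-order
  operator, the eigenfunction satisfies
  ``phi'' = (v/D) phi' + (beta/D)(1 - R/lambda) phi`` with Robin conditions
  ``phi'(x0) = a1 phi(x0)``, ``phi'(y0) = a2 phi(y0)``; eigenvalues are the
  roots of a 2x2 boundary determinant.

:func:`dispersal_success_approx` implements the flat-eigenfunction
approximation ``lambda_a1 = (R/L) * integral s(y) dy``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _bvp
from .kernels import AdvectiveKernelParams, Habitat, kernel_density, pair_integral

__all__ = [
    "StageParams",
    "EigenResult",
    "build_nystrom",
    "principal_eigenpair",
    "eigen_bvp_single",
    "dispersal_success_approx",
]


@dataclass(frozen=True)
class StageParams:
    """One environment stage: a dispersal kernel plus its growth rate.

    ``R`` is the geometric growth rate, the slope of the growth function at
    zero density.
    """

    kernel: AdvectiveKernelParams
    R: float

    def __post_init__(self) -> None:
        if not (self.R > 0):
            raise ValueError(f"growth rate R must be > 0, got {self.R}")


@dataclass
class EigenResult:
    """Principal eigenvalue with its positive, unit-mass eigenfunction.

    ``phi`` holds eigenfunction samples on the habitat nodes, normalized so
    the quadrature mass is one; ``residual`` is the sup-norm of
    ``(operator @ phi) - lambda1 * phi`` on the Nystrom discretization.
    """

    lambda1: float
    phi: np.ndarray
    residual: float
    method: str
    n_nodes: int


def build_nystrom(stage: StageParams, h: Habitat) -> np.ndarray:
    """Nystrom matrix ``M[i, j] = R * K(x_i - x_j) * w_j`` (all entries > 0)."""
    if h.n < 2:
        raise ValueError("habitat needs at least 2 nodes")
    x = h.nodes
    return stage.R * kernel_density(stage.kernel, x[:, None], x[None, :]) * h.weights


class ConvergenceError(RuntimeError):
    pass


def _dominant_pair(apply_fn, n: int, tol: float = 1e-10, maxiter: int = 100_000):
    """Power iteration for a positive operator given only its action.

    Starts from the constant function, which keeps every iterate strictly
    positive (Perron-Frobenius); the eigenvalue estimate is the Rayleigh
    quotient.  Returns ``(lam, vec, converged)``.
    """
    x = np.ones(n)
    lam = 1.0
    for _ in range(maxiter):
        y = apply_fn(x)
        lam = float(y @ x) / float(x @ x)
        resid = float(np.max(np.abs(y - lam * x)))
        x = y / np.max(y)
        if resid <= tol * lam:
            return lam, x, True
    return lam, x, False


def principal_eigenpair(
    M: np.ndarray,
    h: Habitat,
    tol: float = 1e-10,
    maxiter: int = 100_000,
    method_label: str = "nystrom",
) -> EigenResult:
    """Dominant eigenpair of an elementwise-positive operator matrix.

    Power iteration with a dense eigendecomposition fallback if the
    iteration stalls (a small spectral gap).
    """
    if np.any(M <= 0):
        raise ValueError("operator matrix must be elementwise positive")
    n = M.shape[0]
    lam, x, converged = _dominant_pair(lambda v: M @ v, n, tol, maxiter)
    if not converged:
        vals, vecs = np.linalg.eig(M)
        i = int(np.argmax(vals.real))
        if abs(vals[i].imag) > 1e-8 * abs(vals[i].real):
            raise ConvergenceError(
                f"dominant eigenvalue not real after {maxiter} iterations"
            )
        lam = float(vals[i].real)
        x = vecs[:, i].real
        x = x if x.sum() > 0 else -x
    phi = x / float(h.weights @ x)
    resid = float(np.max(np.abs(M @ phi - lam * phi)))
    return EigenResult(lam, phi, resid, method_label, n)


def _single_bvp_det(stage: StageParams, L: float, lam: float):
    """Boundary determinant of the 2x2 system on [0, L] and its root signature."""
    k, R = stage.kernel, stage.R
    roots = np.roots([1.0, -k.v / k.D, -(k.beta / k.D) * (1.0 - R / lam)])
    specs = _bvp.basis_specs(roots)
    table = _bvp.basis_derivative_table(specs, np.array([0.0, L]), 1, L)
    # rows: phi'(0) - a1 phi(0) = 0 ; phi'(L) - a2 phi(L) = 0
    A = _bvp.boundary_matrix(
        [
            table[:, 0, 1] - k.a1 * table[:, 0, 0],
            table[:, 1, 1] - k.a2 * table[:, 1, 0],
        ]
    )
    return _bvp.scaled_det(A), _bvp.signature(roots), specs, A


def _det_roots(det_fn, grid, _depth: int = 0):
    """Bisect every same-signature sign change of det_fn over a lambda grid.

    The determinant is assembled from a root-structure-dependent basis, so
    its value can jump where characteristic roots change character
    (real/complex/confluent); intervals whose endpoints have different
    structure signatures are recursively refined so no root hiding next to
    a structure boundary is missed.
    """
    from scipy.optimize import brentq

    vals = [det_fn(g) for g in grid]
    roots = []
    for (g0, (d0, s0)), (g1, (d1, s1)) in zip(
        zip(grid[:-1], vals[:-1]), zip(grid[1:], vals[1:])
    ):
        if s0 != s1:
            if _depth < 4:
                roots.extend(
                    _det_roots(det_fn, np.linspace(g0, g1, 17), _depth + 1)
                )
            continue
        if d0 == 0.0:
            roots.append(g0)
            continue
        if np.sign(d0) == np.sign(d1):
            continue
        roots.append(brentq(lambda t: det_fn(t)[0], g0, g1, xtol=1e-13, rtol=1e-14))
    if vals and vals[-1][0] == 0.0:
        roots.append(grid[-1])
    return roots


def eigen_bvp_single(
    stage: StageParams,
    h: Habitat,
    lambda_bracket: tuple[float, float] | None = None,
    n_scan: int = 200,
) -> EigenResult:
    """Principal eigenvalue via the second-order boundary-value problem.

    Scans the boundary determinant over ``lambda`` (by default the open
    interval ``(0, R)``, which contains every eigenvalue since dispersal
    loss forces ``lambda_1 < R``), bisects each sign change, and returns
    the largest root with the eigenfunction reconstructed from the
    characteristic basis.
    """
    R, L = stage.R, h.L
    lo, hi = lambda_bracket if lambda_bracket else (R / n_scan, R * (1 - 1e-9))
    grid = np.linspace(lo, hi, n_scan)
    det_fn = lambda lam: _single_bvp_det(stage, L, lam)[:2]
    roots = _det_roots(det_fn, grid)
    if not roots:
        raise ValueError(
            "no sign change of the boundary determinant in "
            f"({lo:g}, {hi:g}); widen the scan"
        )
    lam = max(roots)
    _, _, specs, A = _single_bvp_det(stage, L, lam)
    phi = _eigenfunction_from_nullspace(A, specs, h)
    M = build_nystrom(stage, h)
    resid = float(np.max(np.abs(M @ phi - lam * phi)))
    return EigenResult(lam, phi, resid, "bvp", h.n)


def _eigenfunction_from_nullspace(A: np.ndarray, specs, h: Habitat) -> np.ndarray:
    """Sample the null-vector combination of the basis on the habitat nodes."""
    scale = np.max(np.abs(A), axis=0)
    scale[scale == 0] = 1.0
    _, _, vt = np.linalg.svd(A / scale)
    c = vt[-1] / scale
    xs = h.nodes - h.x0  # basis lives on local [0, L]
    table = _bvp.basis_derivative_table(specs, xs, 0, h.L)
    phi = table[:, :, 0].T @ c
    if phi.sum() < 0:
        phi = -phi
    mass = float(h.weights @ phi)
    return phi / mass


def dispersal_success_approx(stage: StageParams, h: Habitat) -> float:
    """Dispersal success approximation ``(R/L) * integral s(y) dy`` (closed form)."""
    return stage.R * pair_integral(stage.kernel, h) / h.L
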