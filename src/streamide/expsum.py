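"""Closed-form algebra of exponential sums with polynomial coefficients.

Applying an asymmetric Laplace kernel to a density that is a finite sum of
terms ``p(x) * exp(r*x)`` (``p`` polynomial) again yields such a sum: each
incoming rate is preserved, and the two kernel decay rates enter through
boundary terms at the habitat endpoints.  Iterating this observation gives
an exact, quadrature-free representation of the linearized population
density after any number of dispersal-growth steps, and hence an exact
expression for the finite-time growth rate.

When an incoming rate coincides with a kernel decay rate (a repeated
environment), the generic small-divisor formula degenerates; the confluent
limit multiplies by ``x`` instead, which is why coefficients here are
polynomials rather than scalars.  For i.i.d. continuous parameter draws no
two rates ever coincide and every polynomial stays constant.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np
from numpy.polynomial import polynomial as P

from .kernels import AdvectiveKernelParams, Habitat

__all__ = [
    "ExpSum",
    "dispersal_success_expsum",
    "redistribution_expsum",
]

# Two rates closer than this (relative to scale) are treated as equal and
# handled through the confluent (polynomial) branch.
RATE_SNAP = 1e-10


def _trim(c: np.ndarray) -> np.ndarray:
    c = np.atleast_1d(np.asarray(c, dtype=float))
    nz = np.nonzero(c)[0]
    return c[: nz[-1] + 1] if nz.size else np.zeros(1)


def _exp_antideriv(p: np.ndarray, mu: float) -> np.ndarray:
    """Polynomial ``q`` with ``d/dy [exp(mu*y) q(y)] = p(y) exp(mu*y)``.

    ``q = sum_j (-1)^j p^(j) / mu^(j+1)``; requires ``mu != 0``.
    """
    acc = np.zeros_like(p)
    term = p / mu
    while True:
        acc = P.polyadd(acc, term)
        if len(term) == 1:
            break
        term = -P.polyder(term) / mu
    return acc


class ExpSum:
    """A function ``f(x) = sum over rates r of p_r(x) * exp(r*x)``.

    Terms are stored as a map from rate to ascending polynomial
    coefficients.  Rates within :data:`RATE_SNAP` (relative) of an existing
    rate are merged onto it.
    """

    def __init__(self, terms: Dict[float, np.ndarray] | None = None):
        self.terms: Dict[float, np.ndarray] = {}
        if terms:
            for r, c in terms.items():
                self.add_term(r, c)

    # -- construction -------------------------------------------------
    @classmethod
    def constant(cls, c: float) -> "ExpSum":
        return cls({0.0: np.array([float(c)])})

    def copy(self) -> "ExpSum":
        return ExpSum({r: c.copy() for r, c in self.terms.items()})

    def _match_rate(self, r: float) -> float:
        for r0 in self.terms:
            if abs(r - r0) <= RATE_SNAP * max(1.0, abs(r0)):
                return r0
        return r

    def add_term(self, rate: float, coeffs) -> None:
        coeffs = _trim(coeffs)
        r0 = self._match_rate(float(rate))
        if r0 in self.terms:
            self.terms[r0] = _trim(P.polyadd(self.terms[r0], coeffs))
        else:
            self.terms[r0] = coeffs

    # -- queries ------------------------------------------------------
    @property
    def rates(self) -> Tuple[float, ...]:
        return tuple(sorted(self.terms))

    @property
    def n_exponential_terms(self) -> int:
        """Number of genuinely exponential (nonzero-rate) terms."""
        return sum(1 for r in self.terms if r != 0.0)

    @property
    def max_degree(self) -> int:
        return max(len(c) - 1 for c in self.terms.values())

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for r, c in self.terms.items():
            out = out + P.polyval(x, c) * np.exp(r * x)
        return out if out.ndim else float(out)

    def integral(self, x0: float, y0: float) -> float:
        """Definite integral over ``[x0, y0]`` in closed form."""
        total = 0.0
        for r, c in self.terms.items():
            if r == 0.0:
                F = P.polyint(c)
                total += P.polyval(y0, F) - P.polyval(x0, F)
            else:
                q = _exp_antideriv(c, r)
                total += math.exp(r * y0) * P.polyval(y0, q) - math.exp(
                    r * x0
                ) * P.polyval(x0, q)
        return float(total)

    # -- algebra ------------------------------------------------------
    def scaled(self, a: float) -> "ExpSum":
        return ExpSum({r: a * c for r, c in self.terms.items()})

    def __add__(self, other: "ExpSum") -> "ExpSum":
        out = self.copy()
        for r, c in other.terms.items():
            out.add_term(r, c)
        return out

    def __mul__(self, other: "ExpSum") -> "ExpSum":
        out = ExpSum()
        for r1, c1 in self.terms.items():
            for r2, c2 in other.terms.items():
                out.add_term(r1 + r2, P.polymul(c1, c2))
        return out

    # -- the kernel step ----------------------------------------------
    def apply_kernel(self, k: AdvectiveKernelParams, x0: float, y0: float) -> "ExpSum":
        """Closed form of ``x -> integral over [x0,y0] of K(x - y) f(y) dy``.

        Each incoming term keeps its rate; the endpoint contributions feed
        the kernel's own rates (``a1`` from the right endpoint, ``a2`` from
        the left).  A rate colliding with ``a1`` or ``a2`` takes the
        confluent branch and raises the polynomial degree by one.
        """
        out = ExpSum()
        for r, p in self.terms.items():
            # downstream branch: A e^{a2 x} * int_{x0}^{x} p(y) e^{(r-a2) y} dy
            mu = r - k.a2
            if abs(mu) <= RATE_SNAP * max(1.0, abs(k.a2)):
                F = P.polyint(p)
                out.add_term(k.a2, k.A * P.polysub(F, [P.polyval(x0, F)]))
            else:
                q = _exp_antideriv(p, mu)
                out.add_term(r, k.A * q)
                out.add_term(k.a2, [-k.A * math.exp(mu * x0) * P.polyval(x0, q)])
            # upstream branch: A e^{a1 x} * int_{x}^{y0} p(y) e^{(r-a1) y} dy
            nu = r - k.a1
            if abs(nu) <= RATE_SNAP * max(1.0, abs(k.a1)):
                F = P.polyint(p)
                out.add_term(k.a1, k.A * P.polysub([P.polyval(y0, F)], F))
            else:
                q = _exp_antideriv(p, nu)
                out.add_term(r, -k.A * q)
                out.add_term(k.a1, [k.A * math.exp(nu * y0) * P.polyval(y0, q)])
        return out


def dispersal_success_expsum(k: AdvectiveKernelParams, h: Habitat) -> ExpSum:
    """The dispersal success function on the habitat as an exponential sum.

    Valid for arguments inside ``[x0, y0]``:
    ``s(y) = 1 + (A/a2) e^{a2 y0} e^{-a2 y} - (A/a1) e^{a1 x0} e^{-a1 y}``.
    """
    return ExpSum(
        {
            0.0: np.array([1.0]),
            -k.a2: np.array([(k.A / k.a2) * math.exp(k.a2 * h.y0)]),
            -k.a1: np.array([-(k.A / k.a1) * math.exp(k.a1 * h.x0)]),
        }
    )


def redistribution_expsum(k: AdvectiveKernelParams, h: Habitat) -> ExpSum:
    """The redistribution function on the habitat as an exponential sum.

    Valid for arguments inside ``[x0, y0]``:
    ``r(x) = 1 + (A/a2) e^{-a2 x0} e^{a2 x} - (A/a1) e^{-a1 y0} e^{a1 x}``.
    """
    return ExpSum(
        {
            0.0: np.array([1.0]),
            k.a2: np.array([(k.A / k.a2) * math.exp(-k.a2 * h.x0)]),
            k.a1: np.array([-(k.A / k.a1) * math.exp(-k.a1 * h.y0)]),
        }
    )
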