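"""Asymmetric advective dispersal kernels and their derived functionals.

An organism dispersing in a stream moves by advection (flow velocity ``v``),
diffusion (coefficient ``D``) and settles out of the water column at a
constant rate ``beta``.  Integrating the settling flux of the resulting
advection-diffusion-settling process over all time gives the dispersal
kernel: an asymmetric Laplace (two-sided exponential) density

    K(x - y) = A * exp(a1 * (x - y))   for x <  y   (upstream tail)
    K(x - y) = A * exp(a2 * (x - y))   for x >= y   (downstream tail)

with decay rates

    a_{1,2} = v/(2D) +/- sqrt(v^2/(4D^2) + beta/D),    a1 > 0 > a2,

and normalising amplitude ``A = a1*a2/(a2 - a1) = beta/sqrt(v^2 + 4*beta*D)``
so that the kernel integrates to one over the whole line.  With ``v = 0``
the kernel reduces to the symmetric Laplace kernel with rate
``a = sqrt(beta/D)``.

From the kernel we derive, in closed form,

* the *dispersal success function* ``s(y)``: the probability that an
  individual starting at ``y`` settles inside a bounded habitat
  ``Omega = [x0, y0]``;
* the *redistribution function* ``r(x)``: the expected settled density at
  ``x`` after a uniform unit-density release over the habitat;
* the moment generating function of the displacement, used to decide
  whether a population can outgrow wash-out on an infinitely long domain.

All functions accept scalars or NumPy arrays for the spatial argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AdvectiveKernelParams",
    "Habitat",
    "derive_rates",
    "kernel_density",
    "dispersal_success",
    "redistribution",
    "mgf",
    "pair_integral",
]


@dataclass(frozen=True)
class AdvectiveKernelParams:
    """Parameters of one asymmetric advective Laplace kernel.

    Attributes
    ----------
    v : float
        Advection velocity (length/step); may be zero or negative.
    D : float
        Diffusion coefficient (length^2/step), > 0.
    beta : float
        Settling rate (1/step), > 0.
    a1, a2 : float
        Upstream (> 0) and downstream (< 0) exponential decay rates
        (1/length), derived from ``(v, D, beta)``.
    A : float
        Normalising amplitude (1/length), > 0.
    """

    v: float
    D: float
    beta: float
    a1: float = field(init=False)
    a2: float = field(init=False)
    A: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.D > 0):
            raise ValueError(f"diffusion coefficient D must be > 0, got {self.D}")
        if not (self.beta > 0):
            raise ValueError(f"settling rate beta must be > 0, got {self.beta}")
        if not math.isfinite(self.v):
            raise ValueError(f"advection velocity v must be finite, got {self.v}")
        half = self.v / (2.0 * self.D)
        disc = math.sqrt(half * half + self.beta / self.D)
        object.__setattr__(self, "a1", half + disc)
        object.__setattr__(self, "a2", half - disc)
        object.__setattr__(
            self, "A", self.beta / math.sqrt(self.v**2 + 4.0 * self.beta * self.D)
        )


def derive_rates(v: float, D: float, beta: float) -> AdvectiveKernelParams:
    """Build kernel parameters, deriving decay rates and amplitude.

    Parameters
    ----------
    v : float
        Advection velocity; zero gives the symmetric Laplace kernel.
    D : float
        Diffusion coefficient, must be positive.
    beta : float
        Settling rate, must be positive.

    Returns
    -------
    AdvectiveKernelParams
    """
    return AdvectiveKernelParams(v=float(v), D=float(D), beta=float(beta))


@dataclass(frozen=True)
class Habitat:
    """A bounded habitat interval with a composite-Simpson quadrature grid.

    The kernel has a derivative kink on the diagonal ``x = y``; a uniform
    grid keeps that kink on quadrature nodes, preserving Simpson accuracy.

    Parameters
    ----------
    x0, y0 : float
        Habitat endpoints, ``x0 < y0``.
    n : int
        Number of nodes; must be odd and >= 3 (even number of panels).
    """

    x0: float
    y0: float
    n: int = 401

    def __post_init__(self) -> None:
        if not (self.x0 < self.y0):
            raise ValueError(f"require x0 < y0, got [{self.x0}, {self.y0}]")
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError(f"node count must be odd and >= 3, got {self.n}")

    @property
    def L(self) -> float:
        """Domain length ``y0 - x0``."""
        return self.y0 - self.x0

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(self.x0, self.y0, self.n)

    @property
    def weights(self) -> np.ndarray:
        """Composite Simpson weights; strictly positive, summing to ``L``."""
        h = self.L / (self.n - 1)
        w = np.full(self.n, 2.0)
        w[1::2] = 4.0
        w[0] = w[-1] = 1.0
        return w * (h / 3.0)

    def translated(self, new_x0: float) -> "Habitat":
        """Same grid shifted so the left endpoint sits at ``new_x0``."""
        return Habitat(new_x0, new_x0 + self.L, self.n)

    def centered(self) -> "Habitat":
        """The habitat translated to ``[-L/2, L/2]``."""
        return self.translated(-self.L / 2.0)


def kernel_density(k: AdvectiveKernelParams, x, y=0.0):
    """Kernel density ``K(x - y)``; the value on the diagonal is ``A``.

    ``K`` is a difference kernel, so ``y`` defaults to 0 and the
    two-argument call is sugar over the displacement form.
    """
    u = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    out = k.A * np.exp(np.where(u < 0, k.a1 * u, k.a2 * u))
    return out if out.ndim else float(out)


def _settled_below(k: AdvectiveKernelParams, u):
    """Probability of a displacement no greater than ``u`` (kernel CDF)."""
    u = np.asarray(u, dtype=float)
    lo = (k.A / k.a1) * np.exp(k.a1 * np.minimum(u, 0.0))
    hi = (k.A / k.a2) * (np.exp(k.a2 * np.maximum(u, 0.0)) - 1.0)
    return lo + np.where(u > 0, hi, 0.0)


def dispersal_success(k: AdvectiveKernelParams, h: Habitat, y):
    """Probability that a disperser starting at ``y`` settles in the habitat.

    Closed-form integral of the kernel over settling locations
    ``x in [x0, y0]``; always in ``[0, 1]``, and strictly below 1 for ``y``
    in the interior (mass is lost through both ends).
    """
    y = np.asarray(y, dtype=float)
    # clip: the difference of antiderivatives can round a hair outside [0, 1]
    out = np.clip(_settled_below(k, h.y0 - y) - _settled_below(k, h.x0 - y), 0.0, 1.0)
    return out if out.ndim else float(out)


def redistribution(k: AdvectiveKernelParams, h: Habitat, x):
    """Expected settled density at ``x`` after a uniform unit release on the habitat.

    Unlike dispersal success this need not stay below 1 when the kernel is
    asymmetric; for ``v = 0`` the two functions coincide.
    """
    x = np.asarray(x, dtype=float)
    out = np.maximum(_settled_below(k, x - h.x0) - _settled_below(k, x - h.y0), 0.0)
    return out if out.ndim else float(out)


def mgf(k: AdvectiveKernelParams, s: float) -> float:
    """Moment generating function ``E[exp(-s * displacement)]``.

    Sign convention: positive ``s`` tilts weight toward upstream
    displacements, so ``mgf`` grows as ``s`` approaches the upstream pole
    ``a1``.  Closed form ``beta / (beta + v*s - D*s^2)``, finite exactly for
    ``s`` strictly between ``a2`` and ``a1``; equals 1 at ``s = 0``.
    """
    if not (k.a2 < s < k.a1):
        raise ValueError(
            f"tilt s={s} outside the convergence strip ({k.a2}, {k.a1})"
        )
    return k.beta / (k.beta + k.v * s - k.D * s * s)


def pair_integral(k: AdvectiveKernelParams, h: Habitat) -> float:
    """Closed-form double integral of the kernel over the habitat square.

    Equals both ``integral of s(y) dy`` and ``integral of r(x) dx`` over the
    habitat (Fubini); used by the dispersal success approximation.
    """
    L = h.L
    t1 = (math.exp(-k.a1 * L) - 1.0 + k.a1 * L) / (k.a1 * k.a1)
    t2 = (math.exp(k.a2 * L) - 1.0 - k.a2 * L) / (k.a2 * k.a2)
    return k.A * (t1 + t2)
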