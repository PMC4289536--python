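"""Real-arithmetic exponential bases for eigenvalue boundary-value problems.

The eigenfunction of a dispersal-growth operator solves a constant
coefficient linear ODE, so it is a combination of terms ``x^j exp(r x)``
with ``r`` a characteristic root.  Depending on the candidate eigenvalue
the roots may be real, complex conjugate, or (nearly) repeated; this module
classifies the roots and evaluates derivatives of a real-valued basis in
each case, with per-function scaling so that entries stay bounded for long
domains.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from numpy.polynomial import polynomial as P

# relative threshold below which two real roots are merged (confluent basis)
CONFLUENT_RTOL = 1e-8
# relative threshold below which an imaginary part is treated as zero
REAL_RTOL = 1e-9


def basis_specs(roots: np.ndarray) -> List[Tuple[complex, int, str]]:
    """Classify characteristic roots into real basis functions.

    Returns a list of ``(r, j, part)`` triples describing the function
    ``part[x^j exp(r x)]`` with ``part`` one of ``"real"`` (real root),
    ``"re"``/``"im"`` (complex-conjugate pair).  Near-repeated real roots
    share ``r`` with increasing powers ``j`` (confluent basis).
    """
    roots = np.asarray(roots, dtype=complex)
    scale = max(1.0, float(np.max(np.abs(roots))))
    real_parts: List[float] = []
    specs: List[Tuple[complex, int, str]] = []
    for r in roots:
        if abs(r.imag) <= REAL_RTOL * scale:
            real_parts.append(r.real)
        elif r.imag > 0:
            specs.append((r, 0, "re"))
            specs.append((r, 0, "im"))
    # group near-equal real roots into confluent clusters
    real_parts.sort()
    i = 0
    while i < len(real_parts):
        j = i
        while j + 1 < len(real_parts) and real_parts[j + 1] - real_parts[j] <= CONFLUENT_RTOL * scale:
            j += 1
        r = float(np.mean(real_parts[i : j + 1]))
        for power in range(j - i + 1):
            specs.append((complex(r), power, "real"))
        i = j + 1
    return specs


def signature(roots: np.ndarray) -> Tuple[int, int]:
    """Root-structure fingerprint: (number of real roots, confluent clusters)."""
    specs = basis_specs(roots)
    n_real = sum(1 for _, _, part in specs if part == "real")
    n_confluent = sum(1 for _, j, _ in specs if j > 0)
    return (n_real, n_confluent)


def signature_from_specs(specs) -> Tuple[int, int]:
    n_real = sum(1 for _, _, part in specs if part == "real")
    n_confluent = sum(1 for _, j, _ in specs if j > 0)
    return (n_real, n_confluent)


def basis_derivative_table(
    specs: List[Tuple[complex, int, str]], xs: np.ndarray, kmax: int, L: float
) -> np.ndarray:
    """Derivatives 0..kmax of each basis function at each point of ``xs``.

    Output shape ``(n_basis, len(xs), kmax + 1)``, real-valued.  Each basis
    function carries a damping factor ``exp(-max(0, Re r) * L)`` so its
    values stay O(1) on ``[0, L]`` regardless of domain length.
    """
    xs = np.asarray(xs, dtype=float)
    if all(j == 0 for _, j, _ in specs):
        # pure-exponential fast path: d^k/dx^k e^{rx} = r^k e^{rx}
        r = np.array([s[0] for s in specs])
        shift = np.maximum(r.real, 0.0) * L
        base = np.exp(r[:, None] * xs[None, :] - shift[:, None])
        powers = r[:, None] ** np.arange(kmax + 1)[None, :]
        vals = base[:, :, None] * powers[:, None, :]
        out = np.where(
            np.array([part == "im" for _, _, part in specs])[:, None, None],
            vals.imag,
            vals.real,
        )
        return out
    out = np.empty((len(specs), xs.size, kmax + 1))
    for b, (r, j, part) in enumerate(specs):
        # derivative of p(x) e^{rx} is (p' + r p) e^{rx}
        poly = np.zeros(j + 1, dtype=complex)
        poly[j] = 1.0
        shift = max(0.0, r.real) * L
        for k in range(kmax + 1):
            vals = P.polyval(xs, poly) * np.exp(r * xs - shift)
            if part == "im":
                out[b, :, k] = vals.imag
            else:
                out[b, :, k] = vals.real
            poly = P.polyadd(P.polyder(poly), r * poly)
    return out


def boundary_matrix(rows: List[np.ndarray]) -> np.ndarray:
    """Stack row functionals (one array of basis coefficients each)."""
    return np.vstack(rows)


def scaled_det(A: np.ndarray) -> float:
    """Determinant after positive column normalization (sign-preserving)."""
    scale = np.max(np.abs(A), axis=0)
    scale[scale == 0] = 1.0
    return float(np.linalg.det(A / scale))
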