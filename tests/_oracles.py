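"""Independent numerical oracles used by the tests.

These deliberately avoid the code paths they check: the Bessel recovery
factor is evaluated from its power series (and, for large arguments, from
the standard asymptotic expansion of the exponentially scaled modified
Bessel functions), and ANM eigenproblems are solved with plain dense
eigendecompositions of explicitly assembled matrices.
"""

from __future__ import annotations

import math

import numpy as np


def bessel_i0_series(x: float, max_terms: int = 400) -> float:
    """I0(x) by its power series sum_k (x/2)^(2k) / (k!)^2."""
    term, total = 1.0, 1.0
    half2 = (x / 2.0) ** 2
    for k in range(1, max_terms):
        term *= half2 / (k * k)
        total += term
        if term < 1e-18 * total:
            break
    return total


def bessel_i1_series(x: float, max_terms: int = 400) -> float:
    """I1(x) by its power series sum_k (x/2)^(2k+1) / (k! (k+1)!)."""
    term = x / 2.0
    total = term
    half2 = (x / 2.0) ** 2
    for k in range(1, max_terms):
        term *= half2 / (k * (k + 1))
        total += term
        if term < 1e-18 * total:
            break
    return total


def scaled_recovery_series(x: float) -> float:
    """e^{-x} (I0(x) + I1(x)) via the power series (valid to ~1e-13
    relative for x <= ~60 in double precision)."""
    return math.exp(-x) * (bessel_i0_series(x) + bessel_i1_series(x))


def _asymptotic_scaled_iv(nu: int, x: float, n_terms: int = 10) -> float:
    """e^{-x} I_nu(x) from the large-argument asymptotic expansion."""
    mu = 4 * nu * nu
    total, a_k = 1.0, 1.0
    for k in range(1, n_terms):
        a_k *= (mu - (2 * k - 1) ** 2) / (8.0 * k)
        total += (-1) ** k * a_k / x**k
    return total / math.sqrt(2.0 * math.pi * x)


def scaled_recovery_asymptotic(x: float) -> float:
    """e^{-x}(I0 + I1) from the asymptotic series; accurate to better than
    1e-9 relative for x > 50."""
    return _asymptotic_scaled_iv(0, x) + _asymptotic_scaled_iv(1, x)


def scaled_recovery_oracle(x: float) -> float:
    return scaled_recovery_series(x) if x <= 50 else scaled_recovery_asymptotic(x)


def dimer_hessian(d: float = 1.0, gamma: float = 1.0) -> np.ndarray:
    """Explicit 6x6 ANM Hessian of two particles separated by d along x."""
    k = np.zeros((3, 3))
    k[0, 0] = gamma  # bond along x: only the xx component survives
    h = np.zeros((6, 6))
    h[:3, :3] = k
    h[3:, 3:] = k
    h[:3, 3:] = -k
    h[3:, :3] = -k
    return h


def dense_anm_reference(coords: np.ndarray, cutoff: float, gamma: float = 1.0):
    """Independent ANM assembly + dense eigendecomposition (loop form)."""
    n = len(coords)
    h = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            rij = coords[j] - coords[i]
            d2 = float(rij @ rij)
            if d2 <= cutoff**2:
                block = gamma * np.outer(rij, rij) / d2
                h[3 * i:3 * i + 3, 3 * j:3 * j + 3] = -block
                h[3 * i:3 * i + 3, 3 * i:3 * i + 3] += block
    evals, evecs = np.linalg.eigh(h)
    return evals, evecs
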