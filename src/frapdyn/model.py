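"""Two-state binding model for FRAP recovery curves.

The recovery of normalized fluorescence after photobleaching a subnuclear
region is described by a reaction--diffusion model with a freely diffusing
population, a fast-binding state whose exchange is absorbed into an
effective diffusion process, and a weakly bound state that recovers
exponentially (Sprague-type two-state binding model):

    frap(t) = (F_eq + C1_eq) * e^{-x} (I0(x) + I1(x)) + C2_eq (1 - e^{-k2_off t}),

with x = tau1_eff / (2 t) and I0, I1 the modified Bessel functions of the
first kind.  F_eq, C1_eq, C2_eq are the equilibrium fractions of the free
and the two bound states; tau1_eff is the effective recovery time of the
diffusion-coupled population; k2_off is the dissociation rate of the weakly
bound state.  The fractions need not sum to one: the deficit
1 - (F_eq + C1_eq + C2_eq) is the immobile fraction, i.e. molecules that do
not exchange on the observation time scale.

tau1_eff is treated as a phenomenological time constant; no bleach-spot
geometry enters the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "TwoStateParams",
    "diffusion_recovery_term",
    "two_state_frap",
    "plateau_and_fractions",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class TwoStateParams:
    """Parameter vector of the two-state binding recovery model.

    Parameters
    ----------
    f_eq : float
        Equilibrium free fraction, in [0, 1].
    c1_eq : float
        Equilibrium fraction of the fast binding state, in [0, 1].  Enters
        the model only through the sum ``f_eq + c1_eq``.
    c2_eq : float
        Equilibrium fraction of the weakly bound (slow) state, in [0, 1].
    tau1_eff : float
        Effective recovery time of the diffusion-coupled population, s.
    k2_off : float
        Dissociation rate of the weakly bound state, 1/s.
    """

    f_eq: float
    c1_eq: float
    c2_eq: float
    tau1_eff: float
    k2_off: float

    def __post_init__(self) -> None:
        for name in ("f_eq", "c1_eq", "c2_eq"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        s = self.f_eq + self.c1_eq + self.c2_eq
        if s > 1.0 + _SUM_TOL:
            raise ValueError(
                f"fractions must satisfy f_eq + c1_eq + c2_eq <= 1, got {s}"
            )
        if not np.isfinite(self.tau1_eff) or self.tau1_eff <= 0.0:
            raise ValueError(f"tau1_eff must be > 0, got {self.tau1_eff}")
        if not np.isfinite(self.k2_off) or self.k2_off <= 0.0:
            raise ValueError(f"k2_off must be > 0, got {self.k2_off}")

    @property
    def fast_amplitude(self) -> float:
        """The identifiable fast-recovery amplitude F_eq + C1_eq."""
        return self.f_eq + self.c1_eq

    @property
    def plateau(self) -> float:
        """Asymptotic recovery level F_eq + C1_eq + C2_eq (mobile fraction)."""
        return min(self.f_eq + self.c1_eq + self.c2_eq, 1.0)

    @property
    def immobile_fraction(self) -> float:
        """Deficit 1 - plateau: the fraction that never recovers."""
        return max(1.0 - (self.f_eq + self.c1_eq + self.c2_eq), 0.0)


def diffusion_recovery_term(t, tau1_eff: float):
    """Effective-diffusion recovery factor ``e^{-x}(I0(x) + I1(x))``.

    ``x = tau1_eff / (2 t)``.  The factor rises from 0 at the bleach instant
    (t = 0, defined by continuity: e^{-x} I_nu(x) ~ 1/sqrt(2 pi x) -> 0 as
    x -> inf) to 1 at long times (I0(0) = 1, I1(0) = 0).

    Evaluated with exponentially scaled Bessel functions (``i0e``, ``i1e``)
    so the product never overflows, for arguments up to at least 1e6.

    Parameters
    ----------
    t : array_like
        Time since bleach, s, >= 0.
    tau1_eff : float
        Effective recovery time, s, > 0.

    Returns
    -------
    ndarray or float
        Dimensionless recovery fraction in [0, 1].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not np.isfinite(tau1_eff) or tau1_eff <= 0:
        raise ValueError(f"tau1_eff must be > 0, got {tau1_eff}")
    out = np.zeros_like(t)
    pos = t > 0
    x = tau1_eff / (2.0 * t[pos])
    out[pos] = special.i0e(x) + special.i1e(x)
    return out if out.ndim else float(out)


def two_state_frap(t, params: TwoStateParams):
    """Evaluate the two-state binding recovery model at times ``t``.

    Returns ``(f_eq + c1_eq) * diffusion_recovery_term(t, tau1_eff)
    + c2_eq * (1 - e^{-k2_off t})``, a non-decreasing function of t bounded
    by the plateau ``f_eq + c1_eq + c2_eq``.
    """
    t = np.asarray(t, dtype=float)
    fast = params.fast_amplitude * diffusion_recovery_term(t, params.tau1_eff)
    slow = params.c2_eq * -np.expm1(-params.k2_off * t)
    out = fast + slow
    return out if out.ndim else float(out)


def plateau_and_fractions(params: TwoStateParams) -> dict:
    """Derived population fractions of a parameter vector.

    Returns a record with ``plateau`` (= mobile fraction, the asymptotic
    recovery), ``mobile_fraction``, ``immobile_fraction`` (the plateau
    deficit) and ``bound_fraction`` (= c1_eq + c2_eq + immobile: everything
    engaged with chromatin at equilibrium, transiently or stably).
    """
    plateau = params.f_eq + params.c1_eq + params.c2_eq
    immobile = max(1.0 - plateau, 0.0)
    return {
        "plateau": plateau,
        "mobile_fraction": plateau,
        "immobile_fraction": immobile,
        "bound_fraction": params.c1_eq + params.c2_eq + immobile,
    }
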