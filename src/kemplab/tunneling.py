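"""One-dimensional tunneling corrections: Wigner and Eckart κ(T).

This is a deliberate desk-scale stand-in for multidimensional
variational-TST tunneling treatments: the barrier is reduced to a 1D
asymmetric Eckart function matched to the forward barrier V1, reverse
barrier V2 and the magnitude of the imaginary frequency at the saddle
point.  κ multiplies a classical rate constant; it is >= 1 and decays to 1
at high temperature.  The module makes no claim to reproduce
multidimensional small/large-curvature tunneling results.

Transmission probability for the asymmetric Eckart barrier (closed form):
with alpha_i = 2*pi*V_i/(h*nu) and xi = E/V1,

    a = 2*sqrt(alpha1*xi) / (1/sqrt(alpha1) + 1/sqrt(alpha2))
    b = 2*sqrt((xi-1)*alpha1 + alpha2) / (1/sqrt(alpha1) + 1/sqrt(alpha2))
    d = 2*sqrt(alpha1*alpha2 - pi^2/4)

    P(E) = [cosh(2pi(a+b)) - cosh(2pi(a-b))] / [cosh(2pi(a+b)) + cosh(2pi*d)]

and the thermal transmission coefficient is the Boltzmann average

    kappa(T) = exp(V1/kBT) * (1/kBT) * Int_0^inf P(E) exp(-E/kBT) dE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import quad

from kemplab.constants import GAS_CONSTANT_KCAL, HC_OVER_KB_CM_K

__all__ = [
    "BarrierSpec",
    "TunnelingResult",
    "wigner_kappa",
    "eckart_kappa",
    "eckart_transmission",
    "kappa_curve",
    "corrected_kie",
]

#: Deep-tunneling guard: flag κ estimates beyond this as unreliable for a
#: 1D parabolic-top treatment.
_KAPPA_FLAG_THRESHOLD = 1e3


@dataclass(frozen=True)
class BarrierSpec:
    """1D barrier: forward/reverse heights (kcal/mol), imaginary frequency
    magnitude (cm^-1) and the mass of the transferring particle (amu)."""

    forward_barrier: float
    reverse_barrier: float
    imag_freq_cm: float
    mass_amu: float = 1.008

    def __post_init__(self):
        if self.forward_barrier <= 0 or self.reverse_barrier <= 0:
            raise ValueError("barrier heights must be positive")
        if self.imag_freq_cm <= 0:
            raise ValueError("imaginary frequency magnitude must be positive")
        if self.mass_amu <= 0:
            raise ValueError("mass must be positive")

    def isotopologue(self, mass_amu: float) -> "BarrierSpec":
        """Mass-scaled barrier: same heights, frequency scaled by
        sqrt(m_old/m_new) (pure H-transfer mode assumption)."""
        scale = math.sqrt(self.mass_amu / mass_amu)
        return replace(self, imag_freq_cm=self.imag_freq_cm * scale,
                       mass_amu=mass_amu)


def wigner_kappa(freq_cm: float, temp_K: float) -> float:
    """Leading-order Wigner tunneling correction κ = 1 + u²/24.

    ``u = h*c*nu/(kB*T)`` with ``h*c/kB = 1.43877 cm K``.
    """
    if freq_cm <= 0 or temp_K <= 0:
        raise ValueError("frequency and temperature must be positive")
    u = HC_OVER_KB_CM_K * freq_cm / temp_K
    return 1.0 + u * u / 24.0


def _log_cosh(x: float) -> float:
    """log(cosh(x)) stable for large |x|."""
    ax = abs(x)
    return ax + math.log1p(math.exp(-2.0 * ax)) - math.log(2.0)


def eckart_transmission(barrier: BarrierSpec, energy: float) -> float:
    """Closed-form transmission probability P(E) of the asymmetric Eckart
    barrier, E measured from the reactant asymptote (kcal/mol)."""
    if energy <= 0.0:
        return 0.0
    v1 = barrier.forward_barrier
    v2 = barrier.reverse_barrier
    # h*nu in kcal/mol: u = (hc/kB)*nu/T  =>  h*c*nu = kB * 1.43877 * nu
    h_nu = GAS_CONSTANT_KCAL * HC_OVER_KB_CM_K * barrier.imag_freq_cm
    a1 = 2.0 * math.pi * v1 / h_nu
    a2 = 2.0 * math.pi * v2 / h_nu
    xi = energy / v1
    denom = 1.0 / math.sqrt(a1) + 1.0 / math.sqrt(a2)
    # arguments of the cosh terms: 2*pi*a, 2*pi*b, 2*pi*d in reduced form
    arg_a = 2.0 * math.sqrt(a1 * xi) / denom
    b_sq = (xi - 1.0) * a1 + a2
    if b_sq <= 0.0:
        # below the product-side asymptote: no open channel
        return 0.0
    arg_b = 2.0 * math.sqrt(b_sq) / denom
    disc = a1 * a2 - math.pi**2 / 4.0
    log_hi = _log_cosh(arg_a + arg_b)
    log_lo = _log_cosh(arg_a - arg_b)
    if disc >= 0.0:
        # thick barrier: cosh(2*pi*d) term, log-space for stability
        log_d = _log_cosh(2.0 * math.sqrt(disc))
        m = max(log_hi, log_d)
        num = math.exp(log_hi - m) - math.exp(log_lo - m)
        den = math.exp(log_hi - m) + math.exp(log_d - m)
    else:
        # thin barrier: the d-term continues to cos(2*sqrt(-disc)), |.| <= 1
        cos_d = math.cos(2.0 * math.sqrt(-disc))
        m = log_hi
        num = 1.0 - math.exp(log_lo - m)
        den = 1.0 + cos_d * math.exp(-m)
    return min(max(num / den, 0.0), 1.0)


@dataclass
class TunnelingResult:
    """κ(T) series with provenance and reliability flag."""

    method: str
    temperatures: np.ndarray
    kappa: np.ndarray
    flagged: bool = False
    note: str = ""

    def to_records(self) -> list[dict]:
        return [
            {"temp_K": float(t), "kappa": float(k), "method": self.method}
            for t, k in zip(self.temperatures, self.kappa)
        ]


def eckart_kappa(barrier: BarrierSpec, temp_K: float) -> float:
    """Thermally averaged Eckart transmission coefficient κ(T).

    Adaptive quadrature of P(E)exp(-E/kBT) over E in [0, V1 + 40 kBT],
    relative tolerance 1e-6; energy zero at the reactant asymptote.
    """
    if temp_K <= 0:
        raise ValueError("temperature must be positive")
    kT = GAS_CONSTANT_KCAL * temp_K
    v1 = barrier.forward_barrier
    upper = v1 + 40.0 * kT

    def below(e):
        # exp((V1-E)/kT) keeps the integrand O(1) near the barrier top
        return eckart_transmission(barrier, e) * math.exp((v1 - e) / kT)

    def above(e):
        # subtract the classical step so the smooth remainder integrates
        # accurately even when kT dwarfs the barrier region
        return (eckart_transmission(barrier, e) - 1.0) * math.exp((v1 - e) / kT)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo, _ = quad(below, 0.0, v1, epsrel=1e-6, limit=500)
        hi, _ = quad(above, v1, upper, epsrel=1e-6, limit=500)
    # classical part above the barrier integrates to kT (up to e^-40)
    kappa = 1.0 + (lo + hi) / kT
    if not math.isfinite(kappa) or kappa > _KAPPA_FLAG_THRESHOLD:
        warnings.warn(
            "deep-tunneling regime: 1D Eckart kappa unreliable", stacklevel=2
        )
    return kappa


def kappa_curve(barrier: BarrierSpec, temperatures, method: str = "eckart") -> TunnelingResult:
    """κ over a temperature grid, as a :class:`TunnelingResult`."""
    temps = np.asarray(temperatures, dtype=float)
    if method == "wigner":
        kap = np.array([wigner_kappa(barrier.imag_freq_cm, t) for t in temps])
    elif method == "eckart":
        kap = np.array([eckart_kappa(barrier, t) for t in temps])
    else:
        raise ValueError(f"unknown method {method!r}")
    flagged = bool(np.any(~np.isfinite(kap)) or np.any(kap > _KAPPA_FLAG_THRESHOLD))
    return TunnelingResult(method=method, temperatures=temps, kappa=kap,
                           flagged=flagged,
                           note="1D stand-in; not a multidimensional MT result")


def corrected_kie(classical_kie: float, kappa_H: float, kappa_D: float) -> float:
    """Tunneling-corrected KIE = (κ_H/κ_D) * classical KIE.

    κ_H < κ_D violates the mass-scaling invariant (lighter isotope tunnels
    more) and raises.
    """
    if classical_kie <= 0 or kappa_H <= 0 or kappa_D <= 0:
        raise ValueError("all inputs must be positive")
    if kappa_H < kappa_D:
        raise ValueError("kappa_H < kappa_D violates the isotope-mass invariant")
    return (kappa_H / kappa_D) * classical_kie
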