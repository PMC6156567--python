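"""Exactly solvable two-parabola (Marcus) surrogate for the EVB machinery.

Two shifted harmonic diabats along a single coordinate x,

    eps1(x) = 0.5 k (x + d)^2
    eps2(x) = 0.5 k (x - d)^2 + dG0_intrinsic

have reorganisation energy lambda_r = 2 k d^2 and, in the uncoupled limit,
the Marcus barrier dG‡ = (lambda_r + dG0)^2 / (4 lambda_r).  A coupling H12
lowers the symmetric-crossing barrier by ~H12.  Because every mapping
potential (1-lam) eps1 + lam eps2' is itself harmonic in x, frames can be
sampled *exactly* (Gaussian), giving an enumerable oracle for the FEP and
umbrella-sampling estimators and a closed-form test bed for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from kemplab.constants import KB_KCAL
from kemplab.evb.fep import MappingFrame

__all__ = ["TwoParabolaSurrogate", "HarmonicToggleSurrogate"]


@dataclass
class TwoParabolaSurrogate:
    """Shifted harmonic diabats with known Marcus free energies."""

    k: float = 0.5  # kcal/mol/Å^2 (units of x arbitrary)
    d: float = 10.0
    dg0: float = 0.0  # intrinsic offset of state 2 (before any alpha)

    @property
    def reorganization_energy(self) -> float:
        return 2.0 * self.k * self.d**2

    def marcus_barrier(self, alpha: float = 0.0) -> float:
        lr = self.reorganization_energy
        dg0 = self.dg0 + alpha
        return (lr + dg0) ** 2 / (4.0 * lr)

    def eps1(self, x):
        return 0.5 * self.k * (np.asarray(x, float) + self.d) ** 2

    def eps2_raw(self, x):
        return 0.5 * self.k * (np.asarray(x, float) - self.d) ** 2 + self.dg0

    def sample_frames(self, lambdas=None, n_samples=4000, temperature=300.0,
                      alpha=0.0, seed=0) -> list[MappingFrame]:
        """Draw exact Boltzmann samples of every mapping window.

        Em(x) = 0.5 k x^2 + k d (1 - 2 lam) x + const is harmonic with mean
        -d(1-2lam) and variance kT/k, so sampling is exact — estimator error
        is purely statistical.
        """
        if lambdas is None:
            lambdas = np.linspace(0.0, 1.0, 51)
        rng = np.random.default_rng(seed)
        kT = KB_KCAL * temperature
        sd = np.sqrt(kT / self.k)
        frames = []
        for lam in np.asarray(lambdas, float):
            mean = -self.d * (1.0 - 2.0 * lam)
            x = rng.normal(mean, sd, size=n_samples)
            frames.append(MappingFrame(
                lam=float(lam), eps1=self.eps1(x), eps2_raw=self.eps2_raw(x),
                alpha_map=alpha, temperature=temperature))
        return frames

    def simulator(self, lambdas=None, n_samples=4000, temperature=300.0):
        """``(alpha, seed) -> frames`` adapter for the calibration loop."""

        def run(alpha, seed):
            return self.sample_frames(lambdas=lambdas, n_samples=n_samples,
                                      temperature=temperature, alpha=alpha,
                                      seed=int(seed) % 2**31)

        return run

    def exact_profile(self, H12=0.0, alpha=0.0, temperature=300.0,
                      bin_width=1.0, x_pad=6.0, n_grid=200001):
        """Direct Boltzmann integration over a dense x grid (oracle).

        Returns (bin_centers, dg, barrier, reaction_dG) computed by
        numerically integrating exp(-beta Eg(x)) within each gap bin —
        independent of the FEP/umbrella estimator path.
        """
        from kemplab.evb.energy import ground_state

        kT = KB_KCAL * temperature
        sd = np.sqrt(kT / self.k)
        x = np.linspace(-self.d - x_pad * sd, self.d + x_pad * sd, n_grid)
        e1 = self.eps1(x)
        e2 = self.eps2_raw(x) + alpha
        eg, _ = ground_state(e1, e2, H12)
        gap = e1 - e2
        lo = np.floor(gap.min() / bin_width) * bin_width
        hi = np.ceil(gap.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
        centers = 0.5 * (edges[:-1] + edges[1:])
        w = np.exp(-(eg - eg.min()) / kT)
        idx = np.clip(((gap - lo) / bin_width).astype(int), 0, len(centers) - 1)
        mass = np.bincount(idx, weights=w, minlength=len(centers))
        valid = mass > 0
        dg = np.full(len(centers), np.nan)
        dg[valid] = -kT * np.log(mass[valid])
        neg = np.where(valid & (centers < 0))[0]
        pos = np.where(valid & (centers >= 0))[0]
        r = neg[np.nanargmin(dg[neg])]
        p = pos[np.nanargmin(dg[pos])]
        between = np.arange(r, p + 1)
        between = between[valid[between]]
        ts = between[np.nanargmax(dg[between])]
        dg = dg - dg[r]
        return centers[valid], dg[valid], float(dg[ts]), float(dg[p])


@dataclass
class HarmonicToggleSurrogate:
    """eps1 = 0.5 k1 x^2, eps2 = 0.5 k2 x^2: a frequency change with the
    closed-form DG = 0.5 kT ln(k2/k1) between the end states."""

    k1: float = 1.0
    k2: float = 4.0

    def exact_dG(self, temperature=300.0) -> float:
        return 0.5 * KB_KCAL * temperature * np.log(self.k2 / self.k1)

    def sample_frames(self, lambdas=None, n_samples=20000, temperature=300.0,
                      seed=0) -> list[MappingFrame]:
        if lambdas is None:
            lambdas = np.linspace(0.0, 1.0, 11)
        rng = np.random.default_rng(seed)
        kT = KB_KCAL * temperature
        frames = []
        for lam in np.asarray(lambdas, float):
            k_eff = (1.0 - lam) * self.k1 + lam * self.k2
            x = rng.normal(0.0, np.sqrt(kT / k_eff), size=n_samples)
            frames.append(MappingFrame(
                lam=float(lam), eps1=0.5 * self.k1 * x**2,
                eps2_raw=0.5 * self.k2 * x**2, alpha_map=0.0,
                temperature=temperature))
        return frames
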