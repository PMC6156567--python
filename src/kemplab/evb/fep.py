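"""Free-energy estimation from EVB mapping frames: FEP and umbrella binning.

A mapping frame m holds samples of the two diabatic energies collected
while the system moved on Em = (1-lam_m)*eps1 + lam_m*eps2' (eps2' =
eps2_raw + alpha_map).  Free energies between adjacent frames come from the
exponential-average (Zwanzig) formula; the free-energy profile along the
energy-gap coordinate X = eps1 - eps2' is assembled by umbrella-sampling
reweighting of the per-frame gap histograms onto the ground-state surface:

    dG(X) = DG(lam_m) - kT * ln < delta(X - X') exp(-beta (Eg - Em)) >_m

Because the trajectories depend only on the mapping potential, a candidate
coupling (H12, alpha) can be screened on existing samples by recomputing Eg
and X while keeping Em (and hence DG(lam)) fixed — the basis of the
calibration loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from kemplab.constants import KB_KCAL

__all__ = ["MappingFrame", "FEPResult", "FreeEnergyProfile",
           "fep_free_energy", "umbrella_profile"]


@dataclass
class MappingFrame:
    """Samples of one mapping window at fixed lambda."""

    lam: float
    eps1: np.ndarray  # kcal/mol, per sample (includes shared terms)
    eps2_raw: np.ndarray  # eps2 *without* the gas-phase shift
    alpha_map: float  # gas shift used when the frame was simulated
    temperature: float = 300.0
    length_ps: float = 0.0

    def __post_init__(self):
        self.eps1 = np.asarray(self.eps1, float)
        self.eps2_raw = np.asarray(self.eps2_raw, float)
        if self.eps1.shape != self.eps2_raw.shape:
            raise ValueError("eps1/eps2 sample arrays must match")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.eps1)

    def eps2_prime(self, alpha: float | None = None) -> np.ndarray:
        a = self.alpha_map if alpha is None else alpha
        return self.eps2_raw + a

    def mapping_energy(self, lam: float | None = None) -> np.ndarray:
        """Em of these samples on the *sampled* mapping (alpha_map)."""
        lm = self.lam if lam is None else lam
        return (1.0 - lm) * self.eps1 + lm * self.eps2_prime()

    def gap(self, alpha: float | None = None) -> np.ndarray:
        return self.eps1 - self.eps2_prime(alpha)


def _check_frames(frames):
    if len(frames) < 2:
        raise ValueError("need at least two mapping frames")
    lams = np.array([f.lam for f in frames])
    if np.any(np.diff(lams) <= 0):
        raise ValueError("frames must have strictly increasing lambda")
    return lams


def _exp_average(delta_e, beta):
    """-kT ln <exp(-beta dE)> with a max-shift for numerical stability, plus
    the effective sample size of the exponential weights."""
    w = -beta * delta_e
    m = w.max()
    ew = np.exp(w - m)
    dg = -(m + np.log(ew.mean())) / beta
    ess = float(ew.sum() ** 2 / (ew**2).sum())
    return float(dg), ess


@dataclass
class FEPResult:
    lambdas: np.ndarray
    dG: np.ndarray  # cumulative, referenced to lambda=0
    window_dG: np.ndarray
    ess: np.ndarray  # effective sample size per window
    warnings: list = field(default_factory=list)


def fep_free_energy(frames, temperature=300.0, *, bidirectional=False,
                    min_ess=10.0) -> FEPResult:
    """Free energy along the mapping ladder by exponential averaging.

    Forward-only by default (samples of frame m evaluated on frame m+1's
    mapping potential); ``bidirectional`` averages the forward estimate with
    the negated reverse one.  Windows whose exponential weights have an
    effective sample size below ``min_ess`` are flagged on the result.
    """
    lams = _check_frames(frames)
    beta = 1.0 / (KB_KCAL * temperature)
    n_win = len(frames) - 1
    w_dg = np.empty(n_win)
    ess = np.empty(n_win)
    notes = []
    for m in range(n_win):
        f0, f1 = frames[m], frames[m + 1]
        # target Em's use each frame's own sampled alpha; on a consistent
        # series alpha_map is constant across frames
        d_fwd = ((1.0 - lams[m + 1]) * f0.eps1 + lams[m + 1] * f0.eps2_prime()) \
            - f0.mapping_energy()
        dg_f, ess_f = _exp_average(d_fwd, beta)
        if bidirectional:
            d_bwd = ((1.0 - lams[m]) * f1.eps1 + lams[m] * f1.eps2_prime()) \
                - f1.mapping_energy()
            dg_b, ess_b = _exp_average(d_bwd, beta)
            w_dg[m] = 0.5 * (dg_f - dg_b)
            ess[m] = min(ess_f, ess_b)
        else:
            w_dg[m] = dg_f
            ess[m] = ess_f
        if ess[m] < min_ess:
            notes.append(
                f"window {m} (lam {lams[m]:.3f}->{lams[m+1]:.3f}): ESS {ess[m]:.1f}"
            )
    if notes:
        warnings.warn("poorly converged FEP windows: " + "; ".join(notes),
                      stacklevel=2)
    dG = np.concatenate([[0.0], np.cumsum(w_dg)])
    return FEPResult(lambdas=lams, dG=dG, window_dG=w_dg, ess=ess,
                     warnings=notes)


@dataclass
class FreeEnergyProfile:
    """Free energy along the energy-gap coordinate, referenced so that the
    reactant minimum is zero."""

    bin_centers: np.ndarray
    dg: np.ndarray
    counts: np.ndarray
    barrier: float  # dG‡
    reaction_dG: float  # dG0
    reactant_bin: int
    ts_bin: int
    product_bin: int
    flags: list = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {"X": float(x), "dG": float(g), "count": int(c)}
            for x, g, c in zip(self.bin_centers, self.dg, self.counts)
        ]


def umbrella_profile(frames, temperature=300.0, bin_width=2.0, min_count=10,
                     H12=None, alpha=None, *, bidirectional=False,
                     fep: FEPResult | None = None) -> FreeEnergyProfile:
    """Assemble dG(X) from mapping frames by FEP/umbrella-sampling.

    ``H12``/``alpha`` default to the values the frames were simulated with;
    passing different values re-analyses the same samples for a candidate
    coupling (the mapping free energies DG(lam) stay those of the sampled
    potential).  ``H12`` may be a constant or a callable of the raw gap.
    """
    from kemplab.evb.energy import ground_state

    lams = _check_frames(frames)
    beta = 1.0 / (KB_KCAL * temperature)
    if fep is None:
        fep = fep_free_energy(frames, temperature, bidirectional=bidirectional)

    gaps = [f.gap(alpha) for f in frames]
    all_gaps = np.concatenate(gaps)
    if not (all_gaps.min() < 0.0 < all_gaps.max()):
        raise ValueError(
            "frames do not span both basins: the energy-gap coordinate "
            "never changes sign"
        )
    lo = np.floor(all_gaps.min() / bin_width) * bin_width
    hi = np.ceil(all_gaps.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width * 0.5, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)

    num = np.zeros(n_bins)  # sum over frames of n_m(bin) * dg_m(bin)
    counts = np.zeros(n_bins, dtype=int)
    for m, f in enumerate(frames):
        x = gaps[m]
        e2p = f.eps2_prime(alpha)
        h = H12 if H12 is not None else _frame_h12(f)
        h_val = h(x) if callable(h) else h
        eg, _ = ground_state(f.eps1, e2p, h_val)
        em = f.mapping_energy()
        w = -beta * (eg - em)
        idx = np.clip(((x - lo) / bin_width).astype(int), 0, n_bins - 1)
        n_tot = len(x)
        for b in np.unique(idx):
            sel = idx == b
            n_b = int(sel.sum())
            shift = w[sel].max()
            # <delta(X - X_b) exp(-beta(Eg - Em))>_m over *all* frame samples
            mean_w = np.exp(w[sel] - shift).sum() / n_tot
            dg_mb = fep.dG[m] - (shift + np.log(mean_w)) / beta
            num[b] += n_b * dg_mb
            counts[b] += n_b
    valid = counts >= max(min_count, 1)
    if valid.sum() < 3:
        raise ValueError("too few populated gap bins for a profile")
    dg = np.where(valid, num / np.maximum(counts, 1), np.nan)

    vidx = np.where(valid)[0]
    neg = vidx[centers[vidx] < 0.0]
    pos = vidx[centers[vidx] >= 0.0]
    flags = []
    if len(neg) == 0 or len(pos) == 0:
        raise ValueError("no populated bins on one side of the crossing")
    r_bin = int(neg[np.nanargmin(dg[neg])])
    p_bin = int(pos[np.nanargmin(dg[pos])])
    between = vidx[(vidx >= r_bin) & (vidx <= p_bin)]
    ts_bin = int(between[np.nanargmax(dg[between])])
    if ts_bin in (r_bin, p_bin):
        flags.append("monotone profile: no interior barrier found")
    ref = dg[r_bin]
    dg = dg - ref
    barrier = float(dg[ts_bin])
    reaction = float(dg[p_bin])
    return FreeEnergyProfile(
        bin_centers=centers[valid], dg=dg[valid], counts=counts[valid],
        barrier=barrier, reaction_dG=reaction,
        reactant_bin=int(np.searchsorted(np.where(valid)[0], r_bin)),
        ts_bin=int(np.searchsorted(np.where(valid)[0], ts_bin)),
        product_bin=int(np.searchsorted(np.where(valid)[0], p_bin)),
        flags=flags,
    )


def _frame_h12(frame):
    # frames produced by the dynamics module don't carry the coupling;
    # analysis defaults to H12 = 0 unless one is supplied
    return 0.0
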