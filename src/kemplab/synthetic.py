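"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its seed and parameters
(bit-reproducible), and emits the truth alongside the data so downstream
estimators can be validated without external inputs:

* :func:`gen_rate_data` — Michaelis–Menten/Arrhenius rate tables for H/D
  isotopologue pairs with multiplicative lognormal noise (the natural noise
  model for positive kinetic rates) plus a background (buffer) series.
* :func:`gen_toy_evb_system` — a C–H donor / carboxylate-like acceptor
  proton-transfer complex in a droplet of flexible 3-site waters, with
  two-state EVB parameters.
* :func:`gen_rotamer_traj` — multi-state dihedral trajectories: a Markov
  chain over substates with von Mises angular emission.
* :func:`gen_cluster_fixture` — rigid-template coordinate blobs with known
  cluster membership for RMSD clustering tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kemplab.evb.topology import EVBCoupling, EVBStateParams, EVBSystem

__all__ = [
    "GeneratorConfig",
    "gen_rate_data",
    "gen_toy_evb_system",
    "gen_rotamer_traj",
    "gen_cluster_fixture",
    "mapping_simulator",
    "DEFAULT_TEMPERATURES",
]

#: Assay temperature grid, K (10-50 °C).
DEFAULT_TEMPERATURES = (283.0, 293.0, 298.0, 303.0, 308.0, 313.0, 318.0, 323.0)

#: Substrate concentration ladder, mM (9-11 points in 0.01-1.1 mM).
DEFAULT_CONCENTRATIONS = (0.01, 0.025, 0.05, 0.1, 0.2, 0.35, 0.55, 0.8, 1.1)

#: Arrhenius truth per variant and isotope: (Ea kcal/mol, lnA).  The KM (mM)
#: truth is per variant.  Values are representative of an early and a late
#: round of laboratory evolution of a Kemp eliminase plus the uncatalysed
#: background reaction.
DEFAULT_KINETIC_TRUTH = {
    "R1": {"H": (10.8, 14.0), "D": (15.1, 19.6), "KM_mM": 0.96},
    "R7-2": {"H": (6.9, 12.7), "D": (11.3, 18.1), "KM_mM": 0.55},
}
DEFAULT_BACKGROUND_TRUTH = {"H": (14.5, 13.7), "D": (16.7, 16.0)}


@dataclass
class GeneratorConfig:
    """Bundle of generator settings; every emitted artifact records ``seed``."""

    seed: int = 0
    noise: float = 0.02  # lognormal sigma on rates
    kinetic_truth: dict = field(default_factory=lambda: dict(DEFAULT_KINETIC_TRUTH))
    temperatures: tuple = DEFAULT_TEMPERATURES
    concentrations: tuple = DEFAULT_CONCENTRATIONS
    replicates: int = 3
    # rotamer generator
    substate_fractions: dict = field(default_factory=lambda: {"A": 0.7, "B": 0.2, "C": 0.1})
    vonmises_kappa: float = 20.0
    persistence: float = 0.95
    n_frames: int = 5000
    # EVB droplet
    droplet_radius: float = 7.0
    n_waters: int = 30


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def _arrhenius_rate(Ea, lnA, T):
    from kemplab.constants import GAS_CONSTANT_KCAL

    return math.exp(lnA - Ea / (GAS_CONSTANT_KCAL * T))


def gen_rate_data(seed=0, noise=0.02, truth=None, background_truth=None,
                  temperatures=DEFAULT_TEMPERATURES,
                  concentrations=DEFAULT_CONCENTRATIONS, replicates=3):
    """Michaelis–Menten/Arrhenius rate table with planted parameters.

    Observed rates are ``kcat(T) * [S]/(KM + [S]) + k_background(T)`` with
    multiplicative lognormal noise of sigma ``noise``; the background
    (buffer) series is emitted as variant ``"B"`` at the saturating model
    ``k_bg(T)`` directly.  Returns ``(RateTable, truth_dict)``.
    """
    from kemplab.kinetics import RateTable

    if truth is None:
        truth = DEFAULT_KINETIC_TRUTH
    if background_truth is None:
        background_truth = DEFAULT_BACKGROUND_TRUTH
    temperatures = np.asarray(temperatures, float)
    if np.any(temperatures <= 0):
        raise ValueError("temperatures must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for iso, (ea, lna) in background_truth.items():
        for T in temperatures:
            k_bg = _arrhenius_rate(ea, lna, T)
            for rep in range(replicates):
                fac = math.exp(rng.normal(0.0, noise)) if noise > 0 else 1.0
                rows.append(("B", iso, 0.0, T, k_bg * fac, rep))
    for variant, spec in truth.items():
        km = spec["KM_mM"]
        for iso in ("H", "D"):
            ea, lna = spec[iso]
            for T in temperatures:
                kcat = _arrhenius_rate(ea, lna, T)
                k_bg = _arrhenius_rate(*background_truth[iso], T)
                for conc in concentrations:
                    v = kcat * conc / (km + conc) + k_bg
                    for rep in range(replicates):
                        fac = math.exp(rng.normal(0.0, noise)) if noise > 0 else 1.0
                        rows.append((variant, iso, conc, T, v * fac, rep))
    frame = pd.DataFrame(rows, columns=["variant", "isotope", "conc_mM",
                                        "temp_K", "rate_per_s", "replicate"])
    truth_out = {"seed": int(seed), "noise": noise,
                 "variants": truth, "background": background_truth}
    return RateTable(frame), truth_out


# ---------------------------------------------------------------------------
# Toy EVB droplet
# ---------------------------------------------------------------------------

# solute atoms: Cd (donor carbon), Ht (transferring H), Oa (acceptor
# oxygen), Cc (carboxylate carbon), Ob (distal oxygen)
_SOLUTE_NAMES = ["Cd", "Ht", "Oa", "Cc", "Ob"]
_SOLUTE_MASSES = [12.011, 1.008, 15.999, 12.011, 15.999]
_SOLUTE_XYZ = np.array([
    [-1.45, 0.00, 0.00],   # Cd
    [-0.36, 0.00, 0.00],   # Ht (1.09 from Cd, on the transfer axis)
    [1.45, 0.00, 0.00],    # Oa
    [2.70, 0.15, 0.00],    # Cc
    [3.35, 1.20, 0.00],    # Ob
])
# per-state charges (e): state 1 = substrate C-H + carboxylate(-1);
# state 2 = carbanion(-1) + neutral acid O-H
_Q_STATE1 = [-0.25, 0.25, -0.80, 0.60, -0.80]
_Q_STATE2 = [-1.00, 0.45, -0.45, 0.60, -0.60]
# the transferring H carries a small LJ core: with partial Morse bonds at
# intermediate lambda it would otherwise collapse onto a water oxygen
_SOLUTE_SIGMA = [3.50, 1.60, 3.00, 3.40, 3.00]
_SOLUTE_EPS = [0.066, 0.02, 0.17, 0.07, 0.17]

# flexible 3-site water (SPC/Fw-like)
_W_Q = [-0.82, 0.41, 0.41]
_W_SIGMA = [3.166, 0.0, 0.0]
_W_EPS = [0.155, 0.0, 0.0]
_W_ROH = 1.012
_W_THETA = 113.24  # deg
_W_KB = 1059.162  # kcal/mol/Å^2 (0.5*k convention)
_W_KA = 75.90  # kcal/mol/rad^2
_W_RHH = 2.0 * _W_ROH * math.sin(math.radians(_W_THETA) / 2.0)

# Morse parameters for the forming/breaking bonds
_MORSE_CH = (98.0, 1.8, 1.09)  # D, beta, r0 for Cd-Ht (state 1)
_MORSE_OH = (102.0, 2.2, 0.96)  # Oa-Ht (state 2)


def _water_template(rng):
    """One water at the origin with random orientation."""
    theta = math.radians(_W_THETA)
    local = np.array([
        [0.0, 0.0, 0.0],
        [_W_ROH, 0.0, 0.0],
        [_W_ROH * math.cos(theta), _W_ROH * math.sin(theta), 0.0],
    ])
    # random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return local @ q.T


def gen_toy_evb_system(seed=0, droplet_radius=7.0, n_waters=30,
                       shake_waters=True, restraint_k=1.0,
                       donor_acceptor_r0=2.9, max_retries=50000) -> EVBSystem:
    """Donor–H–acceptor proton-transfer complex in a water droplet.

    The solute is a united-atom C–H donor facing a carboxylate-like
    acceptor; state 1 binds the hydrogen to the carbon (Morse C–H), state 2
    to the acceptor oxygen (Morse O–H) with the corresponding charge shift.
    A weak harmonic distance restraint (``restraint_k``, default
    1 kcal/mol/Å^2) keeps the reacting fragment assembled, mirroring the
    restraint used for solution reference simulations; the droplet is bound
    by a harmonic radial wall.
    """
    if droplet_radius < 6.0:
        raise ValueError("droplet radius must be >= 6 Å")
    rng = np.random.default_rng(seed)
    names = list(_SOLUTE_NAMES)
    masses = list(_SOLUTE_MASSES)
    coords = [row.copy() for row in _SOLUTE_XYZ]
    q1 = list(_Q_STATE1)
    q2 = list(_Q_STATE2)
    sig = list(_SOLUTE_SIGMA)
    eps = list(_SOLUTE_EPS)
    constraints = []
    bonds_common = [(2, 3, 450.0, 1.26), (3, 4, 450.0, 1.26)]
    angles_common = [(2, 3, 4, 80.0, 126.0)]

    placed = np.array(coords)
    heavy = [i for i, s in enumerate(sig) if s > 0]  # O/C sites with LJ cores
    n_placed = 0
    tries = 0
    while n_placed < n_waters:
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"could not place {n_waters} waters in radius {droplet_radius}"
            )
        center = rng.uniform(-1.0, 1.0, 3) * (droplet_radius - 1.2)
        if np.linalg.norm(center) > droplet_radius - 1.2:
            continue
        w = _water_template(rng) + center
        # steric criteria: no atom-atom contact < 1.75 Å and the new oxygen
        # at least 2.4 Å from every existing LJ core
        d_all = np.linalg.norm(placed[:, None, :] - w[None, :, :], axis=2)
        if d_all.min() < 1.75:
            continue
        d_o = np.linalg.norm(placed[heavy] - w[0], axis=1)
        if d_o.min() < 2.4:
            continue
        base = len(names)
        names += [f"OW{n_placed}", f"HW{n_placed}a", f"HW{n_placed}b"]
        masses += [15.999, 1.008, 1.008]
        coords += [w[0], w[1], w[2]]
        q1 += _W_Q
        q2 += _W_Q
        sig += _W_SIGMA
        eps += _W_EPS
        bonds_common += [(base, base + 1, _W_KB, _W_ROH),
                         (base, base + 2, _W_KB, _W_ROH)]
        angles_common += [(base + 1, base, base + 2, _W_KA, _W_THETA)]
        if shake_waters:
            constraints += [(base, base + 1, _W_ROH), (base, base + 2, _W_ROH),
                            (base + 1, base + 2, _W_RHH)]
        heavy.append(len(placed))  # the new water oxygen
        placed = np.vstack([placed, w])
        n_placed += 1

    n = len(names)
    state1 = EVBStateParams(
        morse=(0, 1, *_MORSE_CH), charges=np.array(q1),
        lj_sigma=np.array(sig), lj_eps=np.array(eps),
        bonds=list(bonds_common), angles=list(angles_common))
    state2 = EVBStateParams(
        morse=(2, 1, *_MORSE_OH), charges=np.array(q2),
        lj_sigma=np.array(sig), lj_eps=np.array(eps),
        bonds=list(bonds_common), angles=list(angles_common))
    system = EVBSystem(
        names=names, masses=np.array(masses), coords=np.array(coords),
        states=(state1, state2), coupling=EVBCoupling(H12=0.0, alpha=0.0),
        droplet_radius=droplet_radius, wall_k=10.0,
        cutoff=min(10.0, 2.0 * droplet_radius),
        reacting_atoms=(0, 1, 2), donor=0, hydrogen=1, acceptor=2,
        # the transferring H never interacts nonbonded with either bonding
        # partner: in each state one of these pairs is the Morse bond and
        # evaluating LJ/Coulomb across the other at bonded distance would
        # swamp the energy gap with an unphysical clash
        exclusions={frozenset((0, 1)), frozenset((1, 2))},
        constraints=constraints,
        distance_restraints=[(0, 2, restraint_k, donor_acceptor_r0)],
    )
    return system


def mapping_simulator(system, n_steps=300, n_equil=100, dt=1.0,
                      temperature=300.0, sample_every=5, lambdas=None):
    """``(alpha, seed) -> frames`` adapter running the droplet mapping ladder
    (used by :func:`kemplab.evb.calibrate_reference`)."""
    from kemplab.evb.dynamics import run_mapping_series

    def run(alpha, seed):
        sys_a = system.with_coords(system.coords)
        sys_a.coupling = EVBCoupling(H12=system.coupling.H12,
                                     mu=system.coupling.mu, alpha=float(alpha))
        return run_mapping_series(sys_a, lambdas=lambdas, n_steps=n_steps,
                                  n_equil=n_equil, dt=dt,
                                  temperature=temperature,
                                  sample_every=sample_every,
                                  seed=int(seed) % 2**31)

    return run


# ---------------------------------------------------------------------------
# Rotamer trajectories
# ---------------------------------------------------------------------------

def gen_rotamer_traj(seed=0, fractions=None, kappa=20.0, persistence=0.95,
                     n_frames=5000, centers=None):
    """Markov-chain substate trajectory with von Mises angular emission.

    ``persistence`` is the probability of staying in the current state per
    frame; leaving, the next state is drawn from the stationary fractions
    (so the marginal state distribution matches ``fractions``).  Returns
    ``(series, labels, truth)`` where ``series`` maps dihedral name to a
    degree array and ``labels`` is the planted per-frame state.
    """
    from kemplab.substates import default_trp_glu_library

    if fractions is None:
        fractions = {"A": 0.7, "B": 0.2, "C": 0.1}
    if centers is None:
        centers = default_trp_glu_library().centers
    unknown = [s for s in fractions if s not in centers]
    if unknown:
        raise ValueError(f"unknown state labels in fractions: {unknown}")
    probs = np.array(list(fractions.values()), float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if not 0.0 <= persistence <= 1.0:
        raise ValueError("persistence must be in [0, 1]")
    states = list(fractions)
    rng = np.random.default_rng(seed)
    labels = np.empty(n_frames, dtype=object)
    current = states[rng.choice(len(states), p=probs)]
    for t in range(n_frames):
        if t > 0 and rng.random() >= persistence:
            current = states[rng.choice(len(states), p=probs)]
        labels[t] = current
    dihedral_names = sorted(next(iter(centers.values())))
    series = {}
    for name in dihedral_names:
        mu = np.array([math.radians(centers[s][name]) for s in states])
        state_idx = np.array([states.index(l) for l in labels])
        if math.isinf(kappa):
            ang = mu[state_idx]
        else:
            ang = rng.vonmises(mu[state_idx], kappa)
        series[name] = np.degrees(ang)
    truth = {"seed": int(seed), "fractions": dict(fractions), "kappa": kappa,
             "persistence": persistence, "centers": {s: dict(centers[s]) for s in states}}
    return series, labels, truth


# ---------------------------------------------------------------------------
# Cluster fixtures
# ---------------------------------------------------------------------------

def gen_cluster_fixture(seed=0, n_blobs=2, frames_per_blob=8, n_atoms=12,
                        spread=0.1, separation=5.0):
    """Coordinate frames drawn around ``n_blobs`` rigid templates.

    Blob templates are displaced internally (not by rigid motion) so that
    their pairwise RMSD after superposition is ~``separation`` Å while the
    intra-blob jitter is isotropic Gaussian with sigma ``spread``.  Returns
    ``(frames, labels)``.
    """
    if n_blobs < 1:
        raise ValueError("need at least one blob")
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n_atoms, 3)) * 3.0
    frames = []
    labels = []
    for b in range(n_blobs):
        direction = rng.standard_normal((n_atoms, 3))
        direction -= direction.mean(axis=0)
        direction /= np.sqrt((direction**2).sum(axis=1).mean())
        template = base + b * separation * direction
        for _ in range(frames_per_blob):
            frames.append(template + rng.standard_normal((n_atoms, 3)) * spread)
            labels.append(b)
    return np.array(frames), np.array(labels)


def write_truth(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, default=float)
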