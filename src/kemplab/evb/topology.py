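"""EVB system definition: per-state force-field terms, coupling, restraints.

Units: kcal/mol, Å, amu, elementary charge.  A system is a droplet (or
gas-phase cluster) of a reacting fragment plus flexible 3-site waters,
bounded by a harmonic radial wall — a deliberately simplified stand-in for
surface-constrained droplet boundary models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = ["EVBStateParams", "EVBCoupling", "EVBSystem"]


@dataclass
class EVBStateParams:
    """Force-field terms for one diabatic (valence bond) state.

    The reacting X–H bond is a Morse function ``D*(1-exp(-beta*(r-r0)))**2``
    (zero at r0, dissociating to D); spectator internal coordinates are
    harmonic bonds ``0.5*k*(r-r0)**2`` and angles ``0.5*k*(theta-theta0)**2``.
    ``charges`` and per-atom LJ ``(sigma, epsilon)`` belong to this state's
    bonding pattern.
    """

    morse: tuple  # (i, j, D, beta, r0)
    charges: np.ndarray  # (N,) e
    lj_sigma: np.ndarray  # (N,) Å
    lj_eps: np.ndarray  # (N,) kcal/mol
    bonds: list = field(default_factory=list)  # (i, j, k, r0)
    angles: list = field(default_factory=list)  # (i, j, k, k_theta, theta0_deg)

    def __post_init__(self):
        i, j, D, beta, r0 = self.morse
        if D <= 0 or beta <= 0 or r0 <= 0:
            raise ValueError("Morse parameters D, beta, r0 must be positive")
        self.charges = np.asarray(self.charges, float)
        self.lj_sigma = np.asarray(self.lj_sigma, float)
        self.lj_eps = np.asarray(self.lj_eps, float)
        total = float(self.charges.sum())
        if abs(total - round(total)) > 1e-9:
            raise ValueError(f"state total charge {total} is not an integer")


@dataclass
class EVBCoupling:
    """Off-diagonal element H12 and the gas-phase shift alpha (kcal/mol).

    ``H12(r)`` is either constant (``mu == 0``) or the exponential form
    ``A * exp(-mu * r)`` in the donor–acceptor distance r.
    """

    H12: float = 0.0  # constant value, or prefactor A of the exponential form
    mu: float = 0.0  # Å^-1; 0 selects the constant form
    alpha: float = 0.0

    def value(self, r: float | None = None) -> float:
        if self.mu == 0.0:
            out = self.H12
        else:
            if r is None:
                raise ValueError("exponential H12 needs a distance")
            out = self.H12 * math.exp(-self.mu * r)
        if out < 0:
            raise ValueError("H12 must be >= 0 where evaluated")
        return out


@dataclass
class EVBSystem:
    """A reacting fragment in a water droplet with a two-state Hamiltonian.

    ``reacting_atoms`` are exempt from the nonbonded cutoff (they see every
    atom), mirroring the usual EVB practice of applying essentially no
    cutoff to the reacting fragment.  ``constraints`` are SHAKE distance
    constraints (water internal geometry); the transferring hydrogen is
    never constrained.
    """

    names: list
    masses: np.ndarray  # (N,) amu
    coords: np.ndarray  # (N, 3) Å
    states: tuple  # (EVBStateParams, EVBStateParams)
    coupling: EVBCoupling
    droplet_radius: float = 12.0
    wall_k: float = 10.0  # kcal/mol/Å^2, harmonic wall beyond the radius
    cutoff: float = 10.0
    reacting_atoms: tuple = ()
    donor: int = 0  # heavy-atom index of the H donor
    hydrogen: int = 1  # the transferring H
    acceptor: int = 2  # heavy-atom index of the acceptor
    exclusions: set = field(default_factory=set)  # frozenset pairs, both states
    constraints: list = field(default_factory=list)  # (i, j, distance)
    position_restraints: list = field(default_factory=list)  # (i, k, (x,y,z))
    distance_restraints: list = field(default_factory=list)  # (i, j, k, r0)
    wall_center: np.ndarray | None = None

    def __post_init__(self):
        self.masses = np.asarray(self.masses, float)
        self.coords = np.asarray(self.coords, float)
        n = len(self.masses)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (N, 3)")
        if len(self.states) != 2:
            raise ValueError("exactly two diabatic states required")
        for s in self.states:
            if len(s.charges) != n:
                raise ValueError("state charge array length != atom count")
        if self.cutoff > 2 * self.droplet_radius:
            raise ValueError("cutoff exceeds droplet diameter")
        if self.wall_center is None:
            self.wall_center = np.zeros(3)
        for i, j, d in self.constraints:
            if self.hydrogen in (i, j):
                raise ValueError("the transferring hydrogen must stay unconstrained")
        self._build_pairlists()

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    # -- nonbonded bookkeeping ---------------------------------------------
    def _build_pairlists(self):
        n = self.n_atoms
        common_excl = {frozenset(p) for p in self.exclusions}
        # water internal pairs and constrained pairs never interact nonbonded
        for i, j, d in self.constraints:
            common_excl.add(frozenset((i, j)))
        self._pairs_by_state = []
        iu, ju = np.triu_indices(n, k=1)
        base = list(zip(iu.tolist(), ju.tolist()))
        react = set(self.reacting_atoms)
        for s in self.states:
            excl = set(common_excl)
            mi, mj = s.morse[0], s.morse[1]
            excl.add(frozenset((mi, mj)))
            for i, j, *_ in s.bonds:
                excl.add(frozenset((i, j)))
            for i, j, k, *_ in s.angles:
                excl.add(frozenset((i, k)))  # 1-3 exclusion through the angle
                excl.add(frozenset((i, j)))
                excl.add(frozenset((j, k)))
            keep = [(i, j) for (i, j) in base if frozenset((i, j)) not in excl]
            pairs = np.array(keep, dtype=int).reshape(-1, 2)
            exempt = np.array(
                [i in react or j in react for i, j in keep], dtype=bool
            )
            # cache per-pair nonbonded parameters and bonded-term arrays
            qq = s.charges[pairs[:, 0]] * s.charges[pairs[:, 1]]
            sig = 0.5 * (s.lj_sigma[pairs[:, 0]] + s.lj_sigma[pairs[:, 1]])
            eps = np.sqrt(s.lj_eps[pairs[:, 0]] * s.lj_eps[pairs[:, 1]])
            ljA = 4.0 * eps * sig**12
            ljB = 4.0 * eps * sig**6
            bonds = np.array([list(b) for b in s.bonds], float).reshape(-1, 4)
            angles = np.array([list(a) for a in s.angles], float).reshape(-1, 5)
            self._pairs_by_state.append({
                "pairs": pairs, "exempt": exempt, "qq": qq,
                "ljA": ljA, "ljB": ljB,
                "bond_idx": bonds[:, :2].astype(int), "bond_k": bonds[:, 2],
                "bond_r0": bonds[:, 3],
                "angle_idx": angles[:, :3].astype(int), "angle_k": angles[:, 3],
                "angle_theta0": np.radians(angles[:, 4]),
            })

    def pairlist(self, state: int):
        cache = self._pairs_by_state[state]
        return cache["pairs"], cache["exempt"]

    def state_cache(self, state: int) -> dict:
        return self._pairs_by_state[state]

    def with_coords(self, coords: np.ndarray) -> "EVBSystem":
        new = replace(self, coords=np.asarray(coords, float))
        return new

    # -- serialisation ------------------------------------------------------
    def to_yaml(self, path) -> None:
        def state_dict(s: EVBStateParams) -> dict:
            return {
                "morse": list(s.morse),
                "charges": s.charges.tolist(),
                "lj_sigma": s.lj_sigma.tolist(),
                "lj_eps": s.lj_eps.tolist(),
                "bonds": [list(b) for b in s.bonds],
                "angles": [list(a) for a in s.angles],
            }

        doc = {
            "names": list(self.names),
            "masses": self.masses.tolist(),
            "states": [state_dict(s) for s in self.states],
            "coupling": {"H12": self.coupling.H12, "mu": self.coupling.mu,
                         "alpha": self.coupling.alpha},
            "droplet_radius": self.droplet_radius,
            "wall_k": self.wall_k,
            "cutoff": self.cutoff,
            "reacting_atoms": list(self.reacting_atoms),
            "donor": self.donor,
            "hydrogen": self.hydrogen,
            "acceptor": self.acceptor,
            "exclusions": [sorted(p) for p in self.exclusions],
            "constraints": [list(c) for c in self.constraints],
            "position_restraints": [[i, k, list(map(float, x))]
                                    for i, k, x in self.position_restraints],
            "distance_restraints": [list(d) for d in self.distance_restraints],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, topology_path, coords: np.ndarray) -> "EVBSystem":
        with open(topology_path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        states = tuple(
            EVBStateParams(
                morse=tuple(sd["morse"]),
                charges=np.array(sd["charges"], float),
                lj_sigma=np.array(sd["lj_sigma"], float),
                lj_eps=np.array(sd["lj_eps"], float),
                bonds=[tuple(b) for b in sd.get("bonds", [])],
                angles=[tuple(a) for a in sd.get("angles", [])],
            )
            for sd in doc["states"]
        )
        c = doc.get("coupling", {})
        return cls(
            names=doc["names"],
            masses=np.array(doc["masses"], float),
            coords=np.asarray(coords, float),
            states=states,
            coupling=EVBCoupling(H12=float(c.get("H12", 0.0)),
                                 mu=float(c.get("mu", 0.0)),
                                 alpha=float(c.get("alpha", 0.0))),
            droplet_radius=float(doc.get("droplet_radius", 12.0)),
            wall_k=float(doc.get("wall_k", 10.0)),
            cutoff=float(doc.get("cutoff", 10.0)),
            reacting_atoms=tuple(doc.get("reacting_atoms", ())),
            donor=int(doc.get("donor", 0)),
            hydrogen=int(doc.get("hydrogen", 1)),
            acceptor=int(doc.get("acceptor", 2)),
            exclusions={frozenset(p) for p in doc.get("exclusions", [])},
            constraints=[tuple(c) for c in doc.get("constraints", [])],
            position_restraints=[(int(i), float(k), np.array(x, float))
                                 for i, k, x in doc.get("position_restraints", [])],
            distance_restraints=[tuple(d) for d in doc.get("distance_restraints", [])],
        )
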