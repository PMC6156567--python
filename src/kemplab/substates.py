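"""Active-site conformational substates, HREX ladders and structural metrics.

A designed Kemp eliminase active site can populate several discrete rotamer
arrangements of its catalytic residues (labelled A, B, C, ... plus a
"disordered in-between" D state).  This module classifies trajectory frames
into those substates from side-chain χ dihedral time series, builds the
geometric scaling ladders used by Hamiltonian replica exchange (HREX)
solute tempering, clusters structures by pairwise RMSD with the greedy
neighbour (Daura) algorithm, and computes active-site geometry metrics
(ring-plane alignment, donor–H–acceptor angle, distances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from statsmodels.stats.proportion import multinomial_proportions_confint

__all__ = [
    "DihedralSpec",
    "SubstateLibrary",
    "SubstateAssignment",
    "HREXLadder",
    "compute_dihedral",
    "classify_substates",
    "hrex_ladder",
    "select_hot_region",
    "daura_cluster",
    "geometry_metrics",
    "backbone_rmsd",
    "kabsch_rmsd",
    "default_trp_glu_library",
]


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DihedralSpec:
    """A named four-atom dihedral, e.g. Trp50 χ1 = N:CA:CB:CG.

    ``atoms`` holds four (residue_id, atom_name) pairs or plain integer
    indices into a coordinate array.
    """

    name: str
    atoms: tuple

    def __post_init__(self):
        if len(self.atoms) != 4 or len(set(self.atoms)) != 4:
            raise ValueError("a dihedral needs four distinct atoms")


def compute_dihedral(coords: np.ndarray, indices) -> np.ndarray:
    """Signed IUPAC dihedral angle(s) in degrees, range (-180, 180].

    Parameters
    ----------
    coords : (n_frames, n_atoms, 3) or (n_atoms, 3) array, Å.
    indices : four integer atom indices (i, j, k, l).

    The sign follows the right-handed convention: looking down the j->k
    bond, a clockwise rotation of l relative to i is positive.
    """
    xyz = np.asarray(coords, dtype=float)
    single = xyz.ndim == 2
    if single:
        xyz = xyz[None]
    i, j, k, l = indices
    b1 = xyz[:, j] - xyz[:, i]
    b2 = xyz[:, k] - xyz[:, j]
    b3 = xyz[:, l] - xyz[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    # fold -180 to +180 so the range is (-180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return float(ang[0]) if single else ang


def dihedral_series(traj: np.ndarray, specs: list[DihedralSpec],
                    index_of=None) -> dict[str, np.ndarray]:
    """Evaluate several dihedrals over a trajectory.

    ``index_of`` maps a (residue, atom-name) identifier to an integer index;
    identity for integer atom specs.
    """
    out = {}
    for spec in specs:
        try:
            idx = [a if isinstance(a, (int, np.integer)) else index_of(a)
                   for a in spec.atoms]
        except (KeyError, TypeError) as exc:
            raise ValueError(f"dihedral {spec.name}: missing atom {exc}") from exc
        out[spec.name] = compute_dihedral(traj, idx)
    return out


# ---------------------------------------------------------------------------
# Substate classification
# ---------------------------------------------------------------------------

def circular_distance(a, b):
    """Smallest absolute angular separation in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


@dataclass
class SubstateLibrary:
    """Substate definitions: per-state centers (deg) for each dihedral.

    ``centers`` maps state label -> {dihedral name -> center degrees};
    ``tolerance`` is the circular half-width accepted around each center
    (per dihedral, deg).  Frames outside every state's tolerance get
    ``unassigned_label`` (the "disordered in-between" state).
    """

    centers: dict[str, dict[str, float]]
    tolerance: float = 40.0
    unassigned_label: str = "D"

    def __post_init__(self):
        if not self.centers:
            raise ValueError("library needs at least one state")
        names = None
        for label, c in self.centers.items():
            if names is None:
                names = set(c)
            elif set(c) != names:
                raise ValueError(f"state {label} uses different dihedrals")
        self.dihedral_names = sorted(names)
        # distinguishability: every pair of states must be separated by more
        # than the summed tolerances on at least one dihedral
        labels = sorted(self.centers)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                sep = max(
                    circular_distance(self.centers[a][n], self.centers[b][n])
                    for n in self.dihedral_names
                )
                if sep <= self.tolerance:
                    raise ValueError(
                        f"states {a} and {b} are indistinguishable: max "
                        f"center separation {sep:.1f} deg <= tolerance"
                    )
                if sep <= 2 * self.tolerance:
                    warnings.warn(
                        f"states {a} and {b} overlap: max center separation "
                        f"{sep:.1f} deg <= 2*tolerance; ambiguous frames "
                        "tie-break to the smaller label", stacklevel=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SubstateLibrary":
        return cls(centers={k: dict(v) for k, v in d["centers"].items()},
                   tolerance=float(d.get("tolerance", 40.0)),
                   unassigned_label=d.get("unassigned_label", "D"))

    def to_dict(self) -> dict:
        return {"centers": self.centers, "tolerance": self.tolerance,
                "unassigned_label": self.unassigned_label}


def default_trp_glu_library() -> SubstateLibrary:
    """Editable default centers for the Trp/Glu active-site substates.

    The three well-defined configurations: A = designed rotamer, B = A with
    the indole χ2 rotated by ~100°, C = indole flipped so its NH hydrogen
    bonds the catalytic glutamate.  Centers are coarse estimates meant to be
    replaced by values read off a specific system; every assignment records
    the library used.
    """
    return SubstateLibrary(
        centers={
            "A": {"Trp-chi1": -60.0, "Trp-chi2": 100.0},
            "B": {"Trp-chi1": -60.0, "Trp-chi2": -160.0},
            "C": {"Trp-chi1": 180.0, "Trp-chi2": 80.0},
        },
        tolerance=40.0,
        unassigned_label="D",
    )


@dataclass
class SubstateAssignment:
    """Per-frame labels plus populations with multinomial 95% CIs."""

    labels: np.ndarray  # per-frame state label (str)
    states: list[str]  # ordered labels incl. unassigned
    populations: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    transitions: dict[tuple[str, str], int]
    library: SubstateLibrary

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def to_dict(self) -> dict:
        return {
            "n_frames": self.n_frames,
            "populations": self.populations,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "transitions": {f"{a}->{b}": n for (a, b), n in self.transitions.items()},
            "library": self.library.to_dict(),
        }


def classify_substates(series: dict[str, np.ndarray],
                       library: SubstateLibrary) -> SubstateAssignment:
    """Assign each frame to the nearest substate center.

    The distance between a frame and a state is the *maximum* circular
    distance over the library's dihedrals (worst-coordinate match); a frame
    is assigned to the closest state if that distance is within the
    tolerance, else to the unassigned/disordered label.  Exact ties break
    to the lexicographically smaller state label.
    """
    missing = [n for n in library.dihedral_names if n not in series]
    if missing:
        raise ValueError(f"series missing dihedrals: {missing}")
    arrays = {n: np.asarray(series[n], float) for n in library.dihedral_names}
    n_frames = len(next(iter(arrays.values())))
    if n_frames == 0:
        raise ValueError("empty dihedral series")
    for n, a in arrays.items():
        if len(a) != n_frames:
            raise ValueError(f"dihedral {n} has length {len(a)} != {n_frames}")

    state_labels = sorted(library.centers)  # lexicographic tie-break order
    dist = np.empty((n_frames, len(state_labels)))
    for s, label in enumerate(state_labels):
        per_dih = [circular_distance(arrays[n], library.centers[label][n])
                   for n in library.dihedral_names]
        dist[:, s] = np.max(per_dih, axis=0)
    best = np.argmin(dist, axis=1)  # argmin takes the first (smallest label) on ties
    best_dist = dist[np.arange(n_frames), best]
    labels = np.where(best_dist <= library.tolerance,
                      np.array(state_labels)[best], library.unassigned_label)

    states = state_labels + [library.unassigned_label]
    counts = np.array([(labels == s).sum() for s in states])
    pops = counts / n_frames
    ci = multinomial_proportions_confint(np.maximum(counts, 0), alpha=0.05)
    transitions = {}
    for a, b in zip(labels[:-1], labels[1:]):
        transitions[(a, b)] = transitions.get((a, b), 0) + 1
    return SubstateAssignment(
        labels=labels,
        states=states,
        populations={s: float(p) for s, p in zip(states, pops)},
        ci95={s: (float(lo), float(hi)) for s, (lo, hi) in zip(states, ci)},
        transitions=transitions,
        library=library,
    )


# ---------------------------------------------------------------------------
# HREX scaling ladder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HREXLadder:
    """Geometric Hamiltonian-scaling ladder 1.0 -> lambda_min."""

    n_replicas: int
    lambda_min: float
    factors: tuple

    def display(self, decimals: int = 3) -> list[float]:
        return [round(f, decimals) for f in self.factors]


def hrex_ladder(n_replicas: int, lambda_min: float) -> HREXLadder:
    """Geometric ladder factor[i] = lambda_min**(i/(n-1)).

    Six replicas with lambda_min = 0.667 give the canonical solute-tempering
    sequence 1.000, 0.922, 0.850, 0.784, 0.723, 0.667.
    """
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if not 0.0 < lambda_min < 1.0:
        raise ValueError("lambda_min must be in (0, 1)")
    i = np.arange(n_replicas)
    factors = lambda_min ** (i / (n_replicas - 1))
    return HREXLadder(n_replicas=n_replicas, lambda_min=lambda_min,
                      factors=tuple(float(f) for f in factors))


# ---------------------------------------------------------------------------
# Structure-based operations
# ---------------------------------------------------------------------------

def select_hot_region(structure, center_residue: int, radius: float) -> list[int]:
    """Residues with any atom within ``radius`` Å of any center-residue atom.

    ``structure`` is a biotite ``AtomArray`` (see :mod:`kemplab.io`).  The
    center residue is always included.  Returns sorted residue ids.
    """
    res_ids = np.asarray(structure.res_id)
    coords = np.asarray(structure.coord)
    center_mask = res_ids == center_residue
    if not center_mask.any():
        raise ValueError(f"center residue {center_residue} not in structure")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    hot = {int(center_residue)}
    if radius > 0:
        tree = cKDTree(coords[center_mask])
        d, _ = tree.query(coords, k=1)
        hot.update(int(r) for r in res_ids[d <= radius])
    return sorted(hot)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations after optimal superposition.

    Uses the Kabsch algorithm via scipy's ``Rotation.align_vectors`` on the
    centered coordinates.
    """
    from scipy.spatial.transform import Rotation

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("atom-count mismatch between conformations")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(len(a)))


def backbone_rmsd(traj: np.ndarray, reference: np.ndarray,
                  selection=None) -> np.ndarray:
    """Optimal-superposition RMSD of every frame against a reference.

    ``selection`` is an optional integer index array (e.g. backbone atoms).
    """
    traj = np.asarray(traj, float)
    reference = np.asarray(reference, float)
    if selection is not None:
        sel = np.asarray(selection, int)
        traj = traj[:, sel]
        reference = reference[sel]
    if traj.shape[1:] != reference.shape:
        raise ValueError("atom-count mismatch between trajectory and reference")
    return np.array([kabsch_rmsd(frame, reference) for frame in traj])


def daura_cluster(frames: np.ndarray, cutoff: float,
                  selection=None) -> list[dict]:
    """Greedy RMSD-neighbour clustering (Daura et al. / gromos scheme).

    Repeatedly: compute pairwise superposed RMSDs among unassigned frames,
    pick the frame with the most neighbours within ``cutoff`` (ties break to
    the lowest frame index) as centroid, remove it and its neighbours as one
    cluster.  Returns clusters ordered as found (sizes non-increasing), each
    a dict with ``centroid`` (frame index) and ``members`` (sorted indices).
    """
    frames = np.asarray(frames, float)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("need a non-empty (n_frames, n_atoms, 3) array")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if selection is not None:
        sel = np.asarray(selection, int)
        if sel.size == 0:
            raise ValueError("empty atom selection")
        frames = frames[:, sel]
    n = len(frames)
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = kabsch_rmsd(frames[i], frames[j])
    neighbor = rmsd <= cutoff  # includes self
    remaining = np.ones(n, dtype=bool)
    clusters = []
    while remaining.any():
        counts = (neighbor & remaining).sum(axis=1)
        counts[~remaining] = -1
        centroid = int(np.argmax(counts))  # argmax returns lowest index on ties
        members = np.where(neighbor[centroid] & remaining)[0]
        clusters.append({"centroid": centroid,
                         "members": [int(m) for m in members]})
        remaining[members] = False
    return clusters


def _plane_normal(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, float)
    if len(pts) < 3:
        raise ValueError("need at least 3 atoms to fit a plane")
    centered = pts - pts.mean(axis=0)
    # smallest right singular vector = best-fit plane normal
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def geometry_metrics(coords: np.ndarray, ring_a=None, ring_b=None,
                     donor=None, hydrogen=None, acceptor=None,
                     distances: dict | None = None) -> dict:
    """Active-site geometry metrics for one frame.

    * ``ring_plane_angle``: angle between the SVD best-fit plane normals of
      the two ring atom index sets, folded to [0, 90] degrees (0 = parallel
      π-stacking alignment).
    * ``donor_H_acceptor_angle``: angle at the transferring hydrogen,
      degrees (180 = collinear, ideal for proton abstraction).
    * ``distances``: named atom-pair Euclidean distances, Å.
    """
    xyz = np.asarray(coords, float)
    out = {}
    if ring_a is not None and ring_b is not None:
        na = _plane_normal(xyz[np.asarray(ring_a, int)])
        nb = _plane_normal(xyz[np.asarray(ring_b, int)])
        cosang = np.clip(abs(float(na @ nb)), 0.0, 1.0)
        out["ring_plane_angle"] = float(np.degrees(np.arccos(cosang)))
    if donor is not None and hydrogen is not None and acceptor is not None:
        v1 = xyz[donor] - xyz[hydrogen]
        v2 = xyz[acceptor] - xyz[hydrogen]
        c = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        out["donor_H_acceptor_angle"] = float(np.degrees(np.arccos(np.clip(c, -1, 1))))
    if distances:
        out["distances"] = {
            name: float(np.linalg.norm(xyz[i] - xyz[j]))
            for name, (i, j) in distances.items()
        }
    return out


# ---------------------------------------------------------------------------
# Replica-exchange bookkeeping (analysis of logs, not an MD driver)
# ---------------------------------------------------------------------------

def exchange_statistics(attempts: list[tuple[int, int, bool]]) -> dict:
    """Acceptance statistics from a replica-exchange attempt log.

    ``attempts`` holds (replica_i, replica_j, accepted) records, e.g. one
    per 4 ps attempt.  Returns per-pair and overall acceptance ratios.
    """
    per_pair: dict[tuple[int, int], list[int]] = {}
    for i, j, acc in attempts:
        per_pair.setdefault((min(i, j), max(i, j)), []).append(int(bool(acc)))
    overall = [a for accs in per_pair.values() for a in accs]
    return {
        "overall_acceptance": float(np.mean(overall)) if overall else float("nan"),
        "per_pair": {f"{i}-{j}": float(np.mean(a)) for (i, j), a in per_pair.items()},
        "n_attempts": len(overall),
    }
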