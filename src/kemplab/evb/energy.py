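"""Diabatic energies, analytic forces, and the two-state ground surface.

Each diabatic state is a plain classical force field: a Morse term for the
reacting X–H bond, harmonic spectator bonds and angles, Lennard-Jones and
Coulomb nonbonded terms (hard cutoff, with reacting atoms exempt), plus the
shared droplet wall and restraint terms.  The second state additionally
carries the gas-phase shift alpha.  All forces are analytic and validated
against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from kemplab.constants import COULOMB_KCAL

__all__ = ["diabatic_energies", "ground_state", "state_energy_forces",
           "shared_energy_forces"]

_MIN_DIST = 0.1  # Å; closer pairs indicate a broken configuration


def _pair_vectors(coords, pairs):
    rij = coords[pairs[:, 1]] - coords[pairs[:, 0]]
    r = np.linalg.norm(rij, axis=1)
    return rij, r


def _accumulate(forces, pairs, fvec):
    # fvec = dE/dr * unit(i->j): force on j is -fvec, on i +fvec.
    # bincount is much faster than np.add.at for long pair lists
    n = len(forces)
    for d in range(3):
        forces[:, d] += np.bincount(pairs[:, 0], weights=fvec[:, d], minlength=n)
        forces[:, d] -= np.bincount(pairs[:, 1], weights=fvec[:, d], minlength=n)


def morse_energy_force(coords, i, j, D, beta, r0):
    rij = coords[j] - coords[i]
    r = float(np.linalg.norm(rij))
    ex = np.exp(-beta * (r - r0))
    e = D * (1.0 - ex) ** 2
    # dE/dr = 2 D beta ex (1 - ex)
    dedr = 2.0 * D * beta * ex * (1.0 - ex)
    fvec = dedr * rij / r  # force on j is -dE/drj = -dedr * unit; see below
    f = np.zeros_like(coords)
    f[i] += fvec
    f[j] -= fvec
    return e, f


def _bond_terms(coords, idx, k, r0, forces):
    if len(k) == 0:
        return 0.0
    rij = coords[idx[:, 1]] - coords[idx[:, 0]]
    r = np.linalg.norm(rij, axis=1)
    e = 0.5 * float((k * (r - r0) ** 2).sum())
    fvec = ((k * (r - r0)) / r)[:, None] * rij
    np.add.at(forces, idx[:, 0], fvec)
    np.add.at(forces, idx[:, 1], -fvec)
    return e


def _angle_terms(coords, idx, k_theta, theta0, forces):
    if len(k_theta) == 0:
        return 0.0
    rji = coords[idx[:, 0]] - coords[idx[:, 1]]
    rjk = coords[idx[:, 2]] - coords[idx[:, 1]]
    nji = np.linalg.norm(rji, axis=1)
    njk = np.linalg.norm(rjk, axis=1)
    cos_t = np.clip(np.einsum("ij,ij->i", rji, rjk) / (nji * njk),
                    -1.0 + 1e-12, 1.0 - 1e-12)
    theta = np.arccos(cos_t)
    e = 0.5 * float((k_theta * (theta - theta0) ** 2).sum())
    dedt = k_theta * (theta - theta0)
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    u = rji / nji[:, None]
    v = rjk / njk[:, None]
    # dtheta/dri and dtheta/drk (standard angle derivatives)
    di = (cos_t[:, None] * u - v) / (nji * sin_t)[:, None]
    dk = (cos_t[:, None] * v - u) / (njk * sin_t)[:, None]
    np.add.at(forces, idx[:, 0], -dedt[:, None] * di)
    np.add.at(forces, idx[:, 2], -dedt[:, None] * dk)
    np.add.at(forces, idx[:, 1], dedt[:, None] * (di + dk))
    return e


def _nonbonded(coords, pairs, exempt, qq, ljA, ljB, cutoff):
    """LJ + Coulomb over a pair list with a hard cutoff (exempt pairs always
    interact).  Returns energy and the per-pair force vectors."""
    rij, r = _pair_vectors(coords, pairs)
    if len(r) and r.min() < _MIN_DIST:
        k = int(np.argmin(r))
        raise ValueError(
            f"overlapping atoms {pairs[k, 0]}-{pairs[k, 1]} at r={r.min():.3f} Å"
        )
    active = exempt | (r < cutoff)
    inv_r = np.where(active, 1.0 / r, 0.0)
    inv6 = inv_r**6
    e_lj = ljA * inv6 * inv6 - ljB * inv6
    e_c = qq * inv_r
    # dE/dr: LJ: (-12 A r^-13 + 6 B r^-7); Coulomb: -qq r^-2
    dedr = (-12.0 * ljA * inv6 * inv6 + 6.0 * ljB * inv6) * inv_r - e_c * inv_r
    fvec = (dedr * inv_r)[:, None] * rij  # along rij, see _accumulate signs
    return float(e_lj.sum() + e_c.sum()), fvec


def shared_energy_forces(system, coords):
    """Wall and restraint terms, identical in both diabatic states."""
    forces = np.zeros_like(coords)
    e = 0.0
    # harmonic radial wall beyond the droplet radius
    d = coords - system.wall_center
    r = np.linalg.norm(d, axis=1)
    out = r > system.droplet_radius
    if out.any():
        dr = r[out] - system.droplet_radius
        e += 0.5 * system.wall_k * float((dr**2).sum())
        forces[out] -= (system.wall_k * dr / r[out])[:, None] * d[out]
    for i, k, ref in system.position_restraints:
        dv = coords[i] - ref
        e += 0.5 * k * float(dv @ dv)
        forces[i] -= k * dv
    for i, j, k, r0 in system.distance_restraints:
        rij = coords[j] - coords[i]
        rr = float(np.linalg.norm(rij))
        e += 0.5 * k * (rr - r0) ** 2
        fvec = k * (rr - r0) * rij / rr
        forces[i] += fvec
        forces[j] -= fvec
    return e, forces


def state_energy_forces(system, coords, state_index):
    """Energy and analytic forces of one diabatic state (without alpha and
    without the shared wall/restraint terms)."""
    s = system.states[state_index]
    cache = system.state_cache(state_index)
    forces = np.zeros_like(coords)
    i, j, D, beta, r0 = s.morse
    e, f_m = morse_energy_force(coords, i, j, D, beta, r0)
    forces += f_m
    e += _bond_terms(coords, cache["bond_idx"], cache["bond_k"],
                     cache["bond_r0"], forces)
    e += _angle_terms(coords, cache["angle_idx"], cache["angle_k"],
                      cache["angle_theta0"], forces)
    pairs = cache["pairs"]
    if len(pairs):
        e_nb, fvec = _nonbonded(coords, pairs, cache["exempt"],
                                COULOMB_KCAL * cache["qq"], cache["ljA"],
                                cache["ljB"], system.cutoff)
        e += e_nb
        _accumulate(forces, pairs, fvec)
    return e, forces


def diabatic_energies(system, coords=None, include_shared: bool = True):
    """Diabatic energies (eps1, eps2') with analytic forces for both states.

    eps2' includes the gas-phase shift alpha.  ``include_shared`` adds the
    wall/restraint terms (identical in both states, so they cancel in the
    energy gap but matter for dynamics).
    """
    if coords is None:
        coords = system.coords
    coords = np.asarray(coords, float)
    e1, f1 = state_energy_forces(system, coords, 0)
    e2, f2 = state_energy_forces(system, coords, 1)
    if include_shared:
        es, fs = shared_energy_forces(system, coords)
        e1, e2 = e1 + es, e2 + es
        f1, f2 = f1 + fs, f2 + fs
    return e1, e2 + system.coupling.alpha, f1, f2


def ground_state(eps1, eps2, H12):
    """Lowest eigenvalue of the 2x2 EVB matrix and mixing coefficients.

    Eg = (eps1+eps2)/2 - sqrt((eps1-eps2)^2 + 4 H12^2)/2.  Returns
    (Eg, (c1, c2)) for scalars; for arrays the coefficient computation is
    vectorised and Eg has the input shape.
    """
    eps1 = np.asarray(eps1, float)
    eps2 = np.asarray(eps2, float)
    if np.any(np.asarray(H12) < 0):
        raise ValueError("H12 must be >= 0")
    gap = eps1 - eps2
    root = np.sqrt(gap * gap + 4.0 * H12 * H12)
    eg = 0.5 * (eps1 + eps2) - 0.5 * root
    # eigenvector (normalised): (H12, Eg - eps1) up to sign, handle H12=0
    c2 = eg - eps1
    c1 = np.where(np.abs(c2) + np.abs(H12) > 0, np.broadcast_to(H12, eps1.shape), 1.0)
    norm = np.sqrt(c1 * c1 + c2 * c2)
    ok = norm > 0
    c1 = np.where(ok, c1 / np.where(ok, norm, 1.0), 1.0)
    c2 = np.where(ok, c2 / np.where(ok, norm, 1.0), 0.0)
    if eg.ndim == 0:
        return float(eg), (float(abs(c1)), float(abs(c2)))
    return eg, (np.abs(c1), np.abs(c2))
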