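"""Independent brute-force oracles used only by the tests.

Everything here is deliberately naive (pure-Python double loops, grid
searches) and shares no code path with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

from dipolescan.structio import AtomRecord, QMRegion, ReactionStatePair, Structure

K = 332.0637  # kcal·Å·mol⁻¹·e⁻²


def naive_coulomb(atoms_a, atoms_b) -> float:
    """Plain double-loop Coulomb sum over (coords, charges) pairs."""
    ca, qa = atoms_a
    cb, qb = atoms_b
    total = 0.0
    for i in range(len(qa)):
        for j in range(len(qb)):
            r = math.dist(ca[i], cb[j])
            total += K * qa[i] * qb[j] / r
    return total


def naive_deletion_scan(pair: ReactionStatePair, eligible) -> dict:
    """Per-residue ΔΔE = −(V_TS − V_R) by unvectorized loops."""
    r_coords = [(a.x, a.y, a.z) for a in pair.reactant.atoms]
    t_coords = [(a.x, a.y, a.z) for a in pair.transition_state.atoms]
    out = {}
    for key in eligible:
        idx = pair.reactant.residue_atom_indices(key)
        v_r = v_ts = 0.0
        for i in idx:
            qi_r = pair.reactant.atoms[i].charge
            qi_t = pair.transition_state.atoms[i].charge
            for pos, j in enumerate(pair.qm.atom_indices):
                v_r += K * qi_r * pair.qm.charges_R[pos] / math.dist(r_coords[i], r_coords[j])
                v_ts += K * qi_t * pair.qm.charges_TS[pos] / math.dist(t_coords[i], t_coords[j])
        out[key] = -(v_ts - v_r)
    return out


def random_pair(rng: np.random.Generator, n_residues: int = 20,
                atoms_per_residue: int = 4, n_qm: int = 6) -> ReactionStatePair:
    """A random but well-separated R/TS pair for oracle comparisons."""
    atoms = []
    serial = 1
    # QM atoms clustered near the origin
    qm_pos = rng.uniform(-2.0, 2.0, size=(n_qm, 3))
    for i in range(n_qm):
        atoms.append(AtomRecord(serial, f"Q{i}", "QMR", 900, "A",
                                *np.round(qm_pos[i], 3), round(rng.uniform(-0.5, 0.5), 4)))
        serial += 1
    for r in range(n_residues):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = direction * rng.uniform(8.0, 20.0)
        for a in range(atoms_per_residue):
            pos = center + rng.uniform(-1.0, 1.0, size=3)
            atoms.append(AtomRecord(serial, f"X{a}", "RND", 10 + r, "A",
                                    *np.round(pos, 3), round(rng.uniform(-1.0, 1.0), 4)))
            serial += 1
    charges_r = np.round(rng.uniform(-0.8, 0.8, size=n_qm), 4)
    charges_ts = charges_r.copy()
    lam = rng.uniform(0.0, 1.0)
    charges_ts[0] -= lam
    charges_ts[1] += lam
    structure = Structure(atoms)
    qm = QMRegion(list(range(n_qm)), charges_r, charges_ts,
                  {0: "donor_site", 1: "acceptor_site"})
    return ReactionStatePair(structure, Structure(list(atoms)), qm)


def _euler(a: float, b: float, c: float) -> np.ndarray:
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cc, sc = math.cos(c), math.sin(c)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def brute_force_rmsd(mobile: np.ndarray, target: np.ndarray,
                     coarse: int = 24, refine_rounds: int = 40) -> float:
    """Superposition RMSD by Euler-angle grid search plus local refinement.

    No SVD, no scipy: centers both sets, scans a coarse rotation grid, then
    shrinks a local search window around the best angles.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def rmsd_at(angles):
        diff = P0 @ _euler(*angles).T - Q0
        return math.sqrt((diff * diff).sum() / len(P0))

    best_angles, best = None, math.inf
    grid = np.linspace(0, 2 * math.pi, coarse, endpoint=False)
    bgrid = np.linspace(0, math.pi, coarse // 2)
    for a in grid:
        for b in bgrid:
            for c in grid:
                v = rmsd_at((a, b, c))
                if v < best:
                    best, best_angles = v, (a, b, c)

    step = 2 * math.pi / coarse
    angles = list(best_angles)
    for _ in range(refine_rounds):
        improved = True
        while improved:
            improved = False
            for k in range(3):
                for delta in (-step, step):
                    trial = list(angles)
                    trial[k] += delta
                    v = rmsd_at(trial)
                    if v < best:
                        best, angles, improved = v, trial, True
        step *= 0.5
        if step < 1e-10:
            break
    return best
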