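"""Point-charge surrogate of the electrostatic-embedding deletion experiment.

The underlying idea: in a QM/MM picture, deleting an environment residue m
from the point-charge embedding changes the activation barrier by
ΔΔE_m = ΔE_m − ΔE_wt.  Residues with negative ΔΔE are anticatalytic (they
stabilize the reactant charge distribution more than the transition-state
one) and neutralizing their charge is predicted to be rate-enhancing.

Here the QM core is replaced by a classical point-charge distribution that
differs between the reactant (R) and transition state (TS), so the only term
a deletion changes is the residue↔QM Coulomb energy:

    ΔΔE_m = −(V_TS(m) − V_R(m)),   V_X(m) = k Σ_{i∈m, j∈QM} q_i q_j / r_ij

with k = 332.0637 kcal·Å·mol⁻¹·e⁻².  The wild-type barrier ΔE_wt is an
input (default 10.6 kcal/mol); the surrogate never computes QM energies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structio import AtomRecord, ReactionStatePair, ResidueKey

__all__ = [
    "COULOMB_K",
    "DEFAULT_WT_BARRIER",
    "InteractionEnergy",
    "DeletionResult",
    "coulomb",
    "state_interaction",
    "deletion_scan",
    "classify_effect",
    "write_scan_tsv",
    "read_scan_tsv",
]

#: Coulomb constant in kcal·Å·mol⁻¹·e⁻² (two unit charges 1 Å apart).
COULOMB_K = 332.0637

#: Wild-type activation barrier for the rearomatization step, kcal/mol.
DEFAULT_WT_BARRIER = 10.6

_MIN_SEPARATION = 1e-6  # Å; closer cross-group pairs are treated as overlaps


@dataclass(frozen=True)
class InteractionEnergy:
    """Residue↔QM Coulomb energy in both states (kcal/mol)."""

    residue_key: ResidueKey
    V_R: float
    V_TS: float


@dataclass(frozen=True)
class DeletionResult:
    """Outcome of one residue deletion: barrier shift and classification."""

    residue_key: ResidueKey
    V_R: float
    V_TS: float
    dE_m: float
    ddE: float
    effect_class: str  # anticatalytic | procatalytic | neutral


def _as_arrays(group) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(group, tuple) and len(group) == 2:
        coords, charges = group
        return (np.asarray(coords, dtype=float).reshape(-1, 3),
                np.asarray(charges, dtype=float).ravel())
    atoms: Sequence[AtomRecord] = getattr(group, "atoms", group)
    coords = np.array([[a.x, a.y, a.z] for a in atoms]).reshape(len(atoms), 3)
    charges = np.array([a.charge for a in atoms])
    return coords, charges


def coulomb(group_a, group_b, epsilon: float = 1.0) -> float:
    """Coulomb interaction energy between two charge groups, kcal/mol.

    Groups are sequences of AtomRecord (or a ``(coords, charges)`` pair).
    Symmetric in its arguments; a uniform dielectric ``epsilon`` divides the
    vacuum energy (default 1).  Raises if any cross-group pair is closer
    than 1e-6 Å, naming the offending pair.
    """
    ca, qa = _as_arrays(group_a)
    cb, qb = _as_arrays(group_b)
    if len(ca) == 0 or len(cb) == 0:
        return 0.0
    d = cdist(ca, cb)
    if d.min() < _MIN_SEPARATION:
        i, j = np.unravel_index(int(d.argmin()), d.shape)
        raise ValueError(
            f"overlapping atoms: group A atom {i} and group B atom {j} "
            f"are {d[i, j]:.2e} Å apart"
        )
    return float(COULOMB_K / epsilon * (qa[:, None] * qb[None, :] / d).sum())


def state_interaction(pair: ReactionStatePair, residue_key: ResidueKey,
                      epsilon: float = 1.0) -> InteractionEnergy:
    """Residue↔QM interaction energy in R and TS.

    V_R uses reactant coordinates with the reactant QM charge vector; V_TS
    uses transition-state coordinates with the TS vector.  The residue's own
    charges are read from each structure's records.
    """
    qm_idx = list(pair.qm.atom_indices)
    res_idx = pair.reactant.residue_atom_indices(residue_key)
    if not res_idx:
        raise KeyError(f"residue {residue_key} not found")
    if set(res_idx) & set(qm_idx):
        raise ValueError(f"residue {residue_key} overlaps the QM region")

    r_coords = pair.reactant.coords
    t_coords = pair.transition_state.coords
    r_charges = pair.reactant.charges
    t_charges = pair.transition_state.charges

    v_r = coulomb((r_coords[res_idx], r_charges[res_idx]),
                  (r_coords[qm_idx], pair.qm.charges_R), epsilon)
    v_ts = coulomb((t_coords[res_idx], t_charges[res_idx]),
                   (t_coords[qm_idx], pair.qm.charges_TS), epsilon)
    return InteractionEnergy(residue_key, v_r, v_ts)


def classify_effect(ddE: float, threshold: float) -> str:
    """Strict-threshold classification of a barrier shift."""
    if ddE < -threshold:
        return "anticatalytic"
    if ddE > threshold:
        return "procatalytic"
    return "neutral"


def deletion_scan(
    pair: ReactionStatePair,
    dE_wt: float = DEFAULT_WT_BARRIER,
    eligible: Sequence[ResidueKey] | None = None,
    threshold: float = 1.0,
    epsilon: float = 1.0,
) -> list[DeletionResult]:
    """Delete each eligible residue from the embedding and record ΔΔE.

    For residue m the barrier with m deleted is computed as
    ``dE_m = (dE_wt − V_TS(m)) − (−V_R(m))`` — i.e. state energies relative
    to the intact model — and ``ddE = dE_m − dE_wt``, which equals
    −(V_TS−V_R).  Results are sorted ascending by ddE (ties by residue key),
    so the strongest anticatalytic residues come first.
    """
    if eligible is None:
        from .structio import select_eligible_residues

        eligible = select_eligible_residues(pair)
    if not eligible:
        raise ValueError("no eligible residues to scan")

    results = []
    for key in eligible:
        ie = state_interaction(pair, key, epsilon)
        # composed exactly as the ledger recomputes it from an EnergyTable,
        # so exporting the scan and re-running it is bit-for-bit identical
        e_r_del = -ie.V_R
        e_ts_del = dE_wt - ie.V_TS
        dE_m = e_ts_del - e_r_del
        ddE = dE_m - dE_wt
        results.append(DeletionResult(key, ie.V_R, ie.V_TS, dE_m, ddE,
                                      classify_effect(ddE, threshold)))
    return sorted(results, key=lambda r: (r.ddE, r.residue_key))


# ---------------------------------------------------------------------------
# TSV output (machine format shared with the ledger)
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = ["chain", "resid", "resname", "V_R", "V_TS", "dE_m", "ddE", "effect_class"]


def write_scan_tsv(results: Sequence[DeletionResult], path: str | Path,
                   header: Sequence[str] = ()) -> None:
    """Full-precision TSV: chain, resid, resname, V_R, V_TS, dE_m, ddE, class."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_SCAN_COLUMNS) + "\n")
        for r in results:
            chain, resid, resname = r.residue_key
            fh.write(
                f"{chain}\t{resid}\t{resname}\t{r.V_R!r}\t{r.V_TS!r}\t"
                f"{r.dE_m!r}\t{r.ddE!r}\t{r.effect_class}\n"
            )


def read_scan_tsv(path: str | Path) -> list[DeletionResult]:
    results = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("chain\t"):
                continue
            chain, resid, resname, v_r, v_ts, de_m, dde, cls = line.rstrip("\n").split("\t")
            results.append(DeletionResult((chain, int(resid), resname),
                                          float(v_r), float(v_ts),
                                          float(de_m), float(dde), cls))
    return results
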