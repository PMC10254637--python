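"""Structures with partial charges: PQR I/O, reaction-state pairs, eligibility.

The scan operates on a pair of stationary-point structures (reactant R and
transition state TS) whose atoms are in identical order, with per-atom partial
charges in PQR format, plus a QM-region definition carrying two charge vectors
(one per state).  This module owns those containers and the residue-eligibility
rule for the deletion scan: every residue within a cutoff of the QM region,
excluding Gly/Pro and explicitly excluded residue ids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Structure",
    "QMRegion",
    "ReactionStatePair",
    "PQRParseError",
    "read_pqr",
    "write_pqr",
    "read_multimodel",
    "write_multimodel_pdb",
    "apply_charge_sidecar",
    "read_qm_region",
    "write_qm_region",
    "select_eligible_residues",
]

ResidueKey = tuple[str, int, str]  # (chain_id, residue_id, residue_name)


class PQRParseError(ValueError):
    """Raised for malformed PQR/PDB records; message names the line number."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership, coordinates (Å), charge (e)."""

    serial: int
    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    x: float
    y: float
    z: float
    charge: float
    radius: float = 0.0
    element: str = ""

    def __post_init__(self) -> None:
        for v, what in ((self.x, "x"), (self.y, "y"), (self.z, "z"), (self.charge, "charge")):
            if not np.isfinite(v):
                raise ValueError(f"non-finite {what} for atom {self.serial} {self.atom_name}")

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_id, self.residue_name)

    @property
    def atom_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_id, self.atom_name)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    def is_hydrogen(self) -> bool:
        if self.element:
            return self.element.upper() == "H"
        name = self.atom_name.lstrip("0123456789")
        return name[:1].upper() == "H"


@dataclass
class Structure:
    """An ordered list of atoms; atom order is the canonical identity."""

    atoms: list[AtomRecord]
    model_index: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            k = a.atom_key
            if k in seen:
                raise ValueError(f"duplicate atom {k} in model {self.model_index}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms]).reshape(len(self.atoms), 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def residue_keys(self) -> list[ResidueKey]:
        """Residue keys in order of first appearance."""
        out: list[ResidueKey] = []
        seen: set[ResidueKey] = set()
        for a in self.atoms:
            k = a.residue_key
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out

    def residue_atom_indices(self, key: ResidueKey) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.residue_key == key]

    def index_of(self, chain_id: str, residue_id: int, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.atom_key == (chain_id, residue_id, atom_name):
                return i
        raise KeyError(f"atom ({chain_id!r}, {residue_id}, {atom_name!r}) not found")


@dataclass
class QMRegion:
    """QM-region atoms and their two per-state charge vectors.

    ``site_labels`` optionally maps atom indices to ``donor_site`` /
    ``acceptor_site`` / ``other`` to record where the transferring charge
    resides (proton-donor side vs carboxylate-acceptor side).
    """

    atom_indices: list[int]
    charges_R: np.ndarray
    charges_TS: np.ndarray
    site_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.charges_R = np.asarray(self.charges_R, dtype=float)
        self.charges_TS = np.asarray(self.charges_TS, dtype=float)
        n = len(self.atom_indices)
        if len(self.charges_R) != n or len(self.charges_TS) != n:
            raise ValueError("charge vectors must match the number of QM atoms")
        if abs(self.charges_R.sum() - self.charges_TS.sum()) > 1e-10:
            raise ValueError(
                "total QM charge differs between R and TS "
                f"({self.charges_R.sum():.12f} vs {self.charges_TS.sum():.12f}); "
                "proton transfer conserves total charge"
            )


@dataclass
class ReactionStatePair:
    """Reactant and transition-state structures with a shared QM region."""

    reactant: Structure
    transition_state: Structure
    qm: QMRegion

    def __post_init__(self) -> None:
        r, t = self.reactant, self.transition_state
        if len(r) != len(t):
            raise ValueError(f"R has {len(r)} atoms, TS has {len(t)}")
        for i, (a, b) in enumerate(zip(r.atoms, t.atoms)):
            if a.atom_key != b.atom_key:
                raise ValueError(
                    f"atom {i}: R has {a.atom_key}, TS has {b.atom_key}; "
                    "R and TS must share one atom ordering"
                )
        nmax = len(r)
        for idx in self.qm.atom_indices:
            if not 0 <= idx < nmax:
                raise ValueError(f"QM atom index {idx} out of range (0..{nmax - 1})")

    @property
    def qm_residue_keys(self) -> set[ResidueKey]:
        return {self.reactant.atoms[i].residue_key for i in self.qm.atom_indices}


# ---------------------------------------------------------------------------
# PQR I/O (whitespace-delimited dialect; chain column optional)
# ---------------------------------------------------------------------------

def _parse_pqr_fields(fields: Sequence[str], lineno: int) -> AtomRecord:
    # ATOM serial name resname [chain] resid x y z charge radius
    try:
        if len(fields) == 11:
            chain = fields[4]
            serial, name, resname = int(fields[1]), fields[2], fields[3]
            resid = int(fields[5])
            numbers = [float(v) for v in fields[6:11]]
        elif len(fields) == 10:
            chain = ""
            serial, name, resname = int(fields[1]), fields[2], fields[3]
            resid = int(fields[4])
            numbers = [float(v) for v in fields[5:10]]
        else:
            raise ValueError(f"expected 10 or 11 fields, got {len(fields)}")
    except ValueError as exc:
        raise PQRParseError(f"line {lineno}: malformed PQR record: {exc}") from None
    x, y, z, charge, radius = numbers
    return AtomRecord(serial, name, resname, resid, chain, x, y, z, charge, radius)


def read_pqr(path: str | Path) -> Structure:
    """Read a single-model whitespace-delimited PQR file.

    Accepts both dialects (with or without the chain column); an absent chain
    becomes chain_id ``""``.  Raises :class:`PQRParseError` naming the line
    number for malformed records and :class:`ValueError` for empty files.
    """
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                atoms.append(_parse_pqr_fields(line.split(), lineno))
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms)


def write_pqr(structure: Structure, path: str | Path, header: Iterable[str] = ()) -> None:
    """Write a Structure as whitespace-delimited PQR (coords %.3f, q/r %.4f)."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"REMARK {line}\n")
        for a in structure.atoms:
            chain = f"{a.chain_id} " if a.chain_id else ""
            fh.write(
                f"ATOM  {a.serial:5d} {a.atom_name:<4s} {a.residue_name:<4s} "
                f"{chain}{a.residue_id:4d} {a.x:10.3f} {a.y:10.3f} {a.z:10.3f} "
                f"{a.charge:8.4f} {a.radius:7.4f}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Multi-model trajectories (PDB fixed-column or PQR whitespace records)
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip()
        resid = int(line[22:26])
        x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PQRParseError(f"line {lineno}: malformed PDB ATOM record: {exc}") from None
    return AtomRecord(serial, name, resname, resid, chain, x, y, z, 0.0, element=element)


def _looks_like_pqr(line: str) -> bool:
    fields = line.split()
    if len(fields) not in (10, 11):
        return False
    try:
        _parse_pqr_fields(fields, 0)
    except PQRParseError:
        return False
    return True


def read_multimodel(path: str | Path) -> list[Structure]:
    """Read a multi-model PDB/PQR trajectory (MODEL/ENDMDL blocks).

    A file without MODEL records yields a single Structure.  All models must
    share one (chain, resid, atom_name) sequence; PDB records carry no charge
    (supply one via :func:`apply_charge_sidecar` if needed).
    """
    models: list[Structure] = []
    current: list[AtomRecord] = []
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                saw_model = True
                current = []
            elif line.startswith("ENDMDL"):
                models.append(Structure(current, model_index=len(models)))
            elif line.startswith(("ATOM", "HETATM")):
                if _looks_like_pqr(line):
                    current.append(_parse_pqr_fields(line.split(), lineno))
                else:
                    current.append(_parse_pdb_atom(line, lineno))
    if not saw_model:
        if not current:
            raise ValueError(f"{path}: no ATOM/HETATM records found")
        models = [Structure(current, model_index=0)]
    if not models:
        raise ValueError(f"{path}: no complete MODEL blocks found")
    ref_keys = [a.atom_key for a in models[0].atoms]
    for m in models[1:]:
        if [a.atom_key for a in m.atoms] != ref_keys:
            raise ValueError(f"model {m.model_index} atom sequence differs from model 0")
    return models


def write_multimodel_pdb(models: Sequence[Structure], path: str | Path,
                         header: Iterable[str] = ()) -> None:
    """Write structures as a multi-model PDB file (coordinates at %.3f)."""
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"REMARK {line}\n")
        for i, m in enumerate(models, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            for a in m.atoms:
                chain = (a.chain_id or " ")[0]
                fh.write(
                    f"ATOM  {a.serial:5d} {a.atom_name:<4.4s}{a.residue_name:<4.4s}"
                    f"{chain}{a.residue_id:4d}    "
                    f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def apply_charge_sidecar(models: list[Structure], csv_path: str | Path) -> list[Structure]:
    """Attach charges from a sidecar CSV (chain,resid,atom_name,charge)."""
    import pandas as pd

    table = pd.read_csv(csv_path)
    lookup = {
        (str(r.chain) if str(r.chain) != "nan" else "", int(r.resid), str(r.atom_name)): float(r.charge)
        for r in table.itertuples()
    }
    out = []
    for m in models:
        atoms = []
        for a in m.atoms:
            q = lookup.get(a.atom_key)
            if q is None:
                raise KeyError(f"no sidecar charge for atom {a.atom_key}")
            atoms.append(AtomRecord(a.serial, a.atom_name, a.residue_name, a.residue_id,
                                    a.chain_id, a.x, a.y, a.z, q, a.radius, a.element))
        out.append(Structure(atoms, model_index=m.model_index))
    return out


# ---------------------------------------------------------------------------
# QM-region JSON
# ---------------------------------------------------------------------------

def write_qm_region(qm: QMRegion, path: str | Path) -> None:
    payload = {
        "atom_indices": list(qm.atom_indices),
        "charges_R": [float(q) for q in qm.charges_R],
        "charges_TS": [float(q) for q in qm.charges_TS],
        "site_labels": {str(k): v for k, v in qm.site_labels.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_qm_region(path: str | Path) -> QMRegion:
    payload = json.loads(Path(path).read_text())
    return QMRegion(
        atom_indices=[int(i) for i in payload["atom_indices"]],
        charges_R=np.asarray(payload["charges_R"], dtype=float),
        charges_TS=np.asarray(payload["charges_TS"], dtype=float),
        site_labels={int(k): v for k, v in payload.get("site_labels", {}).items()},
    )


# ---------------------------------------------------------------------------
# Deletion eligibility
# ---------------------------------------------------------------------------

def select_eligible_residues(
    pair: ReactionStatePair,
    radius: float = 10.0,
    excluded_resnames: set[str] = frozenset({"GLY", "PRO"}),
    excluded_ids: set[ResidueKey] | None = None,
) -> list[ResidueKey]:
    """Environment residues eligible for the deletion scan.

    A residue is eligible when the minimum distance from any of its atoms
    (hydrogens included) to any QM-region atom, measured on the reactant
    structure, is <= ``radius``; Gly/Pro, QM-region residues, and
    ``excluded_ids`` are removed.  Output is sorted by (chain, residue_id).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not pair.qm.atom_indices:
        raise ValueError("empty QM region")
    excluded_ids = excluded_ids or set()
    excluded_resnames = {r.upper() for r in excluded_resnames}

    coords = pair.reactant.coords
    qm_idx = set(pair.qm.atom_indices)
    tree = cKDTree(coords[sorted(qm_idx)])
    qm_keys = pair.qm_residue_keys

    min_dist: dict[ResidueKey, float] = {}
    for i, atom in enumerate(pair.reactant.atoms):
        if i in qm_idx:
            continue
        d, _ = tree.query(coords[i])
        key = atom.residue_key
        if key not in min_dist or d < min_dist[key]:
            min_dist[key] = float(d)

    eligible = [
        key
        for key, d in min_dist.items()
        if d <= radius
        and key[2].upper() not in excluded_resnames
        and key not in qm_keys
        and key not in excluded_ids
    ]
    return sorted(eligible, key=lambda k: (k[0], k[1]))
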