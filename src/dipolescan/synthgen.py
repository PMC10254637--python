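"""Synthetic toy-enzyme fixtures with analytically known ΔΔE ground truth.

The generator emulates the physical situation the deletion scan assumes: a
small QM core in which the rate-limiting step moves charge between two
named sites — a proton-donor site on the substrate (the quinonoid oxygen,
``OX``, which develops negative charge at the TS) and the acceptor
carboxylate oxygen of the catalytic glutamate (``OE1``) — surrounded by a
shell of charged/polar/apolar environment residues at controlled positions.

Between R and TS a fraction λ of a unit (positive) charge moves donor →
acceptor: the donor-site charge drops by λ and the acceptor-site charge
rises by λ, so total charge is conserved.  λ = 0.5 models a transition
state in which the transferring proton is halfway along the coordinate.
The environment is rigid (identical coordinates and charges in both
states), so every MM–MM term cancels in ΔΔE and each residue's ground-truth
effect is a closed-form Coulomb sum, recorded in a GroundTruth JSON.

Also provided: Gaussian-jitter multi-model trajectories (a stand-in for an
MD production run when exercising the geometry monitors) and synthetic
wild-type/deletion energy tables with planted ΔΔE values for the ledger.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .electro import COULOMB_K
from .structio import (
    AtomRecord,
    QMRegion,
    ReactionStatePair,
    ResidueKey,
    Structure,
    write_multimodel_pdb,
    write_pqr,
    write_qm_region,
)

__all__ = [
    "PlantedResidue",
    "ToyEnzymeSpec",
    "GroundTruth",
    "ToyEnzymeFixture",
    "toy_ncs_spec",
    "make_toy_enzyme",
    "make_trajectory",
    "make_energy_table",
]


# Side-chain-like atom templates: (atom_name, offset from residue center (Å),
# fractional charge).  Charges of charged types sum to ±1 and are scaled by
# the planted formal charge; polar types sum to 0 but carry a dipole.
_TEMPLATES: dict[str, list[tuple[str, tuple[float, float, float], float]]] = {
    "ASP": [("CB", (0.0, 0.0, 0.0), 0.0), ("CG", (1.2, 0.4, 0.0), 0.2),
            ("OD1", (2.0, -0.5, 0.4), -0.6), ("OD2", (1.9, 1.4, -0.5), -0.6)],
    "GLU": [("CB", (0.0, 0.0, 0.0), 0.0), ("CD", (1.3, 0.5, 0.2), 0.2),
            ("OE1", (2.2, -0.4, 0.3), -0.6), ("OE2", (2.0, 1.5, -0.3), -0.6)],
    "LYS": [("CB", (0.0, 0.0, 0.0), 0.0), ("CE", (1.4, 0.3, -0.2), 0.25),
            ("NZ", (2.3, 0.9, 0.3), 0.75)],
    "ARG": [("CB", (0.0, 0.0, 0.0), 0.0), ("CZ", (1.6, 0.2, 0.1), 0.4),
            ("NH1", (2.4, -0.7, 0.3), 0.3), ("NH2", (2.4, 1.1, -0.2), 0.3)],
    "SER": [("CB", (0.0, 0.0, 0.0), 0.05), ("OG", (1.0, 0.5, 0.2), -0.35),
            ("HG", (1.6, 1.1, 0.4), 0.30)],
    "THR": [("CB", (0.0, 0.0, 0.0), 0.05), ("OG1", (1.1, 0.4, -0.3), -0.35),
            ("HG1", (1.7, 1.0, -0.5), 0.30)],
    "TYR": [("CB", (0.0, 0.0, 0.0), 0.0), ("OH", (0.5, 0.0, 0.0), -0.40),
            ("HH", (-0.5, 0.0, 0.0), 0.40)],
    "ALA": [("CB", (0.0, 0.0, 0.0), 0.0)],
    "LEU": [("CB", (0.0, 0.0, 0.0), 0.0), ("CD1", (1.2, 0.6, 0.3), 0.0),
            ("CD2", (1.2, -0.6, -0.3), 0.0)],
}

_CLASS_RESNAMES = {
    "acidic": ["ASP", "GLU"],
    "basic": ["LYS", "ARG"],
    "polar": ["SER", "THR"],  # TYR is reserved for planted oriented probes
    "apolar": ["ALA", "LEU"],
}


@dataclass
class PlantedResidue:
    """One deliberately placed environment residue with known properties."""

    resname: str
    resid: int
    residue_class: str          # acidic | basic | polar | apolar
    position_policy: str        # near_donor | near_acceptor | equidistant | far
    formal_charge: float = 0.0  # e; scales the template charges of charged types
    chain: str = "A"
    distance: float | None = None  # radial distance from the QM center, Å
    oriented: bool = True       # keep template offsets unrotated (axis-aligned)
    caged: bool = False         # surround with neutral atoms (buried control)


@dataclass
class ToyEnzymeSpec:
    """Study conditions for one synthetic R/TS fixture."""

    n_env_residues: int = 30
    shell_radius_range: tuple[float, float] = (12.0, 18.0)
    planted: list[PlantedResidue] = field(default_factory=list)
    transfer_fraction: float = 0.5   # λ, fraction of unit charge moved donor→acceptor
    donor_acceptor_separation: float = 4.0  # Å between the two transfer sites
    jitter_sigma: float = 0.0        # Å, placement noise on template offsets
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.transfer_fraction <= 1.0:
            raise ValueError("transfer_fraction must be in [0, 1]")
        lo, hi = self.shell_radius_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("shell radii must be positive and ordered")


@dataclass
class GroundTruth:
    """Closed-form per-residue ΔΔE of a generated fixture (test oracle)."""

    per_residue: dict[ResidueKey, dict]
    total_ddE: float
    total_charge: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "total_ddE": self.total_ddE,
            "total_charge": self.total_charge,
            "per_residue": {
                f"{c}:{i}:{n}": info for (c, i, n), info in self.per_residue.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        per = {}
        for key, info in payload["per_residue"].items():
            chain, resid, resname = key.split(":")
            per[(chain, int(resid), resname)] = info
        return cls(per, payload["total_ddE"], payload["total_charge"], payload["seed"])


@dataclass
class ToyEnzymeFixture:
    pair: ReactionStatePair
    ground_truth: GroundTruth
    reactant_path: Path | None = None
    ts_path: Path | None = None
    qm_path: Path | None = None
    truth_path: Path | None = None


def toy_ncs_spec(seed: int = 0) -> ToyEnzymeSpec:
    """Default preset mirroring the qualitative candidate pattern of the
    modeled norcoclaurine-synthase system.

    Six charged residues are planted on the wrong side of the reaction
    dipole (acidic near the donor, basic near the acceptor → anticatalytic),
    one neutral tyrosine-like dipolar residue sits close enough to the sites
    to have a large negative ΔΔE despite zero net charge, and one basic
    residue near the donor is both procatalytic and buried inside a neutral
    cage (the exposure control).
    """
    planted = [
        PlantedResidue("ASP", 64, "acidic", "near_donor", -1.0, distance=12.5),
        PlantedResidue("ASP", 71, "acidic", "near_donor", -1.0, distance=14.0),
        PlantedResidue("GLU", 117, "acidic", "near_donor", -1.0, distance=15.5),
        PlantedResidue("ARG", 105, "basic", "near_acceptor", +1.0, distance=13.0),
        PlantedResidue("LYS", 110, "basic", "near_acceptor", +1.0, distance=14.5),
        PlantedResidue("LYS", 163, "basic", "near_acceptor", +1.0, distance=16.0),
        PlantedResidue("TYR", 60, "polar", "near_acceptor", 0.0, distance=7.0),
        PlantedResidue("LYS", 201, "basic", "near_donor", +1.0, distance=13.5,
                       caged=True),
        PlantedResidue("GLU", 202, "acidic", "near_acceptor", -1.0, distance=12.8),
        # surface-exposure control: far outside the shell, guaranteed sparse
        PlantedResidue("LYS", 210, "basic", "equidistant", +1.0, distance=32.0),
    ]
    return ToyEnzymeSpec(n_env_residues=30, planted=planted, seed=seed)


# ---------------------------------------------------------------------------
# QM core geometry
# ---------------------------------------------------------------------------

def _qm_atoms(sep: float) -> tuple[list[AtomRecord], list[float], int, int]:
    """Small QM core: substrate donor side + catalytic glutamate acceptor side.

    Returns (atoms, reactant charges, donor index, acceptor index) where the
    indices point at the two transfer-site atoms within the returned list.
    """
    h = sep / 2.0
    atoms = [
        # substrate (quinonoid) side; OX is the donor site
        AtomRecord(1, "C5", "QIN", 900, "A", -h + 1.0, 0.8, 0.0, 0.10),
        AtomRecord(2, "OX", "QIN", 900, "A", -h, 0.0, 0.0, 0.0),
        AtomRecord(3, "C4", "QIN", 900, "A", -h + 0.6, -1.2, 0.3, -0.10),
        # catalytic glutamate carboxylate; OE1 is the acceptor site
        AtomRecord(4, "CD", "GLU", 109, "A", h + 1.1, 0.6, -0.2, 0.30),
        AtomRecord(5, "OE1", "GLU", 109, "A", h, 0.0, 0.0, -1.0),
        AtomRecord(6, "OE2", "GLU", 109, "A", h + 1.8, 1.6, -0.4, -0.30),
    ]
    charges_r = [a.charge for a in atoms]
    return atoms, charges_r, 1, 4


def _round3(v: float) -> float:
    return round(float(v), 3)


def _sample_direction(rng: np.random.Generator, policy: str) -> np.ndarray:
    """Unit direction respecting a placement policy (donor at −x, acceptor +x)."""
    if policy == "equidistant":
        ang = rng.uniform(0, 2 * math.pi)
        return np.array([0.0, math.cos(ang), math.sin(ang)])
    # cone of half-angle 25° about ±x for near_*; uniform sphere otherwise
    if policy in ("far", "shell"):
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)
    axis = np.array([-1.0, 0.0, 0.0]) if policy == "near_donor" else np.array([1.0, 0.0, 0.0])
    cos_max = math.cos(math.radians(25.0))
    u = rng.uniform(cos_max, 1.0)
    ang = rng.uniform(0, 2 * math.pi)
    s = math.sqrt(1 - u * u)
    perp1 = np.array([0.0, 1.0, 0.0])
    perp2 = np.array([0.0, 0.0, 1.0])
    return u * axis + s * (math.cos(ang) * perp1 + math.sin(ang) * perp2)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_toy_enzyme(spec: ToyEnzymeSpec, outdir: str | Path | None = None,
                    prefix: str = "toy") -> ToyEnzymeFixture:
    """Generate an R/TS pair with a rigid environment and exact ground truth.

    The environment is identical in both states; only the QM charge vector
    changes (λ of a unit charge moves from the donor-site atom to the
    acceptor-site atom).  Per-residue ΔΔE is computed by a plain closed-form
    Coulomb double loop over the final (precision-rounded) records, so it is
    exact for the emitted files.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lam = spec.transfer_fraction

    qm_atoms, qm_charges_r, donor_i, acceptor_i = _qm_atoms(spec.donor_acceptor_separation)
    qm_charges_ts = list(qm_charges_r)
    qm_charges_ts[donor_i] -= lam
    qm_charges_ts[acceptor_i] += lam

    atoms: list[AtomRecord] = list(qm_atoms)
    truth_meta: dict[ResidueKey, dict] = {}
    centers: list[np.ndarray] = []
    serial = len(atoms) + 1
    lo, hi = spec.shell_radius_range

    def place_residue(resname: str, resid: int, chain: str, policy: str,
                      formal_charge: float, distance: float | None,
                      oriented: bool) -> tuple[ResidueKey, np.ndarray]:
        nonlocal serial
        template = _TEMPLATES[resname]
        template_sum = sum(q for _, _, q in template)
        if abs(template_sum) > 1e-9:
            scale = formal_charge / template_sum
        else:
            scale = 1.0  # neutral/polar templates used as-is
        for _attempt in range(100):
            if distance is not None:
                r = distance
            elif policy == "far":
                r = rng.uniform(hi + 5.0, hi + 10.0)
            else:
                r = rng.uniform(lo, hi)
            center = r * _sample_direction(rng, policy)
            if all(np.linalg.norm(center - c) >= 1.0 for c in centers):
                break
        else:
            raise RuntimeError(f"could not place residue {resname} {resid} "
                               "without collisions after 100 attempts")
        centers.append(center)
        rot = np.eye(3) if oriented else _random_rotation(rng)
        key = (chain, resid, resname)
        for atom_name, offset, q in template:
            pos = center + rot @ np.asarray(offset)
            if spec.jitter_sigma > 0:
                pos = pos + rng.normal(scale=spec.jitter_sigma, size=3)
            atoms.append(AtomRecord(serial, atom_name, resname, resid, chain,
                                    _round3(pos[0]), _round3(pos[1]), _round3(pos[2]),
                                    round(q * scale, 4), 1.5))
            serial += 1
        return key, center

    # planted residues first (fixed ids), then random fillers
    planted_keys: list[ResidueKey] = []
    for p in spec.planted:
        if p.residue_class not in _CLASS_RESNAMES:
            raise ValueError(f"unknown residue class {p.residue_class!r}")
        key, center = place_residue(p.resname, p.resid, p.chain, p.position_policy,
                                    p.formal_charge, p.distance, p.oriented)
        planted_keys.append(key)
        truth_meta[key] = {"class": p.residue_class, "policy": p.position_policy,
                           "formal_charge": p.formal_charge, "planted": True,
                           "caged": p.caged}
        if p.caged:
            # neutral single-atom cage residues within ~5 Å of the charged group
            n_cages = sum(1 for m in truth_meta.values() if m.get("cage"))
            for j in range(24):
                v = rng.normal(size=3)
                v = 4.0 * v / np.linalg.norm(v)
                pos = center + np.array([1.5, 0.5, 0.0]) + v
                cage_resid = 300 + n_cages + j
                atoms.append(AtomRecord(serial, "CB", "ALA", cage_resid, "A",
                                        _round3(pos[0]), _round3(pos[1]), _round3(pos[2]),
                                        0.0, 1.5))
                truth_meta[("A", cage_resid, "ALA")] = {
                    "class": "apolar", "policy": "cage", "formal_charge": 0.0,
                    "planted": False, "cage": True}
                serial += 1

    n_fillers = max(0, spec.n_env_residues - len(spec.planted))
    filler_classes = ["polar", "apolar"]
    for j in range(n_fillers):
        cls = filler_classes[j % 2]
        resname = _CLASS_RESNAMES[cls][int(rng.integers(len(_CLASS_RESNAMES[cls])))]
        key, _ = place_residue(resname, 400 + j, "A", "shell", 0.0, None, False)
        truth_meta[key] = {"class": cls, "policy": "filler", "formal_charge": 0.0,
                           "planted": False}

    reactant = Structure(atoms, model_index=0)
    transition = Structure(list(atoms), model_index=0)  # rigid environment & geometry
    qm = QMRegion(
        atom_indices=list(range(len(qm_atoms))),
        charges_R=np.array(qm_charges_r),
        charges_TS=np.array(qm_charges_ts),
        site_labels={donor_i: "donor_site", acceptor_i: "acceptor_site",
                     **{i: "other" for i in range(len(qm_atoms)) if i not in (donor_i, acceptor_i)}},
    )
    pair = ReactionStatePair(reactant, transition, qm)

    # closed-form ground truth: plain double loop over the rounded records
    truth: dict[ResidueKey, dict] = {}
    total = 0.0
    qm_positions = [a.position for a in qm_atoms]
    for key in reactant.residue_keys():
        if key in pair.qm_residue_keys:
            continue
        idx = reactant.residue_atom_indices(key)
        v_r = v_ts = 0.0
        for i in idx:
            a = reactant.atoms[i]
            for jpos, q_r, q_ts in zip(qm_positions, qm_charges_r, qm_charges_ts):
                rij = math.dist((a.x, a.y, a.z), tuple(jpos))
                v_r += COULOMB_K * a.charge * q_r / rij
                v_ts += COULOMB_K * a.charge * q_ts / rij
        dde = -(v_ts - v_r)
        total += dde
        meta = truth_meta.get(key, {})
        truth[key] = {"ddE": dde, "V_R": v_r, "V_TS": v_ts, **meta}

    gt = GroundTruth(truth, total_ddE=total,
                     total_charge=float(sum(a.charge for a in reactant.atoms)),
                     seed=spec.seed)

    fixture = ToyEnzymeFixture(pair, gt)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fixture.reactant_path = outdir / f"{prefix}_R.pqr"
        fixture.ts_path = outdir / f"{prefix}_TS.pqr"
        fixture.qm_path = outdir / f"{prefix}_qm.json"
        fixture.truth_path = outdir / f"{prefix}_truth.json"
        hdr = [f"toy enzyme fixture seed={spec.seed} lambda={lam}"]
        write_pqr(reactant, fixture.reactant_path, header=hdr)
        write_pqr(transition, fixture.ts_path, header=hdr)
        write_qm_region(qm, fixture.qm_path)
        gt.to_json(fixture.truth_path)
    return fixture


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def make_trajectory(reference: Structure, n_frames: int, jitter_sigma: float,
                    seed: int, path: str | Path | None = None) -> list[Structure]:
    """Gaussian-jitter trajectory around a reference geometry.

    Frame 0 is the reference itself; frames 1..n−1 add i.i.d. Gaussian
    displacements (σ = jitter_sigma, per coordinate).  Coordinates are
    rounded to 0.001 Å (the PDB precision) so in-memory frames equal the
    written file.  Deterministic under ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    ref_coords = reference.coords
    frames: list[Structure] = []
    for f in range(n_frames):
        if f == 0 or jitter_sigma == 0:
            coords = ref_coords
        else:
            coords = ref_coords + rng.normal(scale=jitter_sigma, size=ref_coords.shape)
        atoms = [
            AtomRecord(a.serial, a.atom_name, a.residue_name, a.residue_id, a.chain_id,
                       _round3(c[0]), _round3(c[1]), _round3(c[2]),
                       a.charge, a.radius, a.element)
            for a, c in zip(reference.atoms, coords)
        ]
        frames.append(Structure(atoms, model_index=f))
    if path is not None:
        write_multimodel_pdb(frames, path,
                             header=[f"jitter trajectory seed={seed} sigma={jitter_sigma}"])
    return frames


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

def make_energy_table(
    n_residues: int,
    wt_barrier: float = 10.6,
    planted_effects: dict[int, float] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    path: str | Path | None = None,
) -> "EnergyTable":
    """Synthetic wild-type + per-deletion energy table with planted ΔΔE.

    Residue ids are 1..n (chain "A", resname "RES"); ``planted_effects``
    maps a residue id to its true ΔΔE in kcal/mol (unlisted residues get 0).
    Independent Gaussian noise of ``noise_sigma`` kcal/mol is added to every
    state energy, so the noiseless table recovers the planted values exactly
    through the ledger.  Deterministic under ``seed``.
    """
    from .ledger import EnergyTable, write_energy_csv

    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    planted_effects = planted_effects or {}
    unknown = set(planted_effects) - set(range(1, n_residues + 1))
    if unknown:
        raise ValueError(f"planted ids outside 1..{n_residues}: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    def jitter() -> float:
        return float(rng.normal(scale=noise_sigma)) if noise_sigma > 0 else 0.0

    wt_e_r = 0.0 + jitter()
    wt_e_ts = wt_barrier + jitter()
    rows = []
    for resid in range(1, n_residues + 1):
        dde = planted_effects.get(resid, 0.0)
        rows.append((("A", resid, "RES"), 0.0 + jitter(), wt_barrier + dde + jitter()))
    table = EnergyTable(wt_e_r, wt_e_ts, rows, unit="kcal/mol")
    if path is not None:
        write_energy_csv(table, path, header=[f"synthetic energy table seed={seed}"])
    return table
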