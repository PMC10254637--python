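"""Turn a deletion scan into ranked, filtered mutation candidates.

Selection logic: a candidate must (i) raise the wild-type barrier by more
than the threshold when deleted (ΔΔE < −threshold, strictly), (ii) carry a
formal side-chain charge — only charge-neutralizing substitutions are
considered non-disruptive — and (iii) not belong to the excluded set
(catalytic or otherwise mechanistically required residues).  Residues with
a large effect that fail (ii) or (iii) are reported separately with the
reason, since they explain the energetics without being viable targets.

Suggested substitutions cancel the side-chain charge while keeping size and
polarity as close as possible: Glu→Gln, Asp→Asn, Lys→Gln; Arg (and any
other charged type without a canonical neutral partner) falls back to Gln.
Exposure and hydrogen-bond freedom are geometric proxies — a sparse heavy-
atom neighbourhood around the charged group, and no foreign polar heavy
atom within H-bond range — reported as annotations with their raw counts,
not used as filters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .electro import DeletionResult
from .structio import ResidueKey, Structure

__all__ = [
    "AdvisorConfig",
    "Candidate",
    "CandidateReport",
    "CHARGED_RESNAMES",
    "suggest_mutation",
    "is_exposed",
    "is_hbond_free",
    "build_report",
    "write_report",
]

#: Residue types treated as formally charged (His only when its recorded
#: side-chain charges sum to a nonzero integer).
CHARGED_RESNAMES = {"ASP", "GLU", "LYS", "ARG", "HIS"}

_STANDARD_RESNAMES = CHARGED_RESNAMES | {
    "ALA", "ASN", "CYS", "GLN", "GLY", "ILE", "LEU", "MET", "PHE", "PRO",
    "SER", "THR", "TRP", "TYR", "VAL", "RES",
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "HA", "OXT"}

#: Side-chain terminal heavy atoms defining the charged group per type.
_CHARGED_GROUP_ATOMS = {
    "ASP": {"CG", "OD1", "OD2"},
    "GLU": {"CD", "OE1", "OE2"},
    "LYS": {"NZ"},
    "ARG": {"CZ", "NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}

_DEFAULT_MUTATION_MAP = {"GLU": "GLN", "ASP": "ASN", "LYS": "GLN"}


@dataclass
class AdvisorConfig:
    threshold: float = 1.0                     # kcal/mol, strict
    excluded_residues: set[ResidueKey] = field(default_factory=set)
    mutation_map: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_MUTATION_MAP))
    charged_fallback: str = "GLN"              # for Arg-like types without a partner
    neighbor_radius: float = 8.0               # Å, exposure neighbourhood
    max_heavy_neighbors: int = 16              # exposed iff count <= this
    hbond_cutoff: float = 3.5                  # Å, polar heavy atom distance

    def config_hash(self) -> str:
        payload = {
            "threshold": self.threshold,
            "excluded_residues": sorted(map(list, self.excluded_residues)),
            "mutation_map": self.mutation_map,
            "charged_fallback": self.charged_fallback,
            "neighbor_radius": self.neighbor_radius,
            "max_heavy_neighbors": self.max_heavy_neighbors,
            "hbond_cutoff": self.hbond_cutoff,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class Candidate:
    residue_key: ResidueKey
    ddE: float
    suggested_mutation: str
    exposed: bool
    neighbor_count: int
    hbond_free: bool


@dataclass
class CandidateReport:
    candidates: list[Candidate]
    ineligible: list[tuple[ResidueKey, float, str]]  # (key, ddE, reason)
    header: dict


def suggest_mutation(residue_type: str, config: AdvisorConfig | None = None) -> str | None:
    """Charge-cancelling substitution for a residue type.

    Returns the mapped neutral type for charged inputs (Glu→Gln, Asp→Asn,
    Lys→Gln; otherwise the configured fallback) and None — "no change
    needed" — for neutral types.  Unknown codes raise.
    """
    config = config or AdvisorConfig()
    rt = residue_type.upper()
    if rt not in _STANDARD_RESNAMES:
        raise ValueError(f"unknown residue type {residue_type!r}")
    if rt in config.mutation_map:
        return config.mutation_map[rt]
    if rt in CHARGED_RESNAMES:
        return config.charged_fallback
    return None


def _sidechain_charge(structure: Structure, key: ResidueKey) -> int:
    idx = structure.residue_atom_indices(key)
    q = sum(structure.atoms[i].charge for i in idx
            if structure.atoms[i].atom_name.upper() not in _BACKBONE_NAMES)
    return int(round(q))


def is_charged_residue(structure: Structure, key: ResidueKey) -> bool:
    """Charged type with a nonzero formal side-chain charge.

    His counts only when its recorded charges actually sum to a nonzero
    integer (protonation is not inferred from the name alone).
    """
    resname = key[2].upper()
    if resname not in CHARGED_RESNAMES:
        return False
    if resname == "HIS":
        return _sidechain_charge(structure, key) != 0
    return True


def _charged_group_indices(structure: Structure, key: ResidueKey) -> list[int]:
    idx = structure.residue_atom_indices(key)
    if not idx:
        raise KeyError(f"residue {key} not found in structure")
    names = _CHARGED_GROUP_ATOMS.get(key[2].upper())
    if names:
        group = [i for i in idx if structure.atoms[i].atom_name.upper() in names]
        if group:
            return group
    # fallback: all side-chain heavy atoms, else all heavy atoms
    group = [i for i in idx
             if structure.atoms[i].atom_name.upper() not in _BACKBONE_NAMES
             and not structure.atoms[i].is_hydrogen()]
    if not group:
        raise ValueError(f"residue {key} has no side-chain heavy atoms")
    return group


def is_exposed(structure: Structure, key: ResidueKey,
               config: AdvisorConfig | None = None) -> tuple[bool, int]:
    """Solvent-exposure proxy: few foreign heavy atoms near the charged group.

    Counts heavy atoms of *other* residues within ``neighbor_radius`` of the
    charged-group centroid; exposed iff the count is <= the configured
    maximum.  Returns (exposed, neighbor_count).
    """
    config = config or AdvisorConfig()
    group = _charged_group_indices(structure, key)
    coords = structure.coords
    centroid = coords[group].mean(axis=0)
    count = 0
    for i, a in enumerate(structure.atoms):
        if a.residue_key == key or a.is_hydrogen():
            continue
        if np.linalg.norm(coords[i] - centroid) <= config.neighbor_radius:
            count += 1
    return count <= config.max_heavy_neighbors, count


def is_hbond_free(structure: Structure, key: ResidueKey,
                  config: AdvisorConfig | None = None) -> bool:
    """True when no polar heavy atom (N/O) of another residue is within
    H-bond range of any charged-group atom."""
    config = config or AdvisorConfig()
    group = _charged_group_indices(structure, key)
    coords = structure.coords
    for i, a in enumerate(structure.atoms):
        if a.residue_key == key or a.is_hydrogen():
            continue
        elem = (a.element or a.atom_name.lstrip("0123456789")[:1]).upper()
        if elem not in ("N", "O"):
            continue
        d = np.linalg.norm(coords[i, None] - coords[group], axis=1).min()
        if d <= config.hbond_cutoff:
            return False
    return True


def build_report(scan: Sequence[DeletionResult], structure: Structure,
                 config: AdvisorConfig | None = None) -> CandidateReport:
    """Filter and annotate a scan into a candidate report.

    Candidates: ΔΔE < −threshold (strict) AND charged residue type AND not
    excluded; sorted ascending by ΔΔE.  Large-effect residues failing the
    type or exclusion filters appear in the ineligible section with the
    reason.  Raises if a scanned residue is absent from the structure.
    """
    if not scan:
        raise ValueError("empty scan")
    config = config or AdvisorConfig()
    structure_keys = set(structure.residue_keys())

    candidates: list[Candidate] = []
    ineligible: list[tuple[ResidueKey, float, str]] = []
    for r in sorted(scan, key=lambda r: (r.ddE, r.residue_key)):
        if r.residue_key not in structure_keys:
            raise ValueError(f"scan residue {r.residue_key} not present in structure")
        if not r.ddE < -config.threshold:
            continue
        if r.residue_key in config.excluded_residues:
            ineligible.append((r.residue_key, r.ddE, "excluded: mechanistically required"))
            continue
        if not is_charged_residue(structure, r.residue_key):
            ineligible.append((r.residue_key, r.ddE,
                               "not a charged residue type; no charge-cancelling mutation"))
            continue
        exposed, count = is_exposed(structure, r.residue_key, config)
        candidates.append(Candidate(
            r.residue_key, r.ddE,
            suggest_mutation(r.residue_key[2], config) or r.residue_key[2],
            exposed, count,
            is_hbond_free(structure, r.residue_key, config),
        ))

    header = {
        "n_scanned": len(scan),
        "threshold_kcal_mol": config.threshold,
        "config_hash": config.config_hash(),
        "n_candidates": len(candidates),
        "note": ("surrogate point-charge scan; deletion removes a residue's "
                 "embedding charges only"),
    }
    return CandidateReport(candidates, ineligible, header)


def write_report(report: CandidateReport, path: str | Path, fmt: str = "md") -> None:
    """Emit the report as Markdown (human) or TSV (machine)."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            for k, v in report.header.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("chain\tresid\tresname\tddE\tsuggested\texposed\tneighbors\thbond_free\n")
            for c in report.candidates:
                chain, resid, resname = c.residue_key
                fh.write(f"{chain}\t{resid}\t{resname}\t{c.ddE!r}\t{c.suggested_mutation}\t"
                         f"{int(c.exposed)}\t{c.neighbor_count}\t{int(c.hbond_free)}\n")
            for key, dde, reason in report.ineligible:
                fh.write(f"# ineligible\t{key[0]}\t{key[1]}\t{key[2]}\t{dde!r}\t{reason}\n")
        return
    lines = ["# Mutation candidate report", ""]
    lines += [f"- {k}: {v}" for k, v in report.header.items()]
    lines += ["", "| residue | ΔΔE (kcal/mol) | suggested | exposed | neighbors | H-bond free |",
              "|---|---|---|---|---|---|"]
    for c in report.candidates:
        chain, resid, resname = c.residue_key
        lines.append(f"| {chain}{resid} {resname} | {c.ddE:.1f} | {resname}→{c.suggested_mutation} | "
                     f"{'yes' if c.exposed else 'no'} | {c.neighbor_count} | "
                     f"{'yes' if c.hbond_free else 'no'} |")
    if report.ineligible:
        lines += ["", "## Large-effect residues not eligible for mutation", ""]
        for key, dde, reason in report.ineligible:
            lines.append(f"- {key[0]}{key[1]} {key[2]} (ΔΔE = {dde:.1f} kcal/mol): {reason}")
    path.write_text("\n".join(lines) + "\n")
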