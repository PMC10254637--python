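"""Geometry-stability analyses: superposition RMSD and catalytic distances.

Two checks commonly made before trusting a modeled enzyme system: (i) the
structure does not drift — RMSD of the backbone and of the active site
versus a reference stays small across a trajectory — and (ii) the catalytic
contacts persist, e.g. the carboxylate-oxygen•••substrate-proton distance
and the ammonium-proton•••carbonyl distances, tracked frame by frame.
Min-over-set monitors reproduce the per-member comparison used to show that
one carboxylate oxygen is always the near one while the other stays far,
whereas the three ammonium protons are equivalent.

RMSD uses plain (non-mass-weighted) least-squares rigid superposition with
a proper rotation (det = +1); the fit and measure selections may differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .structio import Structure

__all__ = [
    "AtomSel",
    "MonitorSpec",
    "DistanceMonitor",
    "RMSDSeries",
    "kabsch_rotation",
    "kabsch_rmsd",
    "rmsd_series",
    "monitor",
    "load_monitor_specs",
]

AtomSel = tuple[str, int, str]  # (chain_id, residue_id, atom_name)


@dataclass
class MonitorSpec:
    """A labelled distance: one anchor atom against one atom or a set.

    With a multi-member ``to`` set the reported series is the per-frame
    minimum; per-member series are also kept so each member's own mean can
    be compared.
    """

    label: str
    from_sel: AtomSel
    to_sels: list[AtomSel]


@dataclass
class DistanceMonitor:
    label: str
    distances: np.ndarray             # per-frame min distance, Å
    member_distances: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    @property
    def sd(self) -> float:
        # exactly-constant series must report exactly zero spread
        if np.all(self.distances == self.distances[0]):
            return 0.0
        return float(self.distances.std(ddof=0))

    def member_means(self) -> dict[str, float]:
        return {name: float(d.mean()) for name, d in self.member_distances.items()}


@dataclass
class RMSDSeries:
    selection: str
    values: np.ndarray  # per-frame RMSD vs reference, Å

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation and centroids aligning mobile onto target.

    Returns (R, mobile_centroid, target_centroid) with det(R) = +1 such that
    ``(mobile - mc) @ R.T + tc`` is the least-squares superposition.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    if len(P) < 3:
        raise ValueError("need at least 3 atoms to define a superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) fit selection")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, pc, qc


def kabsch_rmsd(
    mobile: np.ndarray,
    target: np.ndarray,
    fit_selection: Sequence[int] | None = None,
    measure_selection: Sequence[int] | None = None,
) -> float:
    """RMSD (Å) after optimal rigid superposition.

    The rotation/translation is fitted on ``fit_selection`` (default: all
    atoms) and the RMSD evaluated on ``measure_selection`` (default: the fit
    selection).  Selections are index arrays into both coordinate sets.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    fit = np.arange(len(P)) if fit_selection is None else np.asarray(fit_selection)
    meas = fit if measure_selection is None else np.asarray(measure_selection)
    if len(fit) == 0 or len(meas) == 0:
        raise ValueError("empty selection")
    R, pc, qc = kabsch_rotation(P[fit], Q[fit])
    moved = (P[meas] - pc) @ R.T + qc
    diff = moved - Q[meas]
    return float(np.sqrt((diff * diff).sum() / len(meas)))


def rmsd_series(
    traj: Sequence[Structure],
    selection: Sequence[int] | None = None,
    reference: int | Structure = 0,
    label: str = "custom",
) -> RMSDSeries:
    """Per-frame RMSD of a trajectory against a reference frame/structure."""
    if not traj:
        raise ValueError("empty trajectory")
    ref = traj[reference] if isinstance(reference, int) else reference
    ref_coords = ref.coords
    values = np.array([
        kabsch_rmsd(frame.coords, ref_coords, fit_selection=selection)
        for frame in traj
    ])
    return RMSDSeries(label, values)


def _atom_index(frame: Structure, sel: AtomSel, frame_no: int,
                cache: dict[AtomSel, int]) -> int:
    idx = cache.get(sel)
    if idx is None:
        try:
            idx = frame.index_of(*sel)
        except KeyError:
            raise KeyError(f"frame {frame_no}: atom {sel} not found") from None
        cache[sel] = idx
    return idx


def monitor(traj: Sequence[Structure], monitors: Sequence[MonitorSpec]) -> list[DistanceMonitor]:
    """Track labelled atom-pair (or min-over-set) distances over a trajectory."""
    if not traj:
        raise ValueError("empty trajectory")
    out = []
    for spec in monitors:
        cache: dict[AtomSel, int] = {}
        members = {f"{c}:{r}:{n}": [] for c, r, n in spec.to_sels}
        mins: list[float] = []
        for f, frame in enumerate(traj):
            coords = frame.coords
            a = coords[_atom_index(frame, spec.from_sel, f, cache)]
            ds = []
            for sel in spec.to_sels:
                d = float(np.linalg.norm(a - coords[_atom_index(frame, sel, f, cache)]))
                members[f"{sel[0]}:{sel[1]}:{sel[2]}"].append(d)
                ds.append(d)
            mins.append(min(ds))
        out.append(DistanceMonitor(
            spec.label,
            np.asarray(mins),
            {name: np.asarray(vals) for name, vals in members.items()},
        ))
    return out


def load_monitor_specs(path: str | Path) -> list[MonitorSpec]:
    """Read monitor specs from JSON: [{label, from: [chain,resid,name], to: [...]}]."""
    import json

    def as_sel(v) -> AtomSel:
        return (str(v[0]), int(v[1]), str(v[2]))

    payload = json.loads(Path(path).read_text())
    specs = []
    for item in payload:
        to = item["to"]
        if to and not isinstance(to[0], (list, tuple)):
            to = [to]
        specs.append(MonitorSpec(item["label"], as_sel(item["from"]),
                                 [as_sel(t) for t in to]))
    return specs


def write_monitor_tsv(monitors: Sequence[DistanceMonitor], outdir: str | Path) -> None:
    """One TSV per monitor (frame, min, members...) plus a summary file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "summary.tsv", "w") as summary:
        summary.write("label\tmean\tsd\tmember\tmember_mean\n")
        for mon in monitors:
            safe = mon.label.replace("/", "_").replace(" ", "_")
            with open(outdir / f"{safe}.tsv", "w") as fh:
                names = list(mon.member_distances)
                fh.write("frame\tmin\t" + "\t".join(names) + "\n")
                for f in range(len(mon.distances)):
                    row = [str(f), f"{mon.distances[f]:.4f}"]
                    row += [f"{mon.member_distances[n][f]:.4f}" for n in names]
                    fh.write("\t".join(row) + "\n")
            if names:
                for n, m in mon.member_means().items():
                    summary.write(f"{mon.label}\t{mon.mean:.4f}\t{mon.sd:.4f}\t{n}\t{m:.4f}\n")
            else:
                summary.write(f"{mon.label}\t{mon.mean:.4f}\t{mon.sd:.4f}\t\t\n")
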