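"""The ΔΔE ledger: barrier arithmetic on wild-type / per-deletion energy tables.

Given single-point state energies for the intact model and for every residue
deletion (from real QM/MM runs, exported to CSV, or from the surrogate scan),
the ledger computes

    ΔE_wt = (E_TS − E_R)_wt,   ΔE_m = (E_TS_del − E_R_del)_m,
    ΔΔE_m−wt = ΔE_m − ΔE_wt

and classifies each residue as anticatalytic (ΔΔE < −threshold),
procatalytic (ΔΔE > +threshold) or neutral.  No zero-point, thermal or
entropic corrections are applied; the ledger works on raw electronic
energies.  Energies may be supplied in hartree or kcal/mol (or any unit with
an explicit scale factor to kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .electro import DeletionResult, classify_effect
from .structio import ResidueKey

__all__ = [
    "HARTREE_TO_KCAL",
    "EnergyTable",
    "compute_barriers",
    "read_energy_csv",
    "write_energy_csv",
    "scan_to_energy_table",
]

HARTREE_TO_KCAL = 627.509474

_UNIT_SCALES = {
    "kcal/mol": 1.0,
    "kcal": 1.0,
    "hartree": HARTREE_TO_KCAL,
}


@dataclass
class EnergyTable:
    """Wild-type and per-deletion state energies feeding the ledger."""

    wt_E_R: float
    wt_E_TS: float
    rows: list[tuple[ResidueKey, float, float]]  # (key, E_R_del, E_TS_del)
    unit: str = "kcal/mol"
    scale_to_kcal: float | None = None  # overrides the unit lookup if given

    def __post_init__(self) -> None:
        keys = [k for k, _, _ in self.rows]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate residue keys in energy table")
        energies = [self.wt_E_R, self.wt_E_TS] + [e for _, er, ets in self.rows for e in (er, ets)]
        if not np.all(np.isfinite(energies)):
            raise ValueError("non-finite energy in table")

    @property
    def scale(self) -> float:
        if self.scale_to_kcal is not None:
            s = self.scale_to_kcal
        else:
            try:
                s = _UNIT_SCALES[self.unit.lower()]
            except KeyError:
                raise ValueError(f"unknown energy unit {self.unit!r}; "
                                 "pass scale_to_kcal explicitly") from None
        if s <= 0:
            raise ValueError("unit scale factor must be positive")
        return s


def compute_barriers(table: EnergyTable, threshold: float = 1.0) -> list[DeletionResult]:
    """Apply the ledger arithmetic to an energy table.

    Returns one DeletionResult per deletion row, in ascending ΔΔE order
    (ties broken by residue key), all energies in kcal/mol.  V_R/V_TS are
    reported as the interaction energies the deletion removed,
    V_X = E_X_wt − E_X_del (zero when state energies equal the wild type).
    """
    s = table.scale
    dE_wt = (table.wt_E_TS - table.wt_E_R) * s
    results = []
    for key, e_r_del, e_ts_del in table.rows:
        dE_m = (e_ts_del * s) - (e_r_del * s)
        ddE = dE_m - dE_wt
        v_r = (table.wt_E_R - e_r_del) * s
        v_ts = (table.wt_E_TS - e_ts_del) * s
        results.append(DeletionResult(key, v_r, v_ts, dE_m, ddE,
                                      classify_effect(ddE, threshold)))
    return sorted(results, key=lambda r: (r.ddE, r.residue_key))


def scan_to_energy_table(results: Sequence[DeletionResult], dE_wt: float) -> EnergyTable:
    """Express a surrogate scan as an EnergyTable (kcal/mol).

    State energies are taken relative to the intact model: the wild type is
    (0, dE_wt) and deleting residue m removes its interaction energy from
    each state, giving (−V_R, dE_wt − V_TS).  Running the result through
    :func:`compute_barriers` reproduces the scan exactly.
    """
    rows = [(r.residue_key, -r.V_R, dE_wt - r.V_TS) for r in results]
    return EnergyTable(0.0, dE_wt, rows, unit="kcal/mol")


# ---------------------------------------------------------------------------
# CSV I/O:  kind,chain,resid,resname,E_R,E_TS
# ---------------------------------------------------------------------------

def read_energy_csv(path: str | Path, unit: str = "kcal/mol",
                    scale_to_kcal: float | None = None) -> EnergyTable:
    """Read an energy table CSV with one ``wildtype`` row and ``deletion`` rows."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"kind", "resid", "E_R", "E_TS"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: energy CSV must have columns {sorted(required)}")
    wt = df[df["kind"] == "wildtype"]
    if len(wt) != 1:
        raise ValueError(f"{path}: expected exactly one wildtype row, found {len(wt)}")
    rows = []
    for rec in df[df["kind"] == "deletion"].itertuples():
        chain = "" if pd.isna(getattr(rec, "chain", "")) else str(getattr(rec, "chain", ""))
        resname = "" if pd.isna(getattr(rec, "resname", "")) else str(getattr(rec, "resname", ""))
        rows.append(((chain, int(rec.resid), resname), float(rec.E_R), float(rec.E_TS)))
    return EnergyTable(float(wt["E_R"].iloc[0]), float(wt["E_TS"].iloc[0]),
                       rows, unit=unit, scale_to_kcal=scale_to_kcal)


def write_energy_csv(table: EnergyTable, path: str | Path,
                     header: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("kind,chain,resid,resname,E_R,E_TS\n")
        fh.write(f"wildtype,,0,,{table.wt_E_R!r},{table.wt_E_TS!r}\n")
        for (chain, resid, resname), e_r, e_ts in table.rows:
            fh.write(f"deletion,{chain},{resid},{resname},{e_r!r},{e_ts!r}\n")
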