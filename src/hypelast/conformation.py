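"""Backbone and proline-ring conformational analysis.

The pyrrolidine ring of proline and its 4-substituted derivatives
(hydroxyproline, methoxyproline) interconverts between two puckers,
C-gamma-endo and C-gamma-exo, distinguished here by the signs of the
side-chain dihedrals chi1 = (N, CA, CB, CG) and chi2 = (CA, CB, CG, CD):
endo has chi1 > 0 and chi2 < 0, exo has chi1 < 0 and chi2 > 0.  The
peptide-bond isomer is read from omega = (CA_{i-1}, C_{i-1}, N_i, CA_i):
near 0 deg is cis, near +/-180 deg is trans, with a hard boundary at
|omega| = 90 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import dihedral as _dihedral
from .trajectory_io import Trajectory

__all__ = [
    "PuckerRecord",
    "dihedral",
    "classify_pucker",
    "classify_isomer",
    "residue_dihedrals",
    "pucker_timeseries",
    "occupancy",
    "ramachandran",
    "distance_map",
    "StructureError",
]

dihedral = _dihedral

RING_RESNAMES = {"PRO", "HYP", "MOP"}


class StructureError(ValueError):
    """Missing atoms for a dihedral or ring classification."""


def classify_pucker(chi1: float, chi2: float) -> str:
    """'endo' iff chi1 > 0 and chi2 < 0; 'exo' iff chi1 < 0 and chi2 > 0;
    any other sign pattern (including exact zeros) is 'other'."""
    if chi1 > 0 and chi2 < 0:
        return "endo"
    if chi1 < 0 and chi2 > 0:
        return "exo"
    return "other"


def classify_isomer(omega: float, boundary: float = 90.0) -> str:
    """'cis' iff |omega| < boundary (default 90 deg), else 'trans'."""
    return "cis" if abs(omega) < boundary else "trans"


@dataclass(frozen=True)
class PuckerRecord:
    frame_index: int
    residue_position: int
    chi1: float
    chi2: float
    omega: float | None
    phi: float | None
    psi: float | None
    pucker: str
    isomer: str | None


def _atom_index(atoms: pd.DataFrame, respos: int, name: str) -> int | None:
    idx = atoms.index[(atoms["respos"] == respos) & (atoms["name"] == name)]
    return int(idx[0]) if len(idx) else None


def _require(atoms, respos, name) -> int:
    i = _atom_index(atoms, respos, name)
    if i is None:
        raise StructureError(f"residue {respos}: missing atom {name}")
    return i


def residue_dihedrals(traj: Trajectory, respos: int):
    """Index tuples for chi1/chi2/omega/phi/psi of one residue (None where a
    neighbour is absent)."""
    atoms = traj.atoms
    n = _require(atoms, respos, "N")
    ca = _require(atoms, respos, "CA")
    cb = _atom_index(atoms, respos, "CB")
    cg = _atom_index(atoms, respos, "CG")
    cd = _atom_index(atoms, respos, "CD")
    c = _atom_index(atoms, respos, "C")
    ca_prev = _atom_index(atoms, respos - 1, "CA")
    c_prev = _atom_index(atoms, respos - 1, "C")
    n_next = _atom_index(atoms, respos + 1, "N")
    chi1 = (n, ca, cb, cg) if cb is not None and cg is not None else None
    chi2 = (ca, cb, cg, cd) if chi1 is not None and cd is not None else None
    omega = (ca_prev, c_prev, n, ca) if ca_prev is not None and c_prev is not None else None
    phi = (c_prev, n, ca, c) if c_prev is not None and c is not None else None
    psi = (n, ca, c, n_next) if c is not None and n_next is not None else None
    return {"chi1": chi1, "chi2": chi2, "omega": omega, "phi": phi, "psi": psi}


def pucker_timeseries(traj: Trajectory, residue_positions) -> list[PuckerRecord]:
    """Per-frame chi1/chi2/omega/phi/psi and pucker/isomer state for ring
    residues (Pro/Hyp/Mop)."""
    atoms = traj.atoms
    records: list[PuckerRecord] = []
    specs = {}
    for respos in residue_positions:
        resnames = set(atoms.loc[atoms["respos"] == respos, "resname"])
        if not resnames:
            raise StructureError(f"no residue at position {respos}")
        if not resnames & RING_RESNAMES:
            raise StructureError(
                f"residue {respos} ({sorted(resnames)}) is not a ring residue"
            )
        spec = residue_dihedrals(traj, respos)
        if spec["chi1"] is None or spec["chi2"] is None:
            raise StructureError(f"residue {respos}: ring atoms missing")
        specs[respos] = spec

    def ang(coords, quad):
        if quad is None:
            return None
        return _dihedral(*(coords[i] for i in quad))

    for fi, frame in enumerate(traj.frames):
        c = frame.coordinates
        for respos, spec in specs.items():
            chi1 = ang(c, spec["chi1"])
            chi2 = ang(c, spec["chi2"])
            omega = ang(c, spec["omega"])
            records.append(
                PuckerRecord(
                    frame_index=fi,
                    residue_position=respos,
                    chi1=chi1,
                    chi2=chi2,
                    omega=omega,
                    phi=ang(c, spec["phi"]),
                    psi=ang(c, spec["psi"]),
                    pucker=classify_pucker(chi1, chi2),
                    isomer=None if omega is None else classify_isomer(omega),
                )
            )
    return records


def occupancy(records: list[PuckerRecord], field: str = "pucker") -> dict[int, dict[str, float]]:
    """Percent of frames per state per residue; sums to 100 per residue."""
    by_res: dict[int, dict[str, int]] = {}
    for r in records:
        state = getattr(r, field)
        if state is None:
            continue
        by_res.setdefault(r.residue_position, {}).setdefault(state, 0)
        by_res[r.residue_position][state] += 1
    out = {}
    for respos, counts in by_res.items():
        total = sum(counts.values())
        out[respos] = {s: 100.0 * c / total for s, c in counts.items()}
    return out


def ramachandran(traj: Trajectory, residue_positions, bin_width: float = 10.0):
    """2D (phi, psi) histogram over frames and residues.

    Bin edges sit at multiples of ``bin_width`` spanning (-180, 180].
    Residues missing a phi or psi neighbour are skipped and counted in the
    returned ``skipped`` tally.  Returns ``(hist, edges, skipped)``.
    """
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    hist = np.zeros((len(edges) - 1, len(edges) - 1))
    skipped = 0
    specs = {}
    for respos in residue_positions:
        spec = residue_dihedrals(traj, respos)
        if spec["phi"] is None or spec["psi"] is None:
            skipped += 1
            continue
        specs[respos] = spec
    for frame in traj.frames:
        c = frame.coordinates
        for spec in specs.values():
            phi = _dihedral(*(c[i] for i in spec["phi"]))
            psi = _dihedral(*(c[i] for i in spec["psi"]))
            i = min(int((phi + 180.0) // bin_width), hist.shape[0] - 1)
            j = min(int((psi + 180.0) // bin_width), hist.shape[1] - 1)
            hist[i, j] += 1
    return hist, edges, skipped


def distance_map(
    traj: Trajectory, residue_positions=None, atom_name: str = "CA"
) -> tuple[np.ndarray, list[int]]:
    """Mean inter-residue distance matrix (Angstrom) over frames, using one
    named atom per residue (default C-alpha).  Symmetric, zero diagonal."""
    atoms = traj.atoms
    if residue_positions is None:
        prot = atoms[~atoms["is_water"]]
        residue_positions = sorted(set(prot["respos"]))
    idx = []
    for respos in residue_positions:
        i = _atom_index(atoms, respos, atom_name)
        if i is None:
            raise StructureError(f"residue {respos}: no atom {atom_name}")
        idx.append(i)
    idx = np.asarray(idx)
    acc = np.zeros((len(idx), len(idx)))
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    for frame in traj.frames:
        c = frame.coordinates[idx]
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        acc += d
    return acc / traj.n_frames, list(residue_positions)
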