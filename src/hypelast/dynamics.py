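"""Superposition, RMSD/RMSF, convergence series, and fluctuation summaries
at annotated site sets (protease target sites, cross-linking lysines)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import kabsch
from .trajectory_io import Trajectory, select

__all__ = [
    "SiteSet",
    "RmsfProfile",
    "superpose",
    "rmsf",
    "site_rmsf",
    "rmsd_series",
    "read_site_sets",
    "write_site_sets",
]


@dataclass(frozen=True)
class SiteSet:
    """Named set of residue positions (e.g. elastase cleavage sites or
    cross-linking lysines)."""

    name: str
    positions: frozenset

    def __post_init__(self):
        object.__setattr__(self, "positions", frozenset(int(p) for p in self.positions))
        if not self.positions:
            raise ValueError("a site set needs at least one position")


def read_site_sets(path) -> dict[str, SiteSet]:
    """Read site sets from a two-column TSV: name <tab> comma-list."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, positions = line.rstrip("\n").split("\t")
            out[name] = SiteSet(name, frozenset(int(p) for p in positions.split(",")))
    return out


def write_site_sets(sets, path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write(f"{s.name}\t{','.join(str(p) for p in sorted(s.positions))}\n")


def superpose(mobile: np.ndarray, reference: np.ndarray, selection=None):
    """Optimal proper-rotation superposition of ``mobile`` onto
    ``reference`` fitted on ``selection`` (index array; default all atoms).

    Returns ``(rotation, translation, rmsd)``; the rmsd is over the fit
    selection.
    """
    if selection is None:
        selection = np.arange(len(mobile))
    selection = np.asarray(selection)
    return kabsch(mobile[selection], reference[selection])


@dataclass
class RmsfProfile:
    """Per-residue root-mean-square fluctuation about the mean structure."""

    residue_positions: list
    values: np.ndarray  # Angstrom
    fit_selection: str | None
    per_atom: pd.DataFrame  # columns: atom index, respos, rmsf


def _fitted_coords(coords: np.ndarray, fit_idx: np.ndarray | None, n_iter: int = 2):
    """Superpose every frame onto the mean structure, iterating fit ->
    recompute mean -> refit ``n_iter`` times.  No-op when fit_idx is None."""
    if fit_idx is None:
        return coords
    out = coords.copy()
    for _ in range(n_iter):
        mean = out.mean(axis=0)
        for f in range(out.shape[0]):
            rot, t, _ = kabsch(out[f][fit_idx], mean[fit_idx])
            out[f] = out[f] @ rot.T + t
    return out


def rmsf(
    traj: Trajectory,
    selection: str | np.ndarray = "protein and not element H",
    fit_selection: str | np.ndarray | None = "backbone",
) -> RmsfProfile:
    """RMSF_i = sqrt(<|r_i - <r_i>|^2>) after iterated superposition onto
    the mean structure; residue values are unweighted means over the
    residue's selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    atoms = traj.atoms
    sel_idx = select(traj, selection) if isinstance(selection, str) else np.asarray(selection)
    if fit_selection is None:
        fit_idx = None
    elif isinstance(fit_selection, str):
        fit_idx = select(traj, fit_selection)
        if len(fit_idx) < 3:
            fit_idx = sel_idx
    else:
        fit_idx = np.asarray(fit_selection)
    coords = _fitted_coords(traj.coordinates(), fit_idx)
    sub = coords[:, sel_idx, :]
    mean = sub.mean(axis=0)
    per_atom_rmsf = np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))
    per_atom = pd.DataFrame(
        {
            "atom": sel_idx,
            "respos": atoms["respos"].to_numpy()[sel_idx],
            "rmsf": per_atom_rmsf,
        }
    )
    by_res = per_atom.groupby("respos")["rmsf"].mean()
    return RmsfProfile(
        residue_positions=[int(p) for p in by_res.index],
        values=by_res.to_numpy(),
        fit_selection=fit_selection if isinstance(fit_selection, str) else None,
        per_atom=per_atom,
    )


def site_rmsf(profile: RmsfProfile, sites: SiteSet) -> tuple[float, float]:
    """Arithmetic mean (and SD across sites) of the RMSF at the listed
    residue positions."""
    lookup = dict(zip(profile.residue_positions, profile.values))
    missing = [p for p in sites.positions if p not in lookup]
    if missing:
        raise ValueError(f"sites absent from profile: {sorted(missing)}")
    vals = np.array([lookup[p] for p in sorted(sites.positions)])
    return float(np.mean(vals)), float(np.std(vals))


def replicate_site_rmsf(trajectories, sites: SiteSet, **rmsf_kwargs):
    """Per-replicate site-mean RMSF values (replicates are the statistical
    unit: RMSF is computed per replicate, then summarized)."""
    means = []
    for t in trajectories:
        profile = rmsf(t, **rmsf_kwargs)
        means.append(site_rmsf(profile, sites)[0])
    means = np.array(means)
    return means, float(np.mean(means)), float(np.std(means, ddof=1) if len(means) > 1 else 0.0)


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    selection: str | np.ndarray = "backbone",
):
    """Per-frame superposed RMSD against a reference (default first frame)
    plus a plateau statistic: the SD of the last-half values.

    Returns ``(series, plateau_sd)``.
    """
    sel_idx = select(traj, selection) if isinstance(selection, str) else np.asarray(selection)
    if len(sel_idx) == 0:
        sel_idx = np.arange(traj.n_atoms)
    ref = traj.frames[0].coordinates if reference is None else np.asarray(reference)
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        _, _, out[i] = kabsch(frame.coordinates[sel_idx], ref[sel_idx])
    half = out[len(out) // 2 :]
    return out, float(np.std(half))
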