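"""Lysine-lysine spatial proximity: mean distance contact maps, cutoff-sweep
contact counts, and replicate-level significance between models.

Cross-links between lysines form through lysyl-oxidase chemistry when the
reactive side-chain amines come close enough; a sweep of cutoff distances
(default 16-30 A in 2 A steps) counts, per frame, the lysine pairs whose
instantaneous N-zeta--N-zeta distance falls within each cutoff.  Model
comparisons use replicate means as the statistical unit (frames are
autocorrelated) with a two-sided Welch t-test and the conventional star
notation (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import minimum_image
from .trajectory_io import Trajectory

__all__ = [
    "ContactSweep",
    "ModelComparison",
    "DEFAULT_CUTOFFS",
    "lysine_map",
    "contact_sweep",
    "compare_models",
    "significance_stars",
]

DEFAULT_CUTOFFS = tuple(float(c) for c in range(16, 31, 2))


def significance_stars(p: float) -> str:
    """Star notation: p<0.05 -> '*', p<0.01 -> '**', p<0.001 -> '***'
    (strict inequalities), else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _lysine_atom_indices(traj: Trajectory, lysine_positions, atom_name: str = "NZ"):
    atoms = traj.atoms
    idx = []
    for respos in sorted(lysine_positions):
        rows = atoms.index[atoms["respos"] == respos]
        if len(rows) == 0:
            raise ValueError(f"no residue at position {respos}")
        resname = atoms.loc[rows[0], "resname"]
        if resname != "LYS":
            raise ValueError(f"residue {respos} is {resname}, not LYS")
        hit = atoms.index[(atoms["respos"] == respos) & (atoms["name"] == atom_name)]
        if len(hit) != 1:
            raise ValueError(f"residue {respos}: expected one {atom_name} atom")
        idx.append(int(hit[0]))
    return np.asarray(idx), sorted(lysine_positions)


def _frame_distances(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    """(n_frames, n_lys, n_lys) minimum-image distance stack."""
    out = np.empty((traj.n_frames, len(idx), len(idx)))
    for fi, frame in enumerate(traj.frames):
        c = frame.coordinates[idx]
        d = minimum_image(c[:, None, :] - c[None, :, :], frame.box)
        out[fi] = np.linalg.norm(d, axis=-1)
    return out


def lysine_map(traj: Trajectory, lysine_positions, atom_name: str = "NZ"):
    """Mean pairwise lysine distance matrix (Angstrom, side-chain N-zeta by
    default) over frames.  Returns ``(matrix, positions)``."""
    idx, positions = _lysine_atom_indices(traj, lysine_positions, atom_name)
    if len(idx) < 2:
        raise ValueError("need at least two lysines")
    return _frame_distances(traj, idx).mean(axis=0), positions


@dataclass
class ContactSweep:
    """Per-cutoff per-frame counts of lysine pairs within the cutoff."""

    cutoffs: np.ndarray
    per_frame_counts: np.ndarray  # (n_cutoffs, n_frames)
    replicate_id: int = 0
    mean_counts: np.ndarray = field(init=False)

    def __post_init__(self):
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.per_frame_counts = np.asarray(self.per_frame_counts)
        self.mean_counts = self.per_frame_counts.mean(axis=1)


def contact_sweep(
    traj: Trajectory,
    lysine_positions,
    cutoffs=DEFAULT_CUTOFFS,
    atom_name: str = "NZ",
) -> ContactSweep:
    """Count, per frame and per cutoff, the lysine pairs whose instantaneous
    distance is within the cutoff (counts are non-decreasing in cutoff)."""
    idx, _ = _lysine_atom_indices(traj, lysine_positions, atom_name)
    if len(idx) < 2:
        raise ValueError("need at least two lysines")
    d = _frame_distances(traj, idx)
    iu = np.triu_indices(len(idx), k=1)
    pair_d = d[:, iu[0], iu[1]]  # (n_frames, n_pairs)
    cutoffs = np.asarray(cutoffs, dtype=float)
    counts = (pair_d[None, :, :] <= cutoffs[:, None, None]).sum(axis=2)
    return ContactSweep(cutoffs=cutoffs, per_frame_counts=counts, replicate_id=traj.replicate_id)


@dataclass
class ModelComparison:
    model_a: str
    model_b: str
    cutoffs: np.ndarray
    p_values: np.ndarray
    stars: list
    direction: list  # 'decrease' | 'increase' | 'none' (B relative to A)


def compare_models(
    sweeps_a, sweeps_b, model_a: str = "A", model_b: str = "B"
) -> ModelComparison:
    """Two-sided Welch t-test per cutoff on replicate-level mean counts.

    ``sweeps_a``/``sweeps_b`` are lists of :class:`ContactSweep`, one per
    replicate, on identical cutoff grids.
    """
    sweeps_a, sweeps_b = list(sweeps_a), list(sweeps_b)
    if len(sweeps_a) < 2 or len(sweeps_b) < 2:
        raise ValueError("need at least two replicates per model")
    cutoffs = sweeps_a[0].cutoffs
    for s in sweeps_a + sweeps_b:
        if not np.array_equal(s.cutoffs, cutoffs):
            raise ValueError("replicate sweeps use different cutoff grids")
    a = np.stack([s.mean_counts for s in sweeps_a])  # (n_rep, n_cut)
    b = np.stack([s.mean_counts for s in sweeps_b])
    p_values = np.empty(len(cutoffs))
    direction = []
    for ci in range(len(cutoffs)):
        if np.allclose(a[:, ci], b[:, ci]) and np.ptp(a[:, ci]) == 0 and np.ptp(b[:, ci]) == 0:
            p_values[ci] = 1.0
        else:
            p_values[ci] = stats.ttest_ind(a[:, ci], b[:, ci], equal_var=False).pvalue
            if np.isnan(p_values[ci]):
                p_values[ci] = 1.0
        diff = b[:, ci].mean() - a[:, ci].mean()
        direction.append("none" if diff == 0 else ("increase" if diff > 0 else "decrease"))
    stars = [significance_stars(p) for p in p_values]
    return ModelComparison(
        model_a=model_a,
        model_b=model_b,
        cutoffs=cutoffs,
        p_values=p_values,
        stars=stars,
        direction=direction,
    )
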