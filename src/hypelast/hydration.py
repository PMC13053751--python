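"""Protein-water structure: radial distribution functions, hydrogen bonds,
three-layer hydration classification, local/global hydration counts, and
short-range protein-solvent interaction energy.

Hydration layers follow the radial-distribution-function picture of water
around a peptide: a first hydrophilic layer at contact distances up to
~2 A (hydrogen-bonded water, H-to-acceptor distance), a second hydrophilic
layer up to 3.2 A, and a third, hydrophobic layer up to ~4 A of water
sitting near carbon/sulfur without a protein-water hydrogen bond.  Water
beyond these shells is bulk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import minimum_image, pair_distances
from .trajectory_io import Frame, Trajectory, select

__all__ = [
    "HBond",
    "WaterLabel",
    "HydrationSummary",
    "RdfTable",
    "TypingError",
    "COULOMB_CONSTANT",
    "detect_hbonds",
    "count_hbonds",
    "classify_waters",
    "hydration_counts",
    "interaction_energy",
    "rdf",
]

#: Coulomb prefactor 138.935485 kJ/mol nm e^-2, expressed per Angstrom
COULOMB_CONSTANT = 1389.35485

_HBOND_DCUT = 3.5  # donor-acceptor distance cutoff, Angstrom
_HBOND_ANGLE = 150.0  # donor-H...acceptor angle cutoff, degrees
_XH_BOND = 1.25  # covalent X-H assignment distance, Angstrom


class TypingError(ValueError):
    """Missing atom typing information (H connectivity, charges, LJ)."""


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # donor-acceptor, Angstrom
    angle: float  # donor-H...acceptor, degrees


@dataclass(frozen=True)
class WaterLabel:
    water_respos: int
    frame_index: int
    label: str  # hydrophilic_L1 | hydrophilic_L2 | hydrophilic_beyond_L2
    #          | hydrophobic_L3 | bulk
    anchor: int | None
    anchor_distance: float


def _donor_hydrogen_pairs(coords: np.ndarray, atoms: pd.DataFrame, box):
    """Assign each hydrogen to its covalently bonded heavy atom (nearest
    heavy atom within 1.25 A); return (donor, hydrogen) index pairs whose
    donor is O or N."""
    h_idx = np.flatnonzero((atoms["element"] == "H").to_numpy())
    heavy_idx = np.flatnonzero((atoms["element"] != "H").to_numpy())
    if len(h_idx) == 0 or len(heavy_idx) == 0:
        return np.empty((0, 2), dtype=int)
    d = pair_distances(coords[h_idx], coords[heavy_idx], box)
    nearest = np.argmin(d, axis=1)
    dist = d[np.arange(len(h_idx)), nearest]
    if np.any(dist > 1.6):
        bad = h_idx[dist > 1.6]
        raise TypingError(
            f"hydrogens with no covalent heavy-atom partner: {bad.tolist()[:5]}"
        )
    partner = heavy_idx[nearest]
    bonded = dist <= _XH_BOND
    elements = atoms["element"].to_numpy()
    keep = bonded & np.isin(elements[partner], ["O", "N"])
    return np.column_stack([partner[keep], h_idx[keep]])


def detect_hbonds(
    frame: Frame,
    atoms: pd.DataFrame,
    d_cut: float = _HBOND_DCUT,
    angle_cut: float = _HBOND_ANGLE,
) -> list[HBond]:
    """Geometric hydrogen bonds: every (donor, H, acceptor) triple with O/N
    donor and acceptor, donor-acceptor distance <= ``d_cut`` and
    donor-H...acceptor angle >= ``angle_cut`` under the minimum image."""
    coords = frame.coordinates
    box = frame.box
    dh = _donor_hydrogen_pairs(coords, atoms, box)
    if len(dh) == 0:
        return []
    acceptors = np.flatnonzero(atoms["element"].isin(["O", "N"]).to_numpy())
    don, hyd = dh[:, 0], dh[:, 1]
    dda = pair_distances(coords[don], coords[acceptors], box)  # (n_dh, n_acc)
    within = dda <= d_cut
    # exclude acceptor == donor
    within &= acceptors[None, :] != don[:, None]
    out: list[HBond] = []
    pair_i, pair_j = np.nonzero(within)
    if len(pair_i) == 0:
        return out
    hv = minimum_image(coords[don[pair_i]] - coords[hyd[pair_i]], box)
    av = minimum_image(coords[acceptors[pair_j]] - coords[hyd[pair_i]], box)
    cosang = np.einsum("ij,ij->i", hv, av) / (
        np.linalg.norm(hv, axis=1) * np.linalg.norm(av, axis=1)
    )
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = ang >= angle_cut
    for k in np.flatnonzero(ok):
        out.append(
            HBond(
                donor=int(don[pair_i[k]]),
                hydrogen=int(hyd[pair_i[k]]),
                acceptor=int(acceptors[pair_j[k]]),
                distance=float(dda[pair_i[k], pair_j[k]]),
                angle=float(ang[k]),
            )
        )
    return out


def count_hbonds(
    traj: Trajectory,
    selection: str | np.ndarray,
    d_cut: float = _HBOND_DCUT,
    angle_cut: float = _HBOND_ANGLE,
):
    """Per-frame protein-water hydrogen-bond counts for a protein selection.

    A bond is counted when one partner (donor or acceptor) lies in the
    selection (a protein sub-selection) and the other on a water molecule.
    Returns ``(counts, mean, sd)``.
    """
    atoms = traj.atoms
    sel_idx = select(traj, selection) if isinstance(selection, str) else np.asarray(selection)
    if len(sel_idx) == 0:
        raise ValueError("selection resolves to no atoms")
    in_sel = np.zeros(len(atoms), dtype=bool)
    in_sel[sel_idx] = True
    is_water = atoms["is_water"].to_numpy()
    counts = np.zeros(traj.n_frames)
    for fi, frame in enumerate(traj.frames):
        n = 0
        for hb in detect_hbonds(frame, atoms, d_cut, angle_cut):
            protein_side = [i for i in (hb.donor, hb.acceptor) if in_sel[i] and not is_water[i]]
            water_side = [i for i in (hb.donor, hb.acceptor) if is_water[i]]
            if protein_side and water_side:
                n += 1
        counts[fi] = n
    return counts, float(np.mean(counts)), float(np.std(counts))


def classify_waters(
    frame: Frame,
    atoms: pd.DataFrame,
    l1: float = 2.0,
    l2: float = 3.2,
    l3: float = 4.0,
    frame_index: int = 0,
    d_cut: float = _HBOND_DCUT,
    angle_cut: float = _HBOND_ANGLE,
) -> list[WaterLabel]:
    """Label every water molecule in one frame.

    hydrophilic_L1/L2: the water forms a protein-water hydrogen bond and
    its closest H-to-acceptor contact distance (water H to protein
    acceptor, or protein H to water oxygen) is <= l1 / <= l2.  Hydrogen-
    bonded water with a larger contact distance is kept as
    'hydrophilic_beyond_L2' rather than silently dropped.
    hydrophobic_L3: no protein hydrogen bond, and the water oxygen lies
    within l3 of a protein carbon/sulfur.  Everything else is bulk.
    """
    coords = frame.coordinates
    box = frame.box
    is_water = atoms["is_water"].to_numpy()
    respos = atoms["respos"].to_numpy()
    elements = atoms["element"].to_numpy()
    water_residues = sorted(set(respos[is_water]))
    if not water_residues:
        return []

    # contact distances per water from protein-water H-bonds
    contact: dict[int, tuple[float, int]] = {}
    for hb in detect_hbonds(frame, atoms, d_cut, angle_cut):
        dw, aw = is_water[hb.donor], is_water[hb.acceptor]
        if dw == aw:  # water-water or protein-protein
            continue
        if dw:  # water donates: contact = water H ... protein acceptor
            wres = respos[hb.donor]
            h, partner = hb.hydrogen, hb.acceptor
        else:  # protein donates: contact = protein H ... water oxygen
            wres = respos[hb.acceptor]
            h, partner = hb.hydrogen, hb.acceptor
            # contact distance is H...acceptor either way
        v = minimum_image(coords[partner] - coords[h], box)
        d = float(np.linalg.norm(v))
        anchor = hb.acceptor if dw else hb.donor  # protein-side heavy atom
        if wres not in contact or d < contact[wres][0]:
            contact[int(wres)] = (d, int(anchor))

    # hydrophobic proximity: water oxygen to protein C/S
    cs_idx = np.flatnonzero(~is_water & np.isin(elements, ["C", "S"]))
    wo_idx = np.flatnonzero(is_water & (elements == "O"))
    wo_res = respos[wo_idx]
    if len(cs_idx) and len(wo_idx):
        dcs = pair_distances(coords[wo_idx], coords[cs_idx], box)
        nearest_cs = np.argmin(dcs, axis=1)
        dist_cs = dcs[np.arange(len(wo_idx)), nearest_cs]
    else:
        dist_cs = np.full(len(wo_idx), np.inf)
        nearest_cs = np.zeros(len(wo_idx), dtype=int)

    labels: list[WaterLabel] = []
    for k, wres in enumerate(wo_res):
        wres = int(wres)
        if wres in contact:
            d, anchor = contact[wres]
            if d <= l1:
                lab = "hydrophilic_L1"
            elif d <= l2:
                lab = "hydrophilic_L2"
            else:
                lab = "hydrophilic_beyond_L2"
            labels.append(WaterLabel(wres, frame_index, lab, anchor, d))
        elif dist_cs[k] <= l3:
            labels.append(
                WaterLabel(
                    wres, frame_index, "hydrophobic_L3",
                    int(cs_idx[nearest_cs[k]]), float(dist_cs[k]),
                )
            )
        else:
            labels.append(WaterLabel(wres, frame_index, "bulk", None, float(dist_cs[k])))
    return labels


@dataclass
class HydrationSummary:
    """Mean hydration-water counts for one scope (a residue or the whole
    protein), with per-frame arrays retained for dispersion estimates."""

    scope: str
    total: float
    hydrophilic: float
    hydrophobic: float
    sd_total: float
    per_frame_hydrophilic: np.ndarray
    per_frame_hydrophobic: np.ndarray
    overflow_beyond_l2: float = 0.0

    @property
    def per_frame_total(self) -> np.ndarray:
        return self.per_frame_hydrophilic + self.per_frame_hydrophobic


def hydration_counts(
    traj: Trajectory,
    scope: str = "global",
    selection: str | np.ndarray | None = None,
    l1: float = 2.0,
    l2: float = 3.2,
    l3: float = 4.0,
) -> HydrationSummary:
    """Count hydration waters whose anchor atom lies in the scope.

    scope='local' restricts anchors to ``selection`` (e.g. one residue);
    scope='global' counts waters anchored anywhere on the protein.  Total
    hydration is hydrophilic (layers 1-2) plus hydrophobic (layer 3);
    hydrogen-bonded water beyond layer 2 is reported separately.
    """
    atoms = traj.atoms
    if scope == "local":
        if selection is None:
            raise ValueError("local scope requires a selection")
        sel_idx = select(traj, selection) if isinstance(selection, str) else np.asarray(selection)
    elif scope == "global":
        sel_idx = np.flatnonzero(~atoms["is_water"].to_numpy())
    else:
        raise ValueError("scope must be 'local' or 'global'")
    in_scope = np.zeros(len(atoms), dtype=bool)
    in_scope[sel_idx] = True

    phil = np.zeros(traj.n_frames)
    phob = np.zeros(traj.n_frames)
    over = np.zeros(traj.n_frames)
    for fi, frame in enumerate(traj.frames):
        for wl in classify_waters(frame, atoms, l1, l2, l3, frame_index=fi):
            if wl.anchor is None or not in_scope[wl.anchor]:
                continue
            if wl.label in ("hydrophilic_L1", "hydrophilic_L2"):
                phil[fi] += 1
            elif wl.label == "hydrophobic_L3":
                phob[fi] += 1
            elif wl.label == "hydrophilic_beyond_L2":
                over[fi] += 1
    total = phil + phob
    return HydrationSummary(
        scope=scope,
        total=float(np.mean(total)),
        hydrophilic=float(np.mean(phil)),
        hydrophobic=float(np.mean(phob)),
        sd_total=float(np.std(total)),
        per_frame_hydrophilic=phil,
        per_frame_hydrophobic=phob,
        overflow_beyond_l2=float(np.mean(over)),
    )


def interaction_energy(
    frame: Frame, atoms: pd.DataFrame, cutoff: float = 12.0
) -> float:
    """Short-range protein-solvent interaction energy in kJ/mol.

    Sum over protein-water atom pairs within ``cutoff`` of the truncated
    Coulomb term f q_i q_j / r plus Lennard-Jones 4 eps [(sig/r)^12 -
    (sig/r)^6] with Lorentz-Berthelot combining, minimum-image distances.
    """
    if atoms["charge"].isna().any() or atoms["sigma"].isna().any():
        raise TypingError("missing charge/LJ parameters")
    is_water = atoms["is_water"].to_numpy()
    p_idx = np.flatnonzero(~is_water)
    w_idx = np.flatnonzero(is_water)
    if len(p_idx) == 0 or len(w_idx) == 0:
        return 0.0
    coords = frame.coordinates
    r = pair_distances(coords[p_idx], coords[w_idx], frame.box)
    mask = (r <= cutoff) & (r > 0)
    q = atoms["charge"].to_numpy()
    eps = atoms["epsilon"].to_numpy()
    sig = atoms["sigma"].to_numpy()
    qq = np.outer(q[p_idx], q[w_idx])
    eij = np.sqrt(np.outer(eps[p_idx], eps[w_idx]))
    sij = 0.5 * (sig[p_idx][:, None] + sig[w_idx][None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        coul = COULOMB_CONSTANT * qq / r
        sr6 = (sij / r) ** 6
        lj = 4.0 * eij * (sr6 * sr6 - sr6)
    return float(np.sum(np.where(mask, coul + lj, 0.0)))


@dataclass
class RdfTable:
    bin_centers: np.ndarray
    g: np.ndarray
    reference: str
    target: str

    def argmax_center(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.g))])


def rdf(
    traj: Trajectory,
    reference: str | np.ndarray,
    target: str | np.ndarray,
    bin_width: float = 0.1,
    r_max: float = 10.0,
) -> RdfTable:
    """Shell-volume-normalized pair distribution g(r) averaged over frames.

    The target density is taken as n_target / V_box, so a uniformly
    distributed target gives g -> 1 at large r.
    """
    ref_idx = select(traj, reference) if isinstance(reference, str) else np.asarray(reference)
    tgt_idx = select(traj, target) if isinstance(target, str) else np.asarray(target)
    if len(ref_idx) == 0 or len(tgt_idx) == 0:
        raise ValueError("empty selection")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    n_frames = traj.n_frames
    for frame in traj.frames:
        box = frame.box
        if box is not None and r_max > 0.5 * float(np.min(box)):
            raise ValueError("r_max exceeds half the smallest box edge")
        if box is None:
            raise ValueError("rdf requires a periodic box to define density")
        d = pair_distances(frame.coordinates[ref_idx], frame.coordinates[tgt_idx], box)
        # discard self pairs when selections overlap
        same = ref_idx[:, None] == tgt_idx[None, :]
        vals = d[~same]
        hist += np.histogram(vals, bins=edges)[0]
    box = traj.frames[0].box
    volume = float(np.prod(box))
    rho = len(tgt_idx) / volume
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = n_frames * len(ref_idx) * shell * rho
    g = hist / norm
    centers = 0.5 * (edges[1:] + edges[:-1])
    ref_name = reference if isinstance(reference, str) else "<indices>"
    tgt_name = target if isinstance(target, str) else "<indices>"
    return RdfTable(bin_centers=centers, g=g, reference=ref_name, target=tgt_name)
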