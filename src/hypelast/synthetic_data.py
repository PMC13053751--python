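"""Synthetic peptide-in-water trajectories with exactly known, planted
properties.

Every analysis stage in this package (hydration classification, hydrogen
bonding, ring pucker occupancies, RMSF, clustering, lysine contacts) can be
exercised against a trajectory whose ground truth is prescribed rather than
simulated: ideal-geometry peptides whose ring dihedrals are built to a
requested pucker state, water molecules placed in exact hydrogen-bonding
(or deliberately non-bonding) geometry in prescribed hydration layers,
Gaussian per-residue displacement noise of known amplitude, and lysine
pairs at prescribed separations.  The displacement noise is unphysical by
design: these fixtures validate estimators, not dynamics.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeometryError, place_atom
from .trajectory_io import Frame, Trajectory, make_atom_table

__all__ = [
    "SyntheticSpec",
    "make_peptide",
    "make_trajectory",
    "make_ensemble",
    "make_lysine_toy",
    "PUCKER_DIHEDRALS",
]

# chi1/chi2 targets used when building a ring to a requested pucker
PUCKER_DIHEDRALS = {"endo": (30.0, -35.0), "exo": (-30.0, 35.0)}

_PHI, _PSI = -70.0, 150.0  # extended/PPII-like backbone

# simple point charges (e) and LJ parameters (kJ/mol, Angstrom) by atom name
_CHARGES = {
    "N": -0.47, "H": 0.31, "CA": 0.07, "C": 0.51, "O": -0.51,
    "CB": -0.18, "CG": -0.18, "CD": 0.19, "HG1": 0.09, "HG2": 0.09,
    "NZ": -0.30, "OW": -0.834, "HW1": 0.417, "HW2": 0.417,
}
_LJ = {  # element -> (epsilon kJ/mol, sigma Angstrom)
    "C": (0.45, 3.40), "N": (0.70, 3.25), "O": (0.65, 3.02),
    "H": (0.00, 1.00), "S": (1.00, 3.60),
}

_WATER_OH = 0.957  # 3-site rigid water O-H bond, Angstrom
_WATER_ANGLE = 104.5


def _atom_params(name: str, element: str):
    q = _CHARGES.get(name, 0.0)
    eps, sig = _LJ.get(element, (0.3, 3.3))
    return q, eps, sig


def make_peptide(sequence: str, pucker=None, omega: float = 180.0):
    """Ideal-geometry peptide whose ring residues are built to requested
    pucker states.

    Parameters
    ----------
    sequence : one-letter codes; 'P' residues get a full pyrrolidine side
        chain (CB, CG, CD and both CG hydrogens).
    pucker : per-residue pucker request, mapping 1-based residue position
        to 'endo' or 'exo' (default 'exo' for every ring residue), or a
        single string applied to all rings.
    omega : peptide-bond dihedral applied at every junction (180 = trans,
        0 = cis).

    Returns a single-frame :class:`~hypelast.trajectory_io.Trajectory` with
    a filled parameter table.
    """
    if isinstance(pucker, str):
        pucker = {i + 1: pucker for i, c in enumerate(sequence) if c == "P"}
    pucker = dict(pucker or {})
    for pos, state in pucker.items():
        if state not in PUCKER_DIHEDRALS:
            raise GeometryError(f"unbuildable pucker state {state!r}")
        if sequence[pos - 1] != "P":
            raise GeometryError(f"residue {pos} is not a ring residue")

    names, resnames, respos, coords = [], [], [], []

    def add(name, resname, pos, xyz):
        names.append(name)
        resnames.append(resname)
        respos.append(pos)
        coords.append(np.asarray(xyz, dtype=float))

    three = {"G": "GLY", "A": "ALA", "V": "VAL", "L": "LEU", "I": "ILE",
             "P": "PRO", "F": "PHE", "R": "ARG", "K": "LYS", "S": "SER",
             "T": "THR", "D": "ASP", "E": "GLU", "N": "ASN", "Q": "GLN",
             "M": "MET", "W": "TRP", "Y": "TYR", "C": "CYS", "H": "HIS"}

    prev_n = prev_ca = prev_c = None
    for i, aa in enumerate(sequence):
        pos = i + 1
        resname = three.get(aa)
        if resname is None:
            raise ValueError(f"invalid residue code {aa!r}")
        if i == 0:
            n = np.array([0.0, 0.0, 0.0])
            ca = np.array([1.458, 0.0, 0.0])
            ang = np.radians(180.0 - 111.0)
            c = ca + 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
        else:
            n = place_atom(prev_n, prev_ca, prev_c, 1.33, 116.7, _PSI)
            ca = place_atom(prev_ca, prev_c, n, 1.458, 121.7, omega)
            c = place_atom(prev_c, n, ca, 1.525, 111.0, _PHI)
        o = place_atom(n, ca, c, 1.23, 120.5, _PSI + 180.0)
        add("N", resname, pos, n)
        if aa != "P":
            h = place_atom(c, ca, n, 1.01, 118.0, 180.0)
            add("H", resname, pos, h)
        add("CA", resname, pos, ca)
        add("C", resname, pos, c)
        add("O", resname, pos, o)
        if aa not in ("G",):
            cb = place_atom(c, n, ca, 1.53, 110.5, 122.0)
            add("CB", resname, pos, cb)
            if aa == "P":
                chi1, chi2 = PUCKER_DIHEDRALS[pucker.get(pos, "exo")]
                cg = place_atom(n, ca, cb, 1.495, 104.0, chi1)
                cd = place_atom(ca, cb, cg, 1.51, 105.0, chi2)
                add("CG", resname, pos, cg)
                add("CD", resname, pos, cd)
                add("HG1", resname, pos, place_atom(ca, cb, cg, 1.09, 111.0, chi2 + 120.0))
                add("HG2", resname, pos, place_atom(ca, cb, cg, 1.09, 111.0, chi2 - 120.0))
            elif aa == "K":
                # coarse side chain ending in the reactive amine
                cg = place_atom(n, ca, cb, 1.53, 111.0, 180.0)
                nz = place_atom(ca, cb, cg, 1.47, 111.0, 180.0)
                add("CG", resname, pos, cg)
                add("NZ", resname, pos, nz)
        prev_n, prev_ca, prev_c = n, ca, c

    elements = [("H" if nm.startswith("H") else nm[0]) for nm in names]
    params = [_atom_params(nm, el) for nm, el in zip(names, elements)]
    atoms = make_atom_table(
        names, resnames, respos,
        elements=elements,
        charges=[p[0] for p in params],
        epsilons=[p[1] for p in params],
        sigmas=[p[2] for p in params],
    )
    frame = Frame(coordinates=np.stack(coords), box=None, time=0.0)
    return Trajectory(atoms, [frame])


# ---------------------------------------------------------------------------
# planted hydration-shell water placement


def _fibonacci_sphere(n: int = 128) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _water_at(o_pos: np.ndarray, toward: np.ndarray, collinear: bool):
    """Rigid 3-site water with O at ``o_pos``.  If ``collinear``, H1 points
    along ``toward`` (donating geometry, 180 deg angle); otherwise both
    hydrogens are placed perpendicular to ``toward`` (non-bonding)."""
    u = toward / np.linalg.norm(toward)
    # orthonormal frame
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, u)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, a)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    half = np.radians(_WATER_ANGLE / 2.0)
    if collinear:
        h1 = o_pos + _WATER_OH * u
        h2 = o_pos + _WATER_OH * (np.cos(np.radians(_WATER_ANGLE)) * u + np.sin(np.radians(_WATER_ANGLE)) * v)
    else:
        h1 = o_pos + _WATER_OH * (np.cos(half) * v + np.sin(half) * w)
        h2 = o_pos + _WATER_OH * (np.cos(half) * v - np.sin(half) * w)
    return np.stack([o_pos, h1, h2])


@dataclass
class SyntheticSpec:
    """Everything the trajectory generator plants.

    ``pucker_occupancy`` maps ring residue position to {'endo': %, 'exo': %}
    (must sum to 100); ``hydration`` maps residue position to layer counts
    {'L1': n, 'L2': n, 'L3': n, 'bulk': n}; ``sigma`` is the per-residue
    Gaussian displacement amplitude in Angstrom (scalar = uniform).
    """

    sequence: str
    box_edge: float = 40.0
    n_frames: int = 100
    seed: int = 0
    sigma: float | dict = 0.0
    pucker_occupancy: dict = field(default_factory=dict)
    omega_state: str = "trans"
    hydration: dict = field(default_factory=dict)

    def sigma_for(self, respos: int) -> float:
        if isinstance(self.sigma, dict):
            return float(self.sigma.get(respos, 0.0))
        return float(self.sigma)

    def max_sigma(self) -> float:
        if isinstance(self.sigma, dict):
            return max(self.sigma.values(), default=0.0)
        return float(self.sigma)


def _plan_waters(spec: SyntheticSpec, protein_atoms: pd.DataFrame, templates):
    """Choose anchor atoms and offsets for every planted water, verifying
    the placement stays unambiguous under the noise amplitude.

    Returns a list of (anchor_index, offset_array(3,3), layer) entries; the
    water coordinates each frame are anchor position + offset, so the
    contact distance to the anchor is exact in every frame.
    """
    names = protein_atoms["name"].to_numpy()
    elements = protein_atoms["element"].to_numpy()
    respos = protein_atoms["respos"].to_numpy()
    all_coords = np.concatenate(templates)  # union over pucker templates
    on_idx = np.flatnonzero(np.isin(elements, ["O", "N"]))
    cs_idx = np.flatnonzero(np.isin(elements, ["C", "S"]))
    centroid = templates[0].mean(axis=0)
    # an extra hydrogen bond needs a donor-acceptor distance <= 3.5 A; the
    # water rides on its anchor while other atoms jitter independently
    margin = 3.5 + max(4.3 * spec.max_sigma(), 0.4)
    dirs = _fibonacci_sphere(512)
    placed_o: list[np.ndarray] = []
    plan = []

    # candidate contact distances per layer (planted waters at slightly
    # different shell radii pack more easily around one anchor); every value
    # keeps the donor-acceptor distance d + r(OH) within the 3.5 A criterion
    contact_for = {"L1": (1.8, 1.7, 1.9), "L2": (2.4, 2.25, 2.5)}

    for pos, layers in sorted(spec.hydration.items()):
        res_mask = respos == pos
        counters: dict[str, int] = {}
        for layer in ("L1", "L2", "L3", "bulk"):
            n_want = int(layers.get(layer, 0))
            if n_want < 0:
                raise ValueError("negative shell count")
            for _ in range(n_want):
                ok = False
                if layer in ("L1", "L2"):
                    # acceptors: the residue's oxygens, then nitrogens
                    anchors = np.concatenate([
                        np.flatnonzero(res_mask & (elements == "O")),
                        np.flatnonzero(res_mask & (elements == "N")),
                    ])
                elif layer == "L3":
                    anchors = np.flatnonzero(res_mask & np.isin(names, ["CB", "CG", "CA"]))
                else:
                    anchors = np.flatnonzero(res_mask & (names == "CA"))
                if len(anchors) == 0:
                    raise ValueError(f"residue {pos}: no anchor atom for layer {layer}")
                k = counters.get(layer, 0)
                counters[layer] = k + 1
                anchor_order = [int(anchors[(k + j) % len(anchors)]) for j in range(len(anchors))]
                for anchor in anchor_order:
                    if ok:
                        break
                    base = templates[0][anchor]
                    out_dir = base - centroid
                    if np.linalg.norm(out_dir) < 1e-6:
                        out_dir = np.array([0.0, 0.0, 1.0])
                    order = np.argsort(-(dirs @ (out_dir / np.linalg.norm(out_dir))))
                    for u in dirs[order]:
                        if layer in ("L1", "L2"):
                            d = contact_for[layer][k % len(contact_for[layer])]
                            o_pos = base + (d + _WATER_OH) * u
                            water = _water_at(o_pos, base - o_pos, collinear=True)
                        elif layer == "L3":
                            o_pos = base + 3.6 * u
                            water = _water_at(o_pos, base - o_pos, collinear=False)
                        else:
                            radius = float(np.max(np.linalg.norm(all_coords - centroid, axis=1)))
                            o_pos = centroid + (radius + 6.5) * u
                            water = _water_at(o_pos, centroid - o_pos, collinear=False)
                        if not _placement_valid(
                            layer, anchor, water, templates, on_idx, cs_idx,
                            respos, pos, margin, placed_o, spec,
                        ):
                            continue
                        plan.append((anchor, water - templates[0][anchor], layer))
                        placed_o.append(water[0])
                        ok = True
                        break
                if not ok:
                    raise ValueError(
                        f"infeasible hydration spec: no room for a {layer} water "
                        f"at residue {pos}"
                    )
    return plan


def _placement_valid(layer, anchor, water, templates, on_idx, cs_idx,
                     respos, pos, margin, placed_o, spec):
    o_pos = water[0]
    for t in templates:
        d_all = np.linalg.norm(t - o_pos, axis=1)
        others = np.ones(len(t), dtype=bool)
        others[anchor] = False
        if np.any(d_all[others] < 2.6):
            return False
        # no second hydrogen bond: stay clear of every other O/N
        on_others = on_idx[on_idx != anchor]
        if len(on_others) and np.min(d_all[on_others]) < margin:
            return False
        if layer == "L3":
            # nearest C/S must be the intended anchor
            cs_others = cs_idx[cs_idx != anchor]
            if len(cs_others) and np.min(d_all[cs_others]) <= 3.6 + 3.0 * spec.max_sigma():
                return False
            if anchor not in cs_idx:
                return False
        if layer == "bulk":
            if np.min(d_all) < 5.5:
                return False
    # waters must stay far enough apart that every hydrogen's nearest heavy
    # atom is its own oxygen (covalent assignment threshold 1.25 A)
    for prev in placed_o:
        if np.linalg.norm(prev - o_pos) < 2.2:
            return False
    if layer in ("L1", "L2") and anchor not in on_idx:
        return False
    return True


def _water_table(n_waters: int, start_respos: int) -> pd.DataFrame:
    names, resnames, respos = [], [], []
    for w in range(n_waters):
        names += ["OW", "HW1", "HW2"]
        resnames += ["SOL"] * 3
        respos += [start_respos + w] * 3
    elements = ["O", "H", "H"] * n_waters
    params = [_atom_params(nm, el) for nm, el in zip(names, elements)]
    return make_atom_table(
        names, resnames, respos, elements=elements,
        charges=[p[0] for p in params],
        epsilons=[p[1] for p in params],
        sigmas=[p[2] for p in params],
    )


def make_trajectory(spec: SyntheticSpec) -> Trajectory:
    """Generate a peptide-in-water trajectory realizing ``spec`` exactly.

    Ring residues are resampled between endo/exo templates so occupancy
    fractions are met to the nearest frame; planted waters ride rigidly on
    their anchor atoms so per-frame layer counts are exact; all protein
    atoms receive independent Gaussian displacement noise of the
    per-residue amplitude.
    """
    rng = np.random.default_rng(spec.seed)
    omega = 180.0 if spec.omega_state == "trans" else 0.0
    ring_positions = sorted(spec.pucker_occupancy)
    for pos, occ in spec.pucker_occupancy.items():
        total = sum(occ.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"residue {pos}: pucker occupancies sum to {total}, not 100")

    # templates for each global ring state assignment we will need
    base_states = {pos: "exo" for pos in ring_positions}
    template_cache: dict[tuple, np.ndarray] = {}

    def template_for(states: dict) -> np.ndarray:
        key = tuple(sorted(states.items()))
        if key not in template_cache:
            t = make_peptide(spec.sequence, pucker={**base_states, **states}, omega=omega)
            template_cache[key] = t.frames[0].coordinates
        return template_cache[key]

    probe = make_peptide(spec.sequence, pucker=base_states or None, omega=omega)
    protein_atoms = probe.atoms
    # per-residue state schedule with exact frame allocation
    schedule: dict[int, np.ndarray] = {}
    for pos in ring_positions:
        occ = spec.pucker_occupancy[pos]
        n_endo = int(round(occ.get("endo", 0.0) / 100.0 * spec.n_frames))
        states = np.array(["endo"] * n_endo + ["exo"] * (spec.n_frames - n_endo))
        rng.shuffle(states)
        schedule[pos] = states

    # distinct state-combination templates
    all_templates = []
    if ring_positions:
        import itertools

        for combo in itertools.product(["endo", "exo"], repeat=len(ring_positions)):
            all_templates.append(template_for(dict(zip(ring_positions, combo))))
    else:
        all_templates.append(template_for({}))

    plan = _plan_waters(spec, protein_atoms, all_templates) if spec.hydration else []
    n_waters = len(plan)
    water_atoms = _water_table(n_waters, start_respos=len(spec.sequence) + 1)
    atoms = pd.concat([protein_atoms, water_atoms], ignore_index=True)

    respos_arr = protein_atoms["respos"].to_numpy()
    sigmas = np.array([spec.sigma_for(int(p)) for p in respos_arr])
    box = np.array([spec.box_edge] * 3)
    # keep everything well inside one periodic image
    shift = box / 2.0

    # ring atom quads so planted pucker states survive the noise: a frame
    # whose noisy chi1/chi2 signs no longer match the scheduled state gets
    # that residue's noise resampled (occupancy must be exact, not nominal)
    names_arr = protein_atoms["name"].to_numpy()
    ring_quads: dict[int, dict] = {}
    for pos in ring_positions:
        idx = {
            nm: int(np.flatnonzero((respos_arr == pos) & (names_arr == nm))[0])
            for nm in ("N", "CA", "CB", "CG", "CD")
        }
        ring_quads[pos] = {
            "chi1": (idx["N"], idx["CA"], idx["CB"], idx["CG"]),
            "chi2": (idx["CA"], idx["CB"], idx["CG"], idx["CD"]),
            "rows": np.flatnonzero(respos_arr == pos),
        }

    def _measured_state(coords, quads):
        from .geometry import dihedral as _dih

        chi1 = _dih(*(coords[i] for i in quads["chi1"]))
        chi2 = _dih(*(coords[i] for i in quads["chi2"]))
        if chi1 > 0 and chi2 < 0:
            return "endo"
        if chi1 < 0 and chi2 > 0:
            return "exo"
        return "other"

    frames = []
    for fi in range(spec.n_frames):
        states = {pos: schedule[pos][fi] for pos in ring_positions}
        coords = template_for(states).copy()
        if np.any(sigmas > 0):
            clean = coords
            coords = clean + rng.normal(0.0, 1.0, clean.shape) * sigmas[:, None]
            for pos in ring_positions:
                quads = ring_quads[pos]
                rows = quads["rows"]
                for attempt in range(1000):
                    if _measured_state(coords, quads) == states[pos]:
                        break
                    coords[rows] = clean[rows] + rng.normal(
                        0.0, 1.0, (len(rows), 3)
                    ) * sigmas[rows][:, None]
                else:
                    raise GeometryError(
                        f"noise amplitude destroys the planted pucker state "
                        f"of residue {pos}"
                    )
        parts = [coords]
        for anchor, offset, _layer in plan:
            parts.append(coords[anchor] + offset)
        allc = np.concatenate(parts) + shift
        frames.append(Frame(coordinates=allc, box=box.copy(), time=fi * 0.4))
    return Trajectory(atoms, frames, replicate_id=0)


# ---------------------------------------------------------------------------
# clustering and lysine fixtures


def make_ensemble(
    n_clusters: int,
    members_per_cluster: int,
    intra_spread: float = 0.2,
    inter_separation: float = 10.0,
    seed: int = 0,
    n_atoms: int = 20,
):
    """Multi-modal conformational ensemble with known cluster labels.

    Cluster centres are scaled copies of one random conformer, so the
    superposed RMSD between centres i and j is exactly
    ``|i - j| * inter_separation``; members add isotropic Gaussian noise of
    RMS amplitude ``intra_spread``.  Returns ``(trajectory, labels)``.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 5.0, (n_atoms, 3))
    base -= base.mean(axis=0)
    r0 = float(np.sqrt(np.mean(np.sum(base**2, axis=1))))
    frames, labels = [], []
    for c in range(n_clusters):
        scale = 1.0 + c * inter_separation / r0
        center = base * scale
        for _ in range(members_per_cluster):
            noise = rng.normal(0.0, intra_spread / np.sqrt(3.0), (n_atoms, 3))
            frames.append(Frame(coordinates=center + noise, box=None, time=len(frames) * 0.4))
            labels.append(c)
    atoms = make_atom_table(
        ["CA"] * n_atoms, ["GLY"] * n_atoms, list(range(1, n_atoms + 1))
    )
    return Trajectory(atoms, frames), np.array(labels)


def make_lysine_toy(
    pair_distances,
    jitter_sigma: float = 0.0,
    n_frames: int = 50,
    seed: int = 0,
    pair_spacing: float = 150.0,
) -> Trajectory:
    """Chain of lysine pairs with planted mean N-zeta--N-zeta distances.

    Each requested distance gets its own lysine pair; pairs are separated
    by ``pair_spacing`` so cross-pair distances never enter the contact
    sweep range.  Per-frame distances are the planted value plus Gaussian
    jitter applied along the pair axis.
    """
    pair_distances = [float(d) for d in pair_distances]
    if any(d <= 0 for d in pair_distances):
        raise ValueError("pair distances must be positive")
    rng = np.random.default_rng(seed)
    n_pairs = len(pair_distances)
    names, resnames, respos = [], [], []
    for r in range(2 * n_pairs):
        names += ["CA", "NZ"]
        resnames += ["LYS", "LYS"]
        respos += [r + 1, r + 1]
    elements = ["C", "N"] * (2 * n_pairs)
    params = [_atom_params(nm, el) for nm, el in zip(names, elements)]
    atoms = make_atom_table(
        names, resnames, respos, elements=elements,
        charges=[p[0] for p in params],
        epsilons=[p[1] for p in params],
        sigmas=[p[2] for p in params],
    )
    box = np.array([max(1000.0, pair_spacing * (n_pairs + 1) * 2)] * 3)
    frames = []
    for fi in range(n_frames):
        coords = []
        for j, d in enumerate(pair_distances):
            origin = np.array([pair_spacing * (j + 1), 100.0, 100.0])
            dd = d + (rng.normal(0.0, jitter_sigma) if jitter_sigma > 0 else 0.0)
            a_nz = origin
            b_nz = origin + np.array([dd, 0.0, 0.0])
            coords += [a_nz + np.array([0.0, 1.5, 0.0]), a_nz,
                       b_nz + np.array([0.0, 1.5, 0.0]), b_nz]
        frames.append(Frame(coordinates=np.stack(coords), box=box.copy(), time=fi * 0.4))
    return Trajectory(atoms, frames)
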