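"""Trajectory containers and I/O.

Coordinates and trajectories (PDB/GRO topology, XTC/DCD/multi-model-PDB
frames) are read through MDAnalysis and normalized into a light in-memory
:class:`Trajectory`: a pandas atom table joined to an ordered list of
:class:`Frame` coordinate snapshots.  Internal units are Angstrom for
lengths, nanoseconds for time, and kJ/mol for energies; GRO nanometres and
MDAnalysis picoseconds are converted on read.

A small boolean selection grammar (``resname``/``resid``/``name``/
``element``/``water``/``protein`` with ``and``/``or``/``not`` and
parentheses) addresses atoms without pulling MDAnalysis into downstream
modules.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Trajectory",
    "FormatError",
    "SelectionError",
    "hydrophilicity_class",
    "make_atom_table",
    "load",
    "read_param_table",
    "write_param_table",
    "equilibrium_window",
    "concatenate",
    "select",
    "write_pdb",
]

#: residue names recognised as water
WATER_RESNAMES = {"SOL", "HOH", "WAT", "TIP3", "TIP3P"}

#: atom-table columns every module may rely on
ATOM_COLUMNS = [
    "name",
    "element",
    "resname",
    "respos",
    "charge",
    "epsilon",
    "sigma",
    "is_water",
    "hydro_class",
]


class FormatError(ValueError):
    """Malformed or inconsistent input files."""


class SelectionError(ValueError):
    """Syntax error in a selection expression."""


def hydrophilicity_class(element: str) -> str:
    """Classify an element for hydration analysis.

    Oxygen, nitrogen and hydrogen are hydrophilic (hydrogen-bond capable);
    carbon and sulfur are hydrophobic; anything else is 'other'.
    """
    e = element.capitalize()
    if e in ("O", "N", "H"):
        return "hydrophilic"
    if e in ("C", "S"):
        return "hydrophobic"
    return "other"


def guess_element(name: str) -> str:
    """Element from an atom name (PDB-style): first alphabetic character,
    honouring two-letter names only for common cases."""
    stripped = re.sub(r"[^A-Za-z]", "", name)
    if not stripped:
        return "X"
    two = stripped[:2].capitalize()
    if two in ("Cl", "Br", "Na", "Mg", "Fe", "Zn", "Ca") and len(stripped) >= 2:
        return two
    return stripped[0].upper()


def make_atom_table(
    names,
    resnames,
    respos,
    elements=None,
    charges=None,
    epsilons=None,
    sigmas=None,
) -> pd.DataFrame:
    """Assemble a normalized atom table from per-atom sequences."""
    names = list(names)
    n = len(names)
    if elements is None:
        elements = [guess_element(nm) for nm in names]
    df = pd.DataFrame(
        {
            "name": names,
            "element": [str(e).capitalize() for e in elements],
            "resname": list(resnames),
            "respos": np.asarray(respos, dtype=int),
        }
    )
    df["charge"] = np.zeros(n) if charges is None else np.asarray(charges, dtype=float)
    df["epsilon"] = np.zeros(n) if epsilons is None else np.asarray(epsilons, dtype=float)
    df["sigma"] = np.zeros(n) if sigmas is None else np.asarray(sigmas, dtype=float)
    df["is_water"] = df["resname"].isin(WATER_RESNAMES)
    df["hydro_class"] = df["element"].map(hydrophilicity_class)
    df.index = pd.RangeIndex(n)
    return df


@dataclass
class Frame:
    """One coordinate snapshot: (n, 3) Angstrom coordinates, optional
    orthorhombic box edges (Angstrom), time stamp in ns, and provenance."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0
    replicate_id: int = 0
    source_index: int = 0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise FormatError("frame coordinates must be (n, 3)")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(self.box <= 0):
                raise FormatError("box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """An atom table plus an ordered list of frames from one replicate
    (or a concatenation carrying per-frame provenance)."""

    atoms: pd.DataFrame
    frames: list[Frame] = field(default_factory=list)
    replicate_id: int = 0

    def __post_init__(self):
        n = len(self.atoms)
        for f in self.frames:
            if f.n_atoms != n:
                raise FormatError(
                    f"frame has {f.n_atoms} atoms but atom table has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coordinates for f in self.frames])

    def with_frames(self, frames: list[Frame]) -> "Trajectory":
        return Trajectory(self.atoms, frames, replicate_id=self.replicate_id)


# ---------------------------------------------------------------------------
# loading


def read_param_table(path) -> pd.DataFrame:
    """Read the per-atom parameter TSV.

    Columns: index, name, element, resname, respos, charge, epsilon
    (kJ/mol), sigma (nm; converted to Angstrom).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"index", "charge", "epsilon", "sigma"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"parameter table missing columns: {sorted(missing)}")
    df = df.sort_values("index").reset_index(drop=True)
    df["sigma"] = df["sigma"] * 10.0  # nm -> Angstrom
    return df


def write_param_table(atoms: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "index": np.arange(len(atoms)),
            "name": atoms["name"].to_numpy(),
            "element": atoms["element"].to_numpy(),
            "resname": atoms["resname"].to_numpy(),
            "respos": atoms["respos"].to_numpy(),
            "charge": atoms["charge"].to_numpy(),
            "epsilon": atoms["epsilon"].to_numpy(),
            "sigma": atoms["sigma"].to_numpy() / 10.0,  # Angstrom -> nm
        }
    )
    out.to_csv(path, sep="\t", index=False)


def _box_from_dimensions(dims) -> np.ndarray | None:
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=float)
    if dims.size < 6 or np.all(dims[:3] == 0):
        return None
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise FormatError("only orthorhombic boxes are supported")
    return dims[:3].copy()


def load(coords_path, traj_path=None, params_path=None, replicate_id: int = 0) -> Trajectory:
    """Load a topology (PDB/GRO) and optional trajectory (XTC/DCD/multi-model
    PDB) into a :class:`Trajectory`, optionally joining a parameter table.
    """
    import MDAnalysis as mda

    try:
        if traj_path is None:
            u = mda.Universe(str(coords_path))
        else:
            u = mda.Universe(str(coords_path), str(traj_path))
    except (ValueError, OSError, EOFError) as exc:
        raise FormatError(f"could not load trajectory: {exc}") from exc

    names = [a.name for a in u.atoms]
    resnames = [a.resname.strip() for a in u.atoms]
    respos = [a.resid for a in u.atoms]
    try:
        elements = [e.capitalize() for e in u.atoms.elements]
    except mda.exceptions.NoDataError:
        elements = [guess_element(nm) for nm in names]
    atoms = make_atom_table(names, resnames, respos, elements=elements)

    if params_path is not None:
        par = read_param_table(params_path)
        if len(par) != len(atoms):
            raise FormatError(
                f"parameter table has {len(par)} rows for {len(atoms)} atoms"
            )
        for col in ("charge", "epsilon", "sigma"):
            atoms[col] = par[col].to_numpy()

    frames = []
    for i, ts in enumerate(u.trajectory):
        frames.append(
            Frame(
                coordinates=ts.positions.astype(float).copy(),
                box=_box_from_dimensions(ts.dimensions),
                time=float(ts.time) / 1000.0,  # ps -> ns
                replicate_id=replicate_id,
                source_index=i,
            )
        )
    return Trajectory(atoms, frames, replicate_id=replicate_id)


def write_pdb(traj: Trajectory, path, frame_indices=None) -> None:
    """Write frames as a (multi-)MODEL PDB snapshot file."""
    import MDAnalysis as mda

    idx = range(traj.n_frames) if frame_indices is None else frame_indices
    atoms = traj.atoms
    respos = atoms["respos"].to_numpy()
    # contiguous residue blocks
    boundaries = np.flatnonzero(np.diff(respos) != 0)
    starts = np.concatenate([[0], boundaries + 1])
    residx = np.zeros(len(atoms), dtype=int)
    for ri, s in enumerate(starts):
        e = starts[ri + 1] if ri + 1 < len(starts) else len(atoms)
        residx[s:e] = ri
    u = mda.Universe.empty(
        len(atoms), n_residues=len(starts), atom_resindex=residx, trajectory=True
    )
    u.add_TopologyAttr("names", atoms["name"].tolist())
    u.add_TopologyAttr("resnames", [atoms["resname"].iloc[s] for s in starts])
    u.add_TopologyAttr("resids", [int(atoms["respos"].iloc[s]) for s in starts])
    u.add_TopologyAttr("elements", atoms["element"].tolist())
    with mda.Writer(str(path), multiframe=True, n_atoms=len(atoms)) as w:
        for i in idx:
            f = traj.frames[i]
            u.atoms.positions = f.coordinates
            if f.box is not None:
                u.dimensions = [*f.box, 90.0, 90.0, 90.0]
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# windowing / concatenation


def equilibrium_window(traj: Trajectory, keep_fraction: float = 0.5) -> Trajectory:
    """Keep the trailing ``ceil(keep_fraction * n_frames)`` frames — the
    equilibrated tail over which all ensemble averages are taken."""
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    keep = math.ceil(keep_fraction * traj.n_frames)
    return traj.with_frames(traj.frames[traj.n_frames - keep :])


def _tables_match(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    key = ["name", "element", "resname", "respos"]
    return len(a) == len(b) and a[key].reset_index(drop=True).equals(
        b[key].reset_index(drop=True)
    )


def concatenate(trajectories) -> Trajectory:
    """Concatenate replicate trajectories; frames keep their replicate id and
    original index so cluster members can be mapped back."""
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("nothing to concatenate")
    head = trajectories[0]
    frames: list[Frame] = []
    for t in trajectories:
        if not _tables_match(head.atoms, t.atoms):
            raise FormatError("atom tables differ between trajectories")
        for f in t.frames:
            frames.append(
                replace(f, replicate_id=t.replicate_id, source_index=f.source_index)
            )
    return Trajectory(head.atoms.copy(), frames, replicate_id=-1)


# ---------------------------------------------------------------------------
# selection grammar

_TOKEN = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[A-Za-z_][A-Za-z0-9_*']*)|"
    r"(?P<range>\d+(?:-\d+)?))"
)

_KEYWORDS = {"and", "or", "not", "water", "protein", "all",
             "resname", "resid", "name", "element", "backbone"}

_BACKBONE_NAMES = {"N", "CA", "C", "O"}


def _tokenize(expr: str):
    pos, out = 0, []
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m or m.end() == pos:
            if expr[pos:].strip():
                raise SelectionError(f"bad token at: {expr[pos:]!r}")
            break
        pos = m.end()
        if m.lastgroup:
            out.append(m.group(m.lastgroup))
    return out


class _Parser:
    """Recursive-descent parser for the boolean selection mini-grammar."""

    def __init__(self, tokens, atoms: pd.DataFrame):
        self.tokens = tokens
        self.i = 0
        self.atoms = atoms

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression")
        self.i += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens: {self.tokens[self.i:]}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("missing closing parenthesis")
            return mask
        return self.primary()

    def _values(self):
        vals = []
        while True:
            tok = self.peek()
            if tok is None or tok in _KEYWORDS or tok in ("(", ")"):
                break
            vals.append(self.next())
        if not vals:
            raise SelectionError("expected at least one value")
        return vals

    def primary(self) -> np.ndarray:
        tok = self.next()
        a = self.atoms
        if tok == "water":
            return a["is_water"].to_numpy()
        if tok == "protein":
            return ~a["is_water"].to_numpy()
        if tok == "all":
            return np.ones(len(a), dtype=bool)
        if tok == "backbone":
            return (~a["is_water"].to_numpy()) & a["name"].isin(_BACKBONE_NAMES).to_numpy()
        if tok == "resname":
            return a["resname"].isin(self._values()).to_numpy()
        if tok == "name":
            return a["name"].isin(self._values()).to_numpy()
        if tok == "element":
            vals = [v.capitalize() for v in self._values()]
            return a["element"].isin(vals).to_numpy()
        if tok == "resid":
            mask = np.zeros(len(a), dtype=bool)
            respos = a["respos"].to_numpy()
            for v in self._values():
                if "-" in v:
                    lo, hi = v.split("-")
                    mask |= (respos >= int(lo)) & (respos <= int(hi))
                else:
                    mask |= respos == int(v)
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r}")


def select(traj_or_atoms, expression: str) -> np.ndarray:
    """Evaluate a selection expression; returns sorted atom indices."""
    atoms = traj_or_atoms.atoms if isinstance(traj_or_atoms, Trajectory) else traj_or_atoms
    mask = _Parser(_tokenize(expression), atoms).parse()
    return np.flatnonzero(mask)
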