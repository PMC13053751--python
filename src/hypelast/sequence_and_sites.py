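"""Elastin sequences, hydroxylation-eligible motifs, hydroxylation maps, and
coordinate-level editing of proline into (2S,4R)-4-hydroxyproline.

Prolyl 4-hydroxylase acts within the sequence motifs Gly-Yaa-Pro-Gly and
Gly-Yaa-Zaa-Pro-Gly (Yaa, Zaa any residue but proline).  In full-length
tropoelastin (isoform 2 numbering) the two most consistently modified sites,
Pro190 and Pro360, are always hydroxylated in a map; Pro615 is hydroxylated
in half the maps; the remainder are drawn uniformly from a pool of 17
experimentally confirmed partially hydroxylated positions.  Pro421 sits
outside any eligible motif in this isoform (Ser422 replaces Gly422) and is
never hydroxylated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, place_atom
from .trajectory_io import Frame, Trajectory, hydrophilicity_class

__all__ = [
    "AMINO_ACIDS",
    "ProteinSequence",
    "MotifHit",
    "CandidatePool",
    "HydroxylationMap",
    "MapFormatError",
    "ALWAYS_HYDROXYLATED",
    "OPTIONAL_SITE",
    "EXCLUDED_SITE",
    "DEFAULT_POOL",
    "scan_motifs",
    "build_map",
    "parse_map",
    "parse_maps",
    "write_maps",
    "hydroxylate_structure",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: sites hydroxylated in every non-empty full-length map
ALWAYS_HYDROXYLATED = frozenset({190, 360})
#: site hydroxylated in half of the maps (~50% observed occupancy)
OPTIONAL_SITE = 615
#: motif-ineligible site, never hydroxylated in isoform 2
EXCLUDED_SITE = 421
#: the 17 confirmed partially hydroxylated positions forming the random pool
DEFAULT_POOL = frozenset(
    {34, 116, 147, 283, 327, 337, 342, 347, 387, 405, 415, 427, 433, 551, 560, 578, 658}
)


class MapFormatError(ValueError):
    """Malformed hydroxylation-map input."""


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter residue string with an offset mapping string index 0 to
    residue number ``numbering_offset + 1``."""

    residues: str
    numbering_offset: int = 0

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"invalid residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def position(self, index: int) -> int:
        """Residue number (1-based plus offset) of 0-based string index."""
        return self.numbering_offset + index + 1

    def residue_at(self, position: int) -> str:
        return self.residues[position - self.numbering_offset - 1]


@dataclass(frozen=True)
class MotifHit:
    """A hydroxylation-eligible motif occurrence; positions use the
    sequence's residue numbering and spans are closed intervals."""

    pro_position: int
    motif_kind: str  # "GXPG" or "GXXPG"
    span: tuple[int, int]


def scan_motifs(seq: ProteinSequence) -> list[MotifHit]:
    """All G-Yaa-P-G and G-Yaa-Zaa-P-G motif occurrences with Yaa, Zaa != P.

    Overlapping hits (a proline matched by both patterns) are all reported;
    results are sorted by proline position then motif kind.
    """
    s = seq.residues
    hits: list[MotifHit] = []
    # GXPG: G at i, Yaa at i+1 (not P), P at i+2, G at i+3
    for m in re.finditer(r"(?=G([^P])PG)", s):
        i = m.start()
        hits.append(
            MotifHit(
                pro_position=seq.position(i + 2),
                motif_kind="GXPG",
                span=(seq.position(i), seq.position(i + 3)),
            )
        )
    # GXXPG: G, Yaa (not P), Zaa (not P), P, G
    for m in re.finditer(r"(?=G([^P])([^P])PG)", s):
        i = m.start()
        hits.append(
            MotifHit(
                pro_position=seq.position(i + 3),
                motif_kind="GXXPG",
                span=(seq.position(i), seq.position(i + 4)),
            )
        )
    hits.sort(key=lambda h: (h.pro_position, h.motif_kind))
    return hits


@dataclass(frozen=True)
class CandidatePool:
    """Pool of sites from which random hydroxylation positions are drawn."""

    sites: frozenset = DEFAULT_POOL

    def __post_init__(self):
        object.__setattr__(self, "sites", frozenset(int(s) for s in self.sites))
        if EXCLUDED_SITE in self.sites:
            raise ValueError(f"position {EXCLUDED_SITE} cannot be in the pool")


@dataclass(frozen=True)
class HydroxylationMap:
    """Designated plus randomly selected hydroxylation positions for one
    model (one row of the full-length model table)."""

    model_name: str
    designated: frozenset = frozenset()
    random: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "designated", frozenset(int(s) for s in self.designated))
        object.__setattr__(self, "random", frozenset(int(s) for s in self.random))
        if self.designated & self.random:
            raise MapFormatError("designated and random sites overlap")
        if EXCLUDED_SITE in self.sites:
            raise MapFormatError(f"position {EXCLUDED_SITE} is never hydroxylated")
        if self.sites and not self.designated >= ALWAYS_HYDROXYLATED:
            raise MapFormatError(
                f"non-empty map must designate {sorted(ALWAYS_HYDROXYLATED)}"
            )

    @property
    def sites(self) -> frozenset:
        return self.designated | self.random

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def build_map(
    n_total: int,
    include_615: bool = False,
    pool: CandidatePool | None = None,
    seed: int = 0,
    model_name: str | None = None,
) -> HydroxylationMap:
    """Draw a hydroxylation map: {190, 360} (+615 when flagged) designated,
    the remainder sampled uniformly without replacement from the pool."""
    pool = pool or CandidatePool()
    designated = set(ALWAYS_HYDROXYLATED)
    if include_615:
        designated.add(OPTIONAL_SITE)
    if n_total < len(designated):
        raise ValueError(
            f"n_total={n_total} below the {len(designated)} designated sites"
        )
    candidates = sorted(pool.sites - designated)
    n_random = n_total - len(designated)
    if n_random > len(candidates):
        raise ValueError(
            f"n_total={n_total} exceeds capacity {len(designated) + len(candidates)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_random, replace=False) if n_random else []
    name = model_name or f"{n_total}hyp-{2 if include_615 else 1}"
    return HydroxylationMap(name, frozenset(designated), frozenset(int(c) for c in chosen))


# --- map file format: one map per line,
#     <name>\tdesignated:<comma-list>\trandom:<comma-list>


def _parse_int_list(text: str) -> frozenset:
    text = text.strip()
    if not text:
        return frozenset()
    out = []
    for tok in text.split(","):
        tok = tok.strip()
        if not re.fullmatch(r"\d+", tok):
            raise MapFormatError(f"malformed position {tok!r}")
        out.append(int(tok))
    if len(out) != len(set(out)):
        raise MapFormatError("duplicate positions in map line")
    return frozenset(out)


def parse_map(line: str) -> HydroxylationMap:
    """Parse one ``name\\tdesignated:...\\trandom:...`` map line."""
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 3:
        raise MapFormatError(f"expected 3 tab-separated fields, got {len(parts)}")
    name, dfield, rfield = parts
    if not dfield.startswith("designated:") or not rfield.startswith("random:"):
        raise MapFormatError("fields must be 'designated:<list>' and 'random:<list>'")
    designated = _parse_int_list(dfield[len("designated:"):])
    random = _parse_int_list(rfield[len("random:"):])
    if designated & random:
        raise MapFormatError("duplicate positions across designated/random")
    return HydroxylationMap(name, designated, random)


def parse_maps(path) -> list[HydroxylationMap]:
    maps = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                maps.append(parse_map(line))
    return maps


def format_map(m: HydroxylationMap) -> str:
    d = ",".join(str(s) for s in sorted(m.designated))
    r = ",".join(str(s) for s in sorted(m.random))
    return f"{m.model_name}\tdesignated:{d}\trandom:{r}"


def write_maps(maps, path) -> None:
    with open(path, "w") as fh:
        for m in maps:
            fh.write(format_map(m) + "\n")


# ---------------------------------------------------------------------------
# coordinate-level hydroxylation

_CO_BOND = 1.43  # Cgamma-O bond length, Angstrom
_OH_BOND = 0.96  # O-H bond length, Angstrom


class StructureError(ValueError):
    """Residue missing, not a proline, or lacking required ring atoms."""


def _residue_atom(atoms, respos: int, name: str) -> int:
    idx = atoms.index[(atoms["respos"] == respos) & (atoms["name"] == name)]
    if len(idx) != 1:
        raise StructureError(f"residue {respos}: expected one atom {name!r}, found {len(idx)}")
    return int(idx[0])


def hydroxylate_structure(
    traj: Trajectory, residue_position: int, hyp_resname: str = "HYP"
) -> Trajectory:
    """Replace the pro-R Cgamma hydrogen of a proline with a hydroxyl group,
    yielding (2S,4R)-4-hydroxyproline.

    The hydroxyl oxygen is placed along the former C-H direction at 1.43 A
    from Cgamma; the hydroxyl hydrogen at 0.96 A from the oxygen, anti to
    Cbeta about the new C-O bond.  Every other atom is untouched and the
    residue is renamed.  Works frame-wise on a whole trajectory; the pro-R
    hydrogen is identified on the first frame.
    """
    atoms = traj.atoms
    sel = atoms.index[atoms["respos"] == residue_position]
    if len(sel) == 0:
        raise StructureError(f"no residue at position {residue_position}")
    resname = atoms.loc[sel[0], "resname"]
    if resname != "PRO":
        raise StructureError(f"residue {residue_position} is {resname}, not PRO")

    i_cb = _residue_atom(atoms, residue_position, "CB")
    i_cg = _residue_atom(atoms, residue_position, "CG")
    i_cd = _residue_atom(atoms, residue_position, "CD")
    hg_idx = [
        int(i)
        for i in atoms.index[
            (atoms["respos"] == residue_position)
            & atoms["name"].isin(["HG1", "HG2", "HG3", "2HG", "3HG"])
        ]
    ]
    if len(hg_idx) < 2:
        raise StructureError(f"residue {residue_position}: Cgamma hydrogens absent")

    # pro-R hydrogen: positive signed volume of (CB-CG, CD-CG, H-CG);
    # replacing it with OH yields the 4R configuration at Cgamma.
    ref = traj.frames[0].coordinates
    def det_for(h):
        return np.linalg.det(
            np.stack([ref[i_cb] - ref[i_cg], ref[i_cd] - ref[i_cg], ref[h] - ref[i_cg]])
        )
    pro_r = max(hg_idx, key=det_for)
    if det_for(pro_r) <= 0:
        raise GeometryError("could not identify a pro-R Cgamma hydrogen")

    keep = [i for i in range(len(atoms)) if i != pro_r]
    insert_at = max(i_cg, *[h for h in hg_idx if h != pro_r])

    new_atoms = atoms.drop(index=pro_r).reset_index(drop=True)
    # map old indices to positions in `keep`
    old_to_new = {old: new for new, old in enumerate(keep)}
    row_od1 = {
        "name": "OD1",
        "element": "O",
        "resname": hyp_resname,
        "respos": residue_position,
        "charge": -0.65,
        "epsilon": 0.6364,
        "sigma": 3.15,
        "is_water": False,
        "hydro_class": hydrophilicity_class("O"),
    }
    row_hd1 = {
        "name": "HD1",
        "element": "H",
        "resname": hyp_resname,
        "respos": residue_position,
        "charge": 0.42,
        "epsilon": 0.0,
        "sigma": 0.4,
        "is_water": False,
        "hydro_class": hydrophilicity_class("H"),
    }
    pos_insert = old_to_new[insert_at] + 1
    import pandas as pd

    new_atoms = pd.concat(
        [
            new_atoms.iloc[:pos_insert],
            pd.DataFrame([row_od1, row_hd1]),
            new_atoms.iloc[pos_insert:],
        ],
        ignore_index=True,
    )
    new_atoms.loc[new_atoms["respos"] == residue_position, "resname"] = hyp_resname

    new_frames = []
    for f in traj.frames:
        c = f.coordinates
        u = c[pro_r] - c[i_cg]
        u = u / np.linalg.norm(u)
        o_pos = c[i_cg] + _CO_BOND * u
        h_pos = place_atom(c[i_cb], c[i_cg], o_pos, _OH_BOND, 109.5, 180.0)
        kept = c[keep]
        new_coords = np.concatenate(
            [kept[:pos_insert], [o_pos, h_pos], kept[pos_insert:]]
        )
        new_frames.append(
            Frame(
                coordinates=new_coords,
                box=None if f.box is None else f.box.copy(),
                time=f.time,
                replicate_id=f.replicate_id,
                source_index=f.source_index,
            )
        )
    return Trajectory(new_atoms, new_frames, replicate_id=traj.replicate_id)


# ---------------------------------------------------------------------------
# FASTA plumbing (Biopython-backed)


def read_fasta(path) -> dict[str, ProteinSequence]:
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = ProteinSequence(str(rec.seq).upper())
    return out


def write_fasta(sequences: dict[str, ProteinSequence], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [SeqRecord(Seq(s.residues), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")
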