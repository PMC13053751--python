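"""Low-level vector geometry: periodic minimum-image arithmetic, dihedral
angles, internal-coordinate atom placement, and Kabsch superposition.

All lengths are in Angstrom and all angles in degrees unless noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "minimum_image",
    "pair_distances",
    "dihedral",
    "place_atom",
    "kabsch",
    "superposed_rmsd",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear dihedral frames,
    underdetermined superpositions, coincident points)."""


def minimum_image(vectors: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the orthorhombic minimum-image convention to displacement vectors.

    Parameters
    ----------
    vectors : (..., 3) array of displacement vectors.
    box : (3,) orthorhombic box edges, or None for a non-periodic system.
    """
    if box is None:
        return vectors
    box = np.asarray(box, dtype=float)
    return vectors - box * np.round(vectors / box)


def pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Minimum-image distance matrix between point sets ``a`` (n,3) and ``b`` (m,3)."""
    d = a[:, None, :] - b[None, :, :]
    d = minimum_image(d, box)
    return np.linalg.norm(d, axis=-1)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, in (-180, 180].

    Sign follows the IUPAC convention (positive for a clockwise rotation of
    the p1->p2 bond projection into the p3->p4 projection when viewed from
    p2 toward p3); ((0,0,0),(1,0,0),(1,1,0),(1,1,1)) gives +90.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("degenerate dihedral geometry (collinear or coincident points)")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    ang = np.degrees(np.arctan2(y, x))
    # canonicalize -180 to +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dihedrals(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> np.ndarray:
    """Vectorized :func:`dihedral` over stacked (n,3) point arrays."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2h = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, n2), b2h)
    ang = np.degrees(np.arctan2(y, x))
    ang[ang <= -180.0] += 360.0
    return ang


def place_atom(a, b, c, bond: float, angle: float, dihedral_deg: float) -> np.ndarray:
    """Place a new atom bonded to ``c`` using internal coordinates.

    The new atom X satisfies |X-c| = bond, angle(b,c,X) = ``angle`` degrees
    and dihedral(a,b,c,X) = ``dihedral_deg`` degrees (NeRF construction).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear reference atoms for placement")
    n /= nn
    m = np.cross(n, bc)
    ang = np.radians(angle)
    dih = np.radians(dihedral_deg)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    basis = np.column_stack([bc, m, n])
    return c + basis @ d


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where the proper rotation
    (det = +1) and translation map mobile coordinates as ``x @ R.T + t``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise GeometryError("superposition needs >= 3 paired atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    t = rc - rot @ mc
    moved = mobile @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, t, rmsd


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of ``a`` onto ``b`` after optimal proper-rotation superposition."""
    return kabsch(a, b)[2]
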