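"""Independent, deliberately naive reference implementations.

These are written with plain Python loops and scalar math so that they
share no code path with the vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def _mi(v, box):
    """Minimum-image displacement, scalar loop version."""
    if box is None:
        return list(v)
    return [v[k] - box[k] * round(v[k] / box[k]) for k in range(3)]


def _dist(a, b, box):
    v = _mi([a[0] - b[0], a[1] - b[1], a[2] - b[2]], box)
    return math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)


def hbond_triples(coords, elements, box, d_cut=3.5, angle_cut=150.0,
                  xh_bond=1.25, orphan_cut=1.6):
    """All (donor, hydrogen, acceptor) index triples by exhaustive search.

    Raises ValueError when a hydrogen has no heavy atom within
    ``orphan_cut`` (mirrors the detector's typing error).
    """
    n = len(elements)
    heavies = [i for i in range(n) if elements[i] != "H"]
    hydrogens = [i for i in range(n) if elements[i] == "H"]
    triples = set()
    for h in hydrogens:
        best, best_d = None, float("inf")
        for j in heavies:
            d = _dist(coords[h], coords[j], box)
            if d < best_d:
                best, best_d = j, d
        if best is None or best_d > orphan_cut:
            raise ValueError(f"orphan hydrogen {h}")
        if best_d > xh_bond or elements[best] not in ("O", "N"):
            continue
        donor = best
        for a in range(n):
            if a == donor or elements[a] not in ("O", "N"):
                continue
            if _dist(coords[donor], coords[a], box) > d_cut:
                continue
            hv = _mi([coords[donor][k] - coords[h][k] for k in range(3)], box)
            av = _mi([coords[a][k] - coords[h][k] for k in range(3)], box)
            dot = sum(hv[k] * av[k] for k in range(3))
            nh = math.sqrt(sum(x * x for x in hv))
            na = math.sqrt(sum(x * x for x in av))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, dot / (nh * na)))))
            if ang >= angle_cut:
                triples.add((donor, h, a))
    return triples


def interaction_energy_double_loop(coords, elements_unused, charges, epsilons,
                                   sigmas, is_water, box, cutoff=12.0,
                                   coulomb=1389.35485):
    """Protein-water nonbonded energy by explicit double loop."""
    n = len(charges)
    total = 0.0
    for i in range(n):
        if is_water[i]:
            continue
        for j in range(n):
            if not is_water[j]:
                continue
            r = _dist(coords[i], coords[j], box)
            if r <= 0 or r > cutoff:
                continue
            e = coulomb * charges[i] * charges[j] / r
            eps = math.sqrt(epsilons[i] * epsilons[j])
            sig = 0.5 * (sigmas[i] + sigmas[j])
            sr6 = (sig / r) ** 6
            e += 4.0 * eps * (sr6 * sr6 - sr6)
            total += e
    return total


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def jarvis_patrick_reference(d, k, min_shared):
    """Shared-nearest-neighbour clustering via brute force + union-find.

    Returns the partition as a set of frozensets of frame indices.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    nn = []
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (d[i, j], j))
        nn.append(set(order[:k]))
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if j in nn[i] and i in nn[j]:
                if len((nn[i] & nn[j]) - {i, j}) >= min_shared:
                    uf.union(i, j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def partition_of(labels):
    """Label vector -> set-of-frozensets partition (relabel-invariant)."""
    groups: dict[int, set] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(i)
    return {frozenset(g) for g in groups.values()}


def dihedral_reference(p1, p2, p3, p4):
    """Dihedral by the textbook normal-vector construction, scalar math."""
    b1 = [p2[k] - p1[k] for k in range(3)]
    b2 = [p3[k] - p2[k] for k in range(3)]
    b3 = [p4[k] - p3[k] for k in range(3)]

    def cross(a, b):
        return [a[1] * b[2] - a[2] * b[1],
                a[2] * b[0] - a[0] * b[2],
                a[0] * b[1] - a[1] * b[0]]

    n1 = cross(b1, b2)
    n2 = cross(b2, b3)
    norm_b2 = math.sqrt(sum(x * x for x in b2))
    m = cross(n1, [x / norm_b2 for x in b2])
    x = sum(n1[k] * n2[k] for k in range(3))
    y = sum(m[k] * n2[k] for k in range(3))
    # the sign flip makes a positive angle a clockwise rotation viewed
    # down b2 (the convention where (0,0,0),(1,0,0),(1,1,0),(1,1,1) -> +90)
    return math.degrees(math.atan2(-y, x))
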