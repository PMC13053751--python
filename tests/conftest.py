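"""Shared fixtures: small synthetic trajectories with planted ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from hypelast import synthetic_data, trajectory_io as tio


def random_hbond_frame(rng, n_atoms=300, box_edge=25.0, periodic=True):
    """A random frame where every hydrogen is covalently attached.

    Heavy atoms (C/N/O) are scattered uniformly; each hydrogen sits
    0.9-1.1 A from a randomly chosen heavy atom, so the nearest heavy atom
    is always within the covalent assignment threshold.  Returns
    ``(coords, elements, box)``.
    """
    n_heavy = int(n_atoms * 0.6)
    n_h = n_atoms - n_heavy
    heavy_elements = rng.choice(["C", "N", "O"], size=n_heavy, p=[0.4, 0.25, 0.35])
    heavy = rng.uniform(0.0, box_edge, (n_heavy, 3))
    hosts = rng.integers(0, n_heavy, size=n_h)
    dirs = rng.normal(size=(n_h, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bonds = rng.uniform(0.9, 1.1, size=(n_h, 1))
    hydrogens = heavy[hosts] + dirs * bonds
    coords = np.vstack([heavy, hydrogens])
    elements = list(heavy_elements) + ["H"] * n_h
    box = np.array([box_edge] * 3) if periodic else None
    return coords, elements, box


def hbond_frame_objects(coords, elements, box):
    """Wrap raw arrays into the Frame/atom-table pair the detector takes."""
    n = len(elements)
    atoms = tio.make_atom_table(
        names=[f"{e}{i}" for i, e in enumerate(elements)],
        resnames=["UNK"] * n,
        respos=[1] * n,
        elements=elements,
    )
    frame = tio.Frame(coordinates=coords, box=box)
    return frame, atoms


@pytest.fixture(scope="session")
def hydration_spec():
    """Noisy peptide with planted pucker occupancies and hydration shells."""
    return synthetic_data.SyntheticSpec(
        sequence="GVPG",
        box_edge=40.0,
        n_frames=20,
        seed=11,
        sigma=0.1,
        pucker_occupancy={3: {"endo": 40.0, "exo": 60.0}},
        hydration={2: {"L1": 3, "L2": 2, "L3": 4, "bulk": 2}},
    )


@pytest.fixture(scope="session")
def hydration_traj(hydration_spec):
    return synthetic_data.make_trajectory(hydration_spec)
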