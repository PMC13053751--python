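"""Hydrogen bonds, hydration shells, interaction energy, and RDF."""

import numpy as np
import pytest

from _oracles import hbond_triples, interaction_energy_double_loop
from conftest import hbond_frame_objects, random_hbond_frame
from hypelast import hydration, trajectory_io as tio
from hypelast.synthetic_data import make_trajectory


def _frame(coords, box=None):
    return tio.Frame(coordinates=np.asarray(coords, dtype=float), box=box)


def _atoms(names, resnames, respos, elements, **kw):
    return tio.make_atom_table(names, resnames, respos, elements=elements, **kw)


class TestDetectHbonds:
    def test_ideal_linear_bond_found(self):
        # O-H...O, donor-acceptor 2.8 A, perfectly linear
        atoms = _atoms(
            ["O1", "H1", "O2"], ["UNK", "UNK", "SOL"], [1, 1, 2], ["O", "H", "O"]
        )
        frame = _frame([[0, 0, 0], [0.96, 0, 0], [2.8, 0, 0]])
        bonds = hydration.detect_hbonds(frame, atoms)
        assert len(bonds) == 1
        hb = bonds[0]
        assert (hb.donor, hb.hydrogen, hb.acceptor) == (0, 1, 2)
        assert hb.distance == pytest.approx(2.8)
        assert hb.angle == pytest.approx(180.0)

    def test_distance_cutoff_excludes(self):
        atoms = _atoms(
            ["O1", "H1", "O2"], ["UNK", "UNK", "SOL"], [1, 1, 2], ["O", "H", "O"]
        )
        frame = _frame([[0, 0, 0], [0.96, 0, 0], [3.6, 0, 0]])
        assert hydration.detect_hbonds(frame, atoms) == []

    def test_angle_cutoff_excludes_bent_geometry(self):
        atoms = _atoms(
            ["O1", "H1", "O2"], ["UNK", "UNK", "SOL"], [1, 1, 2], ["O", "H", "O"]
        )
        # acceptor placed so the donor-H...acceptor angle is ~90 degrees
        frame = _frame([[0, 0, 0], [0.96, 0, 0], [0.96, 2.0, 0]])
        assert hydration.detect_hbonds(frame, atoms) == []

    def test_carbon_cannot_donate_or_accept(self):
        atoms = _atoms(
            ["C1", "H1", "O2"], ["UNK", "UNK", "SOL"], [1, 1, 2], ["C", "H", "O"]
        )
        frame = _frame([[0, 0, 0], [1.05, 0, 0], [2.9, 0, 0]])
        assert hydration.detect_hbonds(frame, atoms) == []

    def test_bond_found_across_periodic_boundary(self):
        atoms = _atoms(
            ["O1", "H1", "O2"], ["UNK", "UNK", "SOL"], [1, 1, 2], ["O", "H", "O"]
        )
        box = np.array([10.0, 10.0, 10.0])
        frame = _frame([[0.3, 5, 5], [9.6, 5, 5], [7.7, 5, 5]], box=box)
        bonds = hydration.detect_hbonds(frame, atoms)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.6)

    def test_orphan_hydrogen_is_a_typing_error(self):
        atoms = _atoms(["O1", "H1"], ["UNK", "UNK"], [1, 1], ["O", "H"])
        frame = _frame([[0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(hydration.TypingError):
            hydration.detect_hbonds(frame, atoms)

    def test_matches_brute_force_oracle_on_random_frames(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            coords, elements, box = random_hbond_frame(
                rng, n_atoms=120, periodic=bool(trial % 2)
            )
            frame, atoms = hbond_frame_objects(coords, elements, box)
            got = {
                (b.donor, b.hydrogen, b.acceptor)
                for b in hydration.detect_hbonds(frame, atoms)
            }
            want = hbond_triples(coords, elements, box)
            assert got == want


class TestCountHbonds:
    def test_counts_only_protein_water_bonds(self):
        # protein O-H donating to water O, plus a water-water bond that
        # must not be counted
        atoms = _atoms(
            ["O1", "H1", "OW", "HW1", "OW", "HW1"],
            ["SER", "SER", "SOL", "SOL", "SOL", "SOL"],
            [1, 1, 2, 2, 3, 3],
            ["O", "H", "O", "H", "O", "H"],
        )
        frame = _frame(
            [
                [0, 0, 0], [0.96, 0, 0],          # protein hydroxyl
                [2.8, 0, 0], [3.76, 0, 0],        # water 2 accepts, donates on
                [5.6, 0, 0], [6.2, 0.8, 0],       # water 3 accepts from water 2
            ]
        )
        traj = tio.Trajectory(atoms, [frame])
        counts, mean, sd = hydration.count_hbonds(traj, "protein")
        assert counts.tolist() == [1.0]
        assert mean == 1.0 and sd == 0.0

    def test_empty_selection_rejected(self):
        atoms = _atoms(["OW", "HW1"], ["SOL", "SOL"], [1, 1], ["O", "H"])
        traj = tio.Trajectory(atoms, [_frame([[0, 0, 0], [0.96, 0, 0]])])
        with pytest.raises(ValueError):
            hydration.count_hbonds(traj, "protein")


class TestClassifyWaters:
    def _system(self, contact_d):
        """One protein carbonyl plus one water donating at the given
        H...acceptor contact distance."""
        atoms = _atoms(
            ["C", "O", "OW", "HW1", "HW2"],
            ["GLY", "GLY", "SOL", "SOL", "SOL"],
            [1, 1, 2, 2, 2],
            ["C", "O", "O", "H", "H"],
        )
        ow = np.array([contact_d + 0.957, 0.0, 0.0])
        frame = _frame(
            [
                [-1.4, 0, 0],                 # C
                [0, 0, 0],                    # O (acceptor)
                ow,                           # OW
                [contact_d, 0.0, 0.0],        # HW1 pointing at the acceptor
                ow + [0.3, 0.9, 0.0],         # HW2 away
            ]
        )
        return atoms, frame

    @pytest.mark.parametrize(
        "contact_d,label",
        [(1.8, "hydrophilic_L1"), (2.0, "hydrophilic_L1"), (2.4, "hydrophilic_L2")],
    )
    def test_contact_distance_sets_the_layer(self, contact_d, label):
        atoms, frame = self._system(contact_d)
        labels = hydration.classify_waters(frame, atoms)
        assert len(labels) == 1
        assert labels[0].label == label
        assert labels[0].anchor == 1  # the protein acceptor
        assert labels[0].anchor_distance == pytest.approx(contact_d, abs=1e-9)

    def test_hydrophobic_water_near_carbon(self):
        atoms = _atoms(
            ["CA", "OW", "HW1", "HW2"],
            ["GLY", "SOL", "SOL", "SOL"],
            [1, 2, 2, 2],
            ["C", "O", "H", "H"],
        )
        frame = _frame(
            [[0, 0, 0], [3.5, 0, 0], [4.2, 0.6, 0], [4.2, -0.6, 0]]
        )
        labels = hydration.classify_waters(frame, atoms)
        assert labels[0].label == "hydrophobic_L3"
        assert labels[0].anchor == 0

    def test_distant_water_is_bulk(self):
        atoms = _atoms(
            ["CA", "OW", "HW1", "HW2"],
            ["GLY", "SOL", "SOL", "SOL"],
            [1, 2, 2, 2],
            ["C", "O", "H", "H"],
        )
        frame = _frame(
            [[0, 0, 0], [9, 0, 0], [9.7, 0.6, 0], [9.7, -0.6, 0]]
        )
        labels = hydration.classify_waters(frame, atoms)
        assert labels[0].label == "bulk"
        assert labels[0].anchor is None

    def test_every_water_gets_exactly_one_label(self, hydration_traj):
        traj = hydration_traj
        n_waters = len(set(traj.atoms.loc[traj.atoms["is_water"], "respos"]))
        for fi, frame in enumerate(traj.frames[:5]):
            labels = hydration.classify_waters(frame, traj.atoms, frame_index=fi)
            assert len(labels) == n_waters
            assert len({wl.water_respos for wl in labels}) == n_waters


class TestHydrationCounts:
    def test_planted_shell_counts_recovered(self, hydration_spec, hydration_traj):
        planted = hydration_spec.hydration[2]
        s = hydration.hydration_counts(hydration_traj, scope="global")
        assert s.hydrophilic == planted["L1"] + planted["L2"]
        assert s.hydrophobic == planted["L3"]
        assert s.total == s.hydrophilic + s.hydrophobic
        assert s.sd_total == 0.0
        assert s.overflow_beyond_l2 == 0.0

    def test_local_scope_restricts_to_the_residue(self, hydration_traj):
        s = hydration.hydration_counts(
            hydration_traj, scope="local", selection="resid 2"
        )
        g = hydration.hydration_counts(hydration_traj, scope="global")
        assert s.total == g.total  # all waters are anchored on residue 2
        far = hydration.hydration_counts(
            hydration_traj, scope="local", selection="resid 4"
        )
        assert far.total == 0.0

    def test_local_scope_requires_selection(self, hydration_traj):
        with pytest.raises(ValueError):
            hydration.hydration_counts(hydration_traj, scope="local")


class TestInteractionEnergy:
    def test_coulomb_pair_closed_form(self):
        atoms = _atoms(
            ["NA", "OW"], ["UNK", "SOL"], [1, 2], ["Na", "O"],
            charges=[1.0, 1.0], epsilons=[0.0, 0.0], sigmas=[1.0, 1.0],
        )
        frame = _frame([[0, 0, 0], [10.0, 0, 0]])
        e = hydration.interaction_energy(frame, atoms)
        assert e == pytest.approx(138.935485, abs=1e-9)

    def test_lj_minimum_closed_form(self):
        eps, sig = 0.8, 3.0
        atoms = _atoms(
            ["C1", "OW"], ["UNK", "SOL"], [1, 2], ["C", "O"],
            charges=[0.0, 0.0], epsilons=[eps, eps], sigmas=[sig, sig],
        )
        r_min = 2.0 ** (1.0 / 6.0) * sig
        frame = _frame([[0, 0, 0], [r_min, 0, 0]])
        e = hydration.interaction_energy(frame, atoms)
        assert e == pytest.approx(-eps, abs=1e-12)

    def test_cutoff_truncates(self):
        atoms = _atoms(
            ["NA", "OW"], ["UNK", "SOL"], [1, 2], ["Na", "O"],
            charges=[1.0, 1.0], epsilons=[0.0, 0.0], sigmas=[1.0, 1.0],
        )
        frame = _frame([[0, 0, 0], [12.5, 0, 0]])
        assert hydration.interaction_energy(frame, atoms) == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        n = 40
        elements = ["O" if i % 3 else "C" for i in range(n)]
        resnames = ["SOL" if i >= n // 2 else "GLY" for i in range(n)]
        atoms = _atoms(
            [f"A{i}" for i in range(n)], resnames, list(range(1, n + 1)),
            elements,
            charges=rng.uniform(-0.8, 0.8, n),
            epsilons=rng.uniform(0.1, 1.0, n),
            sigmas=rng.uniform(2.5, 3.5, n),
        )
        box = np.array([18.0, 18.0, 18.0])
        for _ in range(5):
            coords = rng.uniform(0, 18.0, (n, 3))
            frame = _frame(coords, box=box)
            mine = hydration.interaction_energy(frame, atoms)
            ref = interaction_energy_double_loop(
                coords, elements,
                atoms["charge"].to_list(), atoms["epsilon"].to_list(),
                atoms["sigma"].to_list(), atoms["is_water"].to_list(), box,
            )
            assert mine == pytest.approx(ref, rel=1e-10)

    def test_missing_parameters_rejected(self):
        atoms = _atoms(["C1", "OW"], ["UNK", "SOL"], [1, 2], ["C", "O"])
        atoms.loc[0, "charge"] = np.nan
        frame = _frame([[0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(hydration.TypingError):
            hydration.interaction_energy(frame, atoms)


class TestRdf:
    def _uniform_traj(self, rng, n_ref=50, n_tgt=150, box_edge=24.0, n_frames=30):
        names = [f"R{i}" for i in range(n_ref)] + [f"OW{i}" for i in range(n_tgt)]
        resnames = ["GLY"] * n_ref + ["SOL"] * n_tgt
        respos = list(range(1, n_ref + 1)) + [n_ref + 1 + i for i in range(n_tgt)]
        elements = ["C"] * n_ref + ["O"] * n_tgt
        atoms = _atoms(names, resnames, respos, elements)
        box = np.array([box_edge] * 3)
        frames = [
            _frame(rng.uniform(0, box_edge, (n_ref + n_tgt, 3)), box=box)
            for _ in range(n_frames)
        ]
        return tio.Trajectory(atoms, frames)

    def test_uniform_gas_gives_unity(self):
        traj = self._uniform_traj(np.random.default_rng(5), n_frames=40)
        table = hydration.rdf(traj, "protein", "water", bin_width=0.5, r_max=10.0)
        bulk = table.bin_centers > 3.0
        # individual bins fluctuate with counting noise; their mean is tight
        assert np.all(np.abs(table.g[bulk] - 1.0) < 0.1)
        assert np.mean(table.g[bulk]) == pytest.approx(1.0, abs=0.02)

    def test_r_max_beyond_half_box_rejected(self):
        traj = self._uniform_traj(np.random.default_rng(5), n_frames=1)
        with pytest.raises(ValueError):
            hydration.rdf(traj, "protein", "water", bin_width=0.5, r_max=14.0)

    def test_delta_shell_peak_position(self):
        # all target atoms at 4.05 A (mid-bin) from the single reference atom
        n_tgt = 30
        atoms = _atoms(
            ["CA"] + [f"OW{i}" for i in range(n_tgt)],
            ["GLY"] + ["SOL"] * n_tgt,
            [1] + list(range(2, n_tgt + 2)),
            ["C"] + ["O"] * n_tgt,
        )
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(n_tgt, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        center = np.array([15.0, 15.0, 15.0])
        coords = np.vstack([center, center + 4.05 * dirs])
        traj = tio.Trajectory(atoms, [_frame(coords, box=np.array([30.0] * 3))])
        table = hydration.rdf(traj, "protein", "water", bin_width=0.2, r_max=10.0)
        assert table.argmax_center() == pytest.approx(4.1, abs=0.100001)
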