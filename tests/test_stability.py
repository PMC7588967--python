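import numpy as np
import pytest

import ksbind
from ksbind import NoNativeContactsError, StabilitySeries
from ksbind.stability import detect_exit, mean_ss, production_window

from conftest import brute_force_native_pairs, brute_force_ss


class TestHeavyAtomSelection:
    def test_hydrogen_and_deuterium_excluded(self, make_atom):
        atoms = [
            make_atom(1, (0, 0, 0), element="C"),
            make_atom(2, (1, 0, 0), element="C"),
            make_atom(3, (2, 0, 0), element="H"),
            make_atom(4, (3, 0, 0), element="D"),
            make_atom(5, (4, 0, 0), element="O"),
            make_atom(6, (5, 0, 0), element="N"),
        ]
        structure = ksbind.Structure(atoms=atoms)
        idx = ksbind.select_heavy_atoms(structure, "all")
        assert list(idx) == [0, 1, 4, 5]

    def test_empty_selection_errors(self, make_atom):
        structure = ksbind.Structure(atoms=[make_atom(1, (0, 0, 0), element="H")])
        with pytest.raises(ValueError, match="no heavy atoms"):
            ksbind.select_heavy_atoms(structure, "all")

    def test_selection_by_residue(self, make_atom):
        atoms = [
            make_atom(i, (i, 0, 0), resnum=n, chain="A")
            for i, n in enumerate([38, 38, 65, 93, 94], start=1)
        ]
        structure = ksbind.Structure(atoms=atoms)
        idx = ksbind.select_heavy_atoms(structure, "chain A and resid 38,65,93")
        assert list(idx) == [0, 1, 2, 3]


class TestNativePairs:
    def test_worked_toy_pairs(self, toy_five_atom_trajectory):
        traj, receptor, ligand = toy_five_atom_trajectory
        pairs = ksbind.native_pairs(traj, receptor, ligand)
        assert sorted(map(tuple, pairs.pairs)) == [(0, 3), (1, 3)]
        # oracle: all 6 cross distances enumerated by hand
        expected = brute_force_native_pairs(traj.frames[0], receptor, ligand, 7.0)
        assert sorted(map(tuple, pairs.pairs)) == sorted(expected)

    def test_distant_ligand_gives_empty_set(self, toy_five_atom_trajectory, make_atom):
        traj, receptor, ligand = toy_five_atom_trajectory
        far = traj.frames[0].copy()
        far[[3, 4]] += 100.0
        traj2 = ksbind.Trajectory(topology=traj.topology, frames=[far])
        pairs = ksbind.native_pairs(traj2, receptor, ligand)
        assert len(pairs) == 0

    def test_exact_cutoff_included(self, make_atom):
        atoms = [
            make_atom(1, (0, 0, 0)),
            make_atom(2, (7.0, 0, 0), resname="LIG", chain="B"),
        ]
        structure = ksbind.Structure(atoms=atoms)
        traj = ksbind.Trajectory(topology=structure, frames=[structure.coordinates])
        pairs = ksbind.native_pairs(traj, np.array([0]), np.array([1]))
        assert len(pairs) == 1

    def test_overlapping_selections_rejected(self, toy_five_atom_trajectory):
        traj, receptor, _ = toy_five_atom_trajectory
        with pytest.raises(ValueError, match="disjoint"):
            ksbind.native_pairs(traj, receptor, receptor)


class TestStabilitySeries:
    def test_worked_toy_sequence(self, toy_five_atom_trajectory):
        traj, receptor, ligand = toy_five_atom_trajectory
        pairs = ksbind.native_pairs(traj, receptor, ligand)
        series = ksbind.stability_series(traj, pairs)
        np.testing.assert_array_equal(series.values, [1.0, 0.5])

    def test_reference_frame_scores_one(self):
        complex_ = ksbind.make_toy_complex(12, 3, seed=7)
        traj = ksbind.simulate_bound_trajectory(
            complex_, ksbind.SyntheticSpec(seed=7, n_frames=10)
        )
        pairs = ksbind.native_pairs(traj, complex_.receptor_indices, complex_.ligand_indices)
        series = ksbind.stability_series(traj, pairs)
        assert series.values[0] == 1.0

    def test_translated_ligand_scores_zero(self, toy_five_atom_trajectory):
        traj, receptor, ligand = toy_five_atom_trajectory
        gone = traj.frames[0].copy()
        gone[[3, 4]] += 100.0
        traj2 = ksbind.Trajectory(topology=traj.topology, frames=[traj.frames[0], gone])
        pairs = ksbind.native_pairs(traj2, receptor, ligand)
        series = ksbind.stability_series(traj2, pairs)
        assert series.values[1] == 0.0

    def test_empty_pair_set_is_defined_error(self, toy_five_atom_trajectory):
        traj, _, _ = toy_five_atom_trajectory
        empty = ksbind.NativePairSet(pairs=np.empty((0, 2), dtype=int))
        with pytest.raises(NoNativeContactsError, match="SS undefined"):
            ksbind.stability_series(traj, empty)

    def test_matches_brute_force_oracle_on_random_systems(self, make_atom):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_rec = int(rng.integers(2, 20))
            n_lig = int(rng.integers(1, 10))
            n_frames = int(rng.integers(1, 20))
            coords0 = rng.uniform(-10, 10, (n_rec + n_lig, 3))
            frames = [coords0] + [
                coords0 + rng.normal(0, 3, coords0.shape) for _ in range(n_frames - 1)
            ]
            atoms = [make_atom(i + 1, coords0[i]) for i in range(n_rec + n_lig)]
            traj = ksbind.Trajectory(topology=ksbind.Structure(atoms=atoms), frames=frames)
            receptor = np.arange(n_rec)
            ligand = np.arange(n_rec, n_rec + n_lig)
            pairs = ksbind.native_pairs(traj, receptor, ligand)
            if len(pairs) == 0:
                continue
            series = ksbind.stability_series(traj, pairs)
            oracle = brute_force_ss(frames, pairs.pairs, 7.0)
            np.testing.assert_array_equal(series.values, oracle)

    def test_rigid_transform_invariance(self):
        complex_ = ksbind.make_toy_complex(15, 4, seed=11)
        traj = ksbind.simulate_bound_trajectory(
            complex_, ksbind.SyntheticSpec(seed=11, n_frames=15)
        )
        pairs = ksbind.native_pairs(traj, complex_.receptor_indices, complex_.ligand_indices)
        base = ksbind.stability_series(traj, pairs)

        rng = np.random.default_rng(5)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = 1.1
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
        shift = np.array([12.0, -3.0, 44.0])
        moved = ksbind.Trajectory(
            topology=traj.topology, frames=[f @ R.T + shift for f in traj.frames]
        )
        transformed = ksbind.stability_series(moved, pairs)
        np.testing.assert_allclose(transformed.values, base.values, atol=1e-9)

    def test_bounds_invariant(self):
        for seed in range(5):
            complex_ = ksbind.make_toy_complex(10, 3, seed=seed)
            traj = ksbind.simulate_unbinding_trajectory(
                complex_, ksbind.SyntheticSpec(seed=seed, n_frames=80, exit_frame=30)
            )
            pairs = ksbind.native_pairs(
                traj, complex_.receptor_indices, complex_.ligand_indices
            )
            values = ksbind.stability_series(traj, pairs).values
            assert values[0] == 1.0
            assert np.all((values >= 0) & (values <= 1))


class TestProductionWindow:
    def test_default_is_last_half(self):
        series = StabilitySeries(values=np.linspace(1, 0, 200))
        window = production_window(series)
        assert len(window) == 100
        np.testing.assert_array_equal(window.values, series.values[100:])

    def test_zero_fraction_is_identity(self):
        series = StabilitySeries(values=np.ones(10))
        np.testing.assert_array_equal(production_window(series, 0.0).values, series.values)

    def test_floor_arithmetic(self):
        series = StabilitySeries(values=np.arange(7) / 7.0)
        window = production_window(series, 0.5)
        np.testing.assert_array_equal(window.values, series.values[3:])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            production_window(StabilitySeries(values=np.array([1.0])))


class TestMeanAndExit:
    def test_mean_matches_naive_sum(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, 100)
        series = StabilitySeries(values=values)
        naive = sum(float(v) for v in values) / len(values)
        assert mean_ss(series) == pytest.approx(naive, abs=1e-12)

    def test_constant_series(self):
        assert mean_ss(StabilitySeries(values=np.ones(5))) == 1.0
        assert mean_ss(StabilitySeries(values=np.array([1.0, 0.0]))) == 0.5

    def test_bound_trajectory_never_exits(self):
        complex_ = ksbind.make_toy_complex(20, 4, seed=2)
        traj = ksbind.simulate_bound_trajectory(complex_, ksbind.SyntheticSpec(seed=2))
        pairs = ksbind.native_pairs(traj, complex_.receptor_indices, complex_.ligand_indices)
        series = ksbind.stability_series(traj, pairs)
        assert detect_exit(series) is None

    def test_sustained_drop_detected_at_onset(self):
        values = np.ones(100)
        values[50:] = 0.0
        assert detect_exit(StabilitySeries(values=values)) == 50

    def test_transient_dip_ignored(self):
        values = np.ones(100)
        values[40:43] = 0.0  # 3-frame dip, sustain window is 10
        assert detect_exit(StabilitySeries(values=values), sustain_frames=10) is None

    def test_terminal_dip_shorter_than_window(self):
        values = np.ones(30)
        values[25:] = 0.0
        assert detect_exit(StabilitySeries(values=values), sustain_frames=10) is None

    def test_sustain_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_exit(StabilitySeries(values=np.ones(5)), sustain_frames=0)


def test_monotone_degradation_on_unbinding():
    """Any positive drift makes post-exit mean SS strictly lower than pre-exit."""
    for drift in (0.2, 0.5, 1.0, 2.0):
        complex_ = ksbind.make_toy_complex(20, 4, seed=9)
        spec = ksbind.SyntheticSpec(
            seed=9, n_frames=100, exit_frame=40, drift_rate_A_per_frame=drift
        )
        traj = ksbind.simulate_unbinding_trajectory(complex_, spec)
        pairs = ksbind.native_pairs(traj, complex_.receptor_indices, complex_.ligand_indices)
        values = ksbind.stability_series(traj, pairs).values
        assert values[40:].mean() < values[:40].mean()
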