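"""Trajectory descriptors: RMSD/RMSF, distances, H-bonds, dihedrals, windows."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lidkit.io import Trajectory, select
from lidkit.synthetic import (
    SyntheticSpec,
    make_toy_chain,
    orthogonalize_to_rigid,
    plant_hbond_series,
    random_orthonormal_modes,
    simulate_modes_trajectory,
)
from lidkit.traj import (
    AtomSpec,
    DistanceSeries,
    HBondCriterion,
    com_distance_series,
    dihedral_series,
    distance_series,
    end_to_end_series,
    hbond_series,
    rmsd_series,
    rmsf,
    segment_stats,
    to_nm,
)

from conftest import ca_only_structure


def static_trajectory(structure, n_frames):
    return Trajectory(
        topology=structure,
        frames=np.repeat(structure.coords[None], n_frames, axis=0),
    )


class TestRMSD:
    def test_copies_of_reference_are_zero(self, toy_chain):
        traj = static_trajectory(toy_chain, 5)
        np.testing.assert_allclose(rmsd_series(traj, toy_chain), 0.0, atol=1e-12)

    def test_rigid_motion_is_zero_after_superposition(self, toy_chain):
        rng = np.random.default_rng(0)
        frames = []
        for _ in range(6):
            rot = Rotation.random(random_state=int(rng.integers(1e6))).as_matrix()
            frames.append(toy_chain.coords @ rot.T + rng.normal(size=3) * 10)
        traj = Trajectory(topology=toy_chain, frames=np.array(frames))
        np.testing.assert_allclose(rmsd_series(traj, toy_chain), 0.0, atol=1e-9)

    def test_three_frame_hand_oracle(self, toy_chain):
        ca = select(toy_chain, atom_names={"CA"})
        rng = np.random.default_rng(1)
        perturbations = [rng.normal(scale=s, size=ca.coords.shape) for s in (0.1, 0.5, 1.0)]
        frames = np.array([ca.coords + p for p in perturbations])
        traj = Trajectory(topology=ca, frames=frames)
        got = rmsd_series(traj, ca)
        from lidkit.io import kabsch_superpose

        for f in range(3):
            _, _, expected = kabsch_superpose(frames[f], ca.coords)
            assert got[f] == pytest.approx(expected, abs=1e-9)

    def test_selection_mismatch_raises(self, toy_chain, lid_chain):
        traj = static_trajectory(toy_chain, 2)
        with pytest.raises(ValueError, match="selection maps"):
            rmsd_series(traj, lid_chain, selection={"atom_names": {"CA"}})


class TestRMSF:
    def test_static_trajectory_is_zero(self, toy_chain):
        traj = static_trajectory(toy_chain, 10)
        np.testing.assert_allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_static_plus_rigid_motion_is_zero(self, toy_chain):
        rng = np.random.default_rng(2)
        frames = []
        for _ in range(8):
            rot = Rotation.random(random_state=int(rng.integers(1e6))).as_matrix()
            frames.append(toy_chain.coords @ rot.T + rng.normal(size=3) * 5)
        traj = Trajectory(topology=toy_chain, frames=np.array(frames))
        np.testing.assert_allclose(rmsf(traj, superpose=True), 0.0, atol=1e-9)

    def test_single_alternating_atom_analytic(self, toy_chain):
        ca = select(toy_chain, atom_names={"CA"})
        delta = 0.7
        frames = np.repeat(ca.coords[None], 4, axis=0)
        frames[::2, 5, 0] += delta
        frames[1::2, 5, 0] -= delta
        traj = Trajectory(topology=ca, frames=frames)
        prof = rmsf(traj, superpose=False)
        assert prof[5] == pytest.approx(delta, abs=1e-12)
        others = np.delete(prof, 5)
        np.testing.assert_allclose(others, 0.0, atol=1e-12)

    def test_recovers_planted_mode_sigmas(self):
        ref = make_toy_chain(30, seed=9)
        modes = random_orthonormal_modes(
            30, 3, np.random.default_rng(10), exclude_rigid_of=ref
        )
        sigmas = np.array([1.5, 0.8, 0.4])
        spec = SyntheticSpec(
            n_residues=30, mode_vectors=modes, mode_sigmas=sigmas,
            n_frames=10_000, seed=11,
        )
        traj, _ = simulate_modes_trajectory(ref, spec)
        prof = rmsf(traj, selection={"atom_names": {"CA"}})
        per_atom = np.sqrt(
            ((modes.reshape(3, 30, 3) ** 2).sum(axis=2) * sigmas[:, None] ** 2).sum(axis=0)
        )
        np.testing.assert_allclose(prof, per_atom, rtol=0.05)

    def test_single_frame_rejected(self, toy_chain):
        with pytest.raises(ValueError):
            rmsf(static_trajectory(toy_chain, 1))


class TestDistanceSeries:
    def test_constant_pair(self, toy_chain):
        ca = select(toy_chain, atom_names={"CA"})
        coords = ca.coords.copy()
        coords[1] = coords[0] + [10.0, 0, 0]
        traj = Trajectory(
            topology=ca, frames=np.repeat(coords[None], 7, axis=0)
        )
        ds = distance_series(traj, AtomSpec("A", 1, "CA"), AtomSpec("A", 2, "CA"))
        assert ds.mean == pytest.approx(10.0)
        assert ds.sd == 0.0 and ds.range_dd == 0.0

    def test_stats_match_independent_recomputation(self, toy_chain):
        rng = np.random.default_rng(3)
        frames = toy_chain.coords[None] + rng.normal(scale=0.5, size=(100, toy_chain.n_atoms, 3))
        traj = Trajectory(topology=toy_chain, frames=frames)
        ds = distance_series(traj, AtomSpec("A", 3, "CA"), AtomSpec("A", 40, "CA"))
        i = toy_chain.atom_index("A", 3, "CA")
        j = toy_chain.atom_index("A", 40, "CA")
        oracle = np.array(
            [np.sqrt(((frames[f, i] - frames[f, j]) ** 2).sum()) for f in range(100)]
        )
        assert ds.mean == pytest.approx(oracle.sum() / 100, abs=1e-12)
        assert ds.sd == pytest.approx(np.sqrt(((oracle - oracle.mean()) ** 2).sum() / 99), abs=1e-12)
        assert ds.range_dd == pytest.approx(oracle.max() - oracle.min(), abs=1e-12)

    def test_com_distance_matches_hand_computation(self, lid_chain):
        traj = static_trajectory(lid_chain, 2)
        ds = com_distance_series(
            traj, AtomSpec("A", 140, "CA"), chain="A", resid_range=(121, 131)
        )
        sub = select(lid_chain, chain="A", resid_range=(121, 131))
        w = sub.masses
        com = (sub.coords * w[:, None]).sum(axis=0) / w.sum()
        ca140 = lid_chain.coords[lid_chain.atom_index("A", 140, "CA")]
        assert ds.values[0] == pytest.approx(np.linalg.norm(ca140 - com), abs=1e-12)

    def test_nm_conversion(self):
        assert to_nm(14.93) == pytest.approx(1.493)


class TestHBonds:
    def test_linear_within_cutoffs_present(self):
        traj, _ = plant_hbond_series(np.array([True]))
        hs = hbond_series(
            traj, AtomSpec("A", 1, "N"), AtomSpec("A", 2, "O"), AtomSpec("A", 1, "H")
        )
        assert hs.occupancy == 1.0

    def test_long_distance_absent(self):
        traj, _ = plant_hbond_series(np.array([False]), violation="distance")
        hs = hbond_series(
            traj, AtomSpec("A", 1, "N"), AtomSpec("A", 2, "O"), AtomSpec("A", 1, "H")
        )
        assert hs.occupancy == 0.0

    def test_planted_occupancy_is_exact(self):
        rng = np.random.default_rng(12)
        plan = rng.random(1000) < 0.4
        traj, truth = plant_hbond_series(plan)
        hs = hbond_series(
            traj, AtomSpec("A", 1, "N"), AtomSpec("A", 2, "O"), AtomSpec("A", 1, "H")
        )
        assert hs.occupancy == truth == plan.mean()

    def test_angle_violation_passes_distance_only_mode(self):
        plan = np.array([False] * 10)
        traj, _ = plant_hbond_series(plan, violation="angle")
        with_h = hbond_series(
            traj, AtomSpec("A", 1, "N"), AtomSpec("A", 2, "O"), AtomSpec("A", 1, "H")
        )
        without_h = hbond_series(traj, AtomSpec("A", 1, "N"), AtomSpec("A", 2, "O"))
        assert with_h.occupancy == 0.0
        assert without_h.occupancy == 1.0

    def test_disjoint_occupancies_add(self):
        rng = np.random.default_rng(13)
        a = np.zeros(500, bool)
        a[:150] = True
        b = np.zeros(500, bool)
        b[150:350] = True
        traj_a, _ = plant_hbond_series(a)
        traj_b, _ = plant_hbond_series(b)
        spec = (AtomSpec("A", 1, "N"), AtomSpec("A", 2, "O"), AtomSpec("A", 1, "H"))
        occ_a = hbond_series(traj_a, spec[0], spec[1], spec[2]).occupancy
        occ_b = hbond_series(traj_b, spec[0], spec[1], spec[2]).occupancy
        union_traj, _ = plant_hbond_series(a | b)
        occ_union = hbond_series(union_traj, spec[0], spec[1], spec[2]).occupancy
        assert occ_union == pytest.approx(occ_a + occ_b, abs=1e-12)


class TestEndToEnd:
    def build_carbon_chain(self, folded):
        from lidkit.io import AtomRecord, Structure

        bond, angle = 1.53, np.radians(111.0)
        pts = [np.zeros(3)]
        direction = np.array([1.0, 0.0, 0.0])
        for i in range(11):
            if folded and i == 5:
                direction = np.array([-1.0, 0.2, 0.0])
                direction /= np.linalg.norm(direction)
            step = direction * bond
            # zig-zag in y
            step[1] += (bond * np.cos(angle)) * (-1) ** i
            pts.append(pts[-1] + step)
        atoms = [
            AtomRecord(i + 1, f"C{i + 1}", "", "LIG", "A", 1, p, element="C")
            for i, p in enumerate(pts)
        ]
        return Structure(atoms)

    def test_extended_chain_matches_geometric_sum(self):
        s = self.build_carbon_chain(folded=False)
        traj = static_trajectory(s, 3)
        ds = end_to_end_series(traj, AtomSpec("A", 1, "C1"), AtomSpec("A", 1, "C12"))
        expected = np.linalg.norm(s.coords[-1] - s.coords[0])
        np.testing.assert_allclose(ds.values, expected, atol=1e-12)

    def test_folded_is_shorter_than_extended(self):
        ext = self.build_carbon_chain(folded=False)
        fold = self.build_carbon_chain(folded=True)
        spec = (AtomSpec("A", 1, "C1"), AtomSpec("A", 1, "C12"))
        d_ext = end_to_end_series(static_trajectory(ext, 1), *spec).values[0]
        d_fold = end_to_end_series(static_trajectory(fold, 1), *spec).values[0]
        assert d_fold < d_ext


class TestDihedralSeries:
    def test_matches_static_dihedral(self, toy_chain):
        from lidkit.io import dihedral

        traj = static_trajectory(toy_chain, 3)
        series = dihedral_series(
            traj,
            AtomSpec("A", 10, "N"),
            AtomSpec("A", 10, "CA"),
            AtomSpec("A", 10, "CB"),
            AtomSpec("A", 10, "CG"),
        )
        pts = [
            toy_chain.coords[toy_chain.atom_index("A", 10, nm)]
            for nm in ("N", "CA", "CB", "CG")
        ]
        np.testing.assert_allclose(series, dihedral(*pts), atol=1e-12)


class TestSegmentStats:
    def test_constant_series(self):
        ds = DistanceSeries("x", np.full(50, 4.2), times=np.arange(50, dtype=float))
        (w,) = segment_stats(ds, [(10.0, 30.0)])
        assert w["mean"] == pytest.approx(4.2)
        assert w["sd"] == pytest.approx(0.0, abs=1e-12)
        assert w["n_frames"] == 20  # [10, 30) inclusive-exclusive

    def test_tiling_windows_partition_frames(self):
        ds = DistanceSeries("x", np.arange(100, dtype=float) + 1.0)
        wins = segment_stats(ds, [(0, 37), (37, 100)])
        assert wins[0]["n_frames"] + wins[1]["n_frames"] == 100

    def test_alternating_series_closed_form(self):
        vals = np.tile([1.0, 3.0], 10)
        ds = DistanceSeries("x", vals)
        (w,) = segment_stats(ds, [(0, 20)])
        assert w["mean"] == pytest.approx(2.0)
        # sample sd of n/2 ones and n/2 threes: sqrt(n/(n-1))
        assert w["sd"] == pytest.approx(np.sqrt(20 / 19), abs=1e-12)

    def test_empty_window_raises(self):
        ds = DistanceSeries("x", np.ones(5))
        with pytest.raises(ValueError, match="no frames"):
            segment_stats(ds, [(10, 20)])
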