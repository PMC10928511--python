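"""Superposition, RMSF, mobility testing, ligand RMSD and pose clustering."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lipsite.core import Bead, Residue, SystemTopology, Trajectory, ConfigError
from lipsite.structure_metrics import (DegenerateGeometryError, RMSFProfile,
                                       cluster_poses, differential_mobility,
                                       kabsch_superpose, ligand_rmsd_series,
                                       motif_pocket_distance,
                                       region_contact_frequency, rmsf_profile)

from conftest import build_system


def random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31))).as_matrix()
    t = rng.uniform(-5, 5, 3)
    return R, t


class TestKabschSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).uniform(0, 5, (6, 3))
        R, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_pure_translation_removed(self):
        pts = np.random.default_rng(1).uniform(0, 5, (5, 3))
        R, t, rmsd = kabsch_superpose(pts + np.array([1.0, 2.0, 3.0]), pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-3, 3, (8, 3))
        Y = X + rng.normal(0, 0.1, X.shape)
        _, _, base = kabsch_superpose(X, Y)
        for _ in range(5):
            R, t = random_rigid(rng)
            _, _, moved = kabsch_superpose(X @ R.T + t, Y)
            assert moved == pytest.approx(base, abs=1e-9)

    def test_proper_rotation_even_for_mirrored_input(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-2, 2, (10, 3))
        Y = X.copy()
        Y[:, 0] *= -1  # reflection
        R, _, _ = kabsch_superpose(X, Y)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_quaternion_oracle(self):
        """Post-fit RMSD agrees with the independent QCP quaternion method."""
        from MDAnalysis.lib.qcprot import CalcRMSDRotationalMatrix
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(4, 12)
            X = rng.uniform(-4, 4, (n, 3))
            Y = X + rng.normal(0, rng.uniform(0.05, 1.0), X.shape)
            _, _, ours = kabsch_superpose(X, Y)
            rot = np.zeros(9)
            qcp = CalcRMSDRotationalMatrix(
                (Y - Y.mean(0)).astype(np.float64),
                (X - X.mean(0)).astype(np.float64), n, rot, None)
            assert ours == pytest.approx(qcp, abs=1e-8)

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)

    def test_too_few_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1.0, 1, 1]])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(pts, pts)


def _protein_only_system(frames_nm, n_res):
    """Topology of n_res single-backbone-bead residues + a parked lipid."""
    residues = [Residue(residue_id=i + 1, name="ALA",
                        beads=(Bead(i, "BB", "backbone"),))
                for i in range(n_res)]
    from lipsite.core import Lipid
    lipids = [Lipid(lipid_id=n_res + 1, species="POPC",
                    headgroup_bead_indices=(n_res,),
                    all_bead_indices=(n_res,), leaflet="lower",
                    resname="POPC")]
    topo = SystemTopology(residues=residues, lipids=lipids,
                          species_to_class={"POPC": "PC"},
                          bead_names=tuple(["BB"] * n_res + ["PO4"]))
    topo.validate()
    n_frames = frames_nm.shape[0]
    coords = np.concatenate(
        [frames_nm, np.full((n_frames, 1, 3), 9.0)], axis=1)
    traj = Trajectory(times=np.arange(n_frames, dtype=float),
                      coordinates=coords,
                      box=np.tile([20.0, 20.0, 20.0], (n_frames, 1)))
    traj.validate()
    return topo, traj


class TestRMSFProfile:
    def _static_frames(self, n_frames, n_res, rng=None):
        base = np.random.default_rng(0).uniform(0, 5, (n_res, 3))
        return np.tile(base, (n_frames, 1, 1))

    def test_static_trajectory_is_zero(self):
        topo, traj = _protein_only_system(self._static_frames(10, 5), 5)
        prof = rmsf_profile(traj, topo)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-9)

    def test_two_point_alternation(self):
        # one bead alternating x = 0 / x = 0.2 nm -> RMSF 0.1 nm = 1 A
        frames = self._static_frames(10, 5).copy()
        frames[1::2, 4, 0] += 0.2
        topo, traj = _protein_only_system(frames, 5)
        prof = rmsf_profile(traj, topo, align_residues=[1, 2, 3, 4])
        assert prof.rmsf[4] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(prof.rmsf[:4], 0.0, atol=1e-9)

    def test_isotropic_jitter_gives_sigma_root3(self):
        rng = np.random.default_rng(6)
        n_frames, sigma_nm = 10000, 0.05
        frames = self._static_frames(n_frames, 5).copy()
        frames[:, 4] += rng.normal(0, sigma_nm, (n_frames, 3))
        topo, traj = _protein_only_system(frames, 5)
        prof = rmsf_profile(traj, topo, align_residues=[1, 2, 3, 4])
        expect = sigma_nm * np.sqrt(3) * 10  # A
        assert prof.rmsf[4] == pytest.approx(expect, rel=0.05)

    def test_global_rigid_motion_removed(self):
        rng = np.random.default_rng(7)
        frames = self._static_frames(20, 6).copy()
        moved = np.empty_like(frames)
        for f in range(frames.shape[0]):
            R, t = random_rigid(rng)
            moved[f] = frames[f] @ R.T + t
        topo, traj = _protein_only_system(moved, 6)
        prof = rmsf_profile(traj, topo)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-7)

    def test_needs_two_frames(self):
        topo, traj = _protein_only_system(self._static_frames(1, 4), 4)
        with pytest.raises(ConfigError):
            rmsf_profile(traj, topo)


def _profiles(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = np.arange(values.shape[1]) if ids is None else np.asarray(ids)
    return [RMSFProfile(residue_ids=ids, rmsf=row, replicate_id=str(i))
            for i, row in enumerate(values)]


class TestDifferentialMobility:
    def test_identical_arms_give_p_one(self):
        arm = [[1.0, 2.0], [1.2, 2.2], [0.8, 1.8]]
        out = differential_mobility(_profiles(arm), _profiles(arm))
        np.testing.assert_allclose(out["t_stat"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p_value"], 1.0, atol=1e-12)
        assert not out["significant"].any()

    def test_planted_large_shift_is_flagged(self):
        rng = np.random.default_rng(8)
        base = rng.normal(2.0, 0.1, (5, 3))
        shifted = base.copy()
        shifted[:, 0] += 1.0  # 10 pooled standard deviations
        out = differential_mobility(_profiles(shifted), _profiles(base))
        assert out.loc[0, "p_value"] < 1e-3
        assert bool(out.loc[0, "significant"])

    def test_type_one_error_calibration(self):
        """Under the null, the flagged fraction at alpha=0.05 stays inside
        binomial 99% bounds (1000 independent synthetic residues)."""
        rng = np.random.default_rng(9)
        n_res = 1000
        A = rng.normal(2.0, 0.3, (5, n_res))
        B = rng.normal(2.0, 0.3, (5, n_res))
        out = differential_mobility(_profiles(A), _profiles(B), alpha=0.05)
        frac = out["significant"].mean()
        bound = 2.576 * np.sqrt(0.05 * 0.95 / n_res)
        assert abs(frac - 0.05) <= bound

    def test_mismatched_residues_rejected(self):
        with pytest.raises(ConfigError):
            differential_mobility(_profiles([[1.0, 2], [1, 2]], ids=[1, 2]),
                                  _profiles([[1.0, 2], [1, 2]], ids=[1, 3]))


class TestLigandRMSD:
    def _system(self):
        rng = np.random.default_rng(10)
        prot = rng.uniform(0, 3, (5, 3))
        lig = np.array([[4.0, 4.0, 4.0], [4.2, 4.0, 4.0]])
        return prot, lig

    def _traj(self, frames):
        return Trajectory(times=np.arange(len(frames), dtype=float),
                          coordinates=np.asarray(frames),
                          box=np.tile([20.0, 20, 20], (len(frames), 1)))

    def test_reference_frame_is_zero(self):
        prot, lig = self._system()
        frame = np.concatenate([prot, lig])
        traj = self._traj([frame, frame])
        out = ligand_rmsd_series(traj, [5, 6], [0, 1, 2, 3, 4])
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_global_translation_removed(self):
        prot, lig = self._system()
        f0 = np.concatenate([prot, lig])
        f1 = f0 + np.array([1.0, -2.0, 0.5])
        out = ligand_rmsd_series(self._traj([f0, f1]), [5, 6],
                                 [0, 1, 2, 3, 4])
        assert out[1] == pytest.approx(0.0, abs=1e-7)

    def test_pure_ligand_displacement(self):
        prot, lig = self._system()
        f0 = np.concatenate([prot, lig])
        f1 = f0.copy()
        f1[5:, 0] += 0.1  # 0.1 nm = 1 A along x, protein fixed
        out = ligand_rmsd_series(self._traj([f0, f1]), [5, 6],
                                 [0, 1, 2, 3, 4])
        assert out[1] == pytest.approx(1.0, abs=1e-7)


class TestClusterPoses:
    def test_all_identical_frames_one_cluster(self):
        pose = np.random.default_rng(11).uniform(0, 5, (4, 3))
        coords = np.tile(pose, (6, 1, 1))
        pc = cluster_poses(coords, cutoff=1.0)
        assert len(pc.clusters) == 1
        assert len(pc.clusters[0]) == 6

    def test_planted_7_3_partition(self):
        rng = np.random.default_rng(12)
        pose_a = rng.uniform(0, 5, (5, 3))
        R, t = random_rigid(rng)
        pose_b = pose_a @ R.T + t + rng.normal(0, 3.0, pose_a.shape)
        frames = [pose_a + rng.normal(0, 0.05, pose_a.shape) for _ in range(7)]
        frames += [pose_b + rng.normal(0, 0.05, pose_b.shape) for _ in range(3)]
        pc = cluster_poses(np.array(frames), cutoff=1.0)
        assert len(pc.clusters[0]) == 7
        assert pc.representative in pc.clusters[0]
        assert set(pc.clusters[0].tolist()) == set(range(7))

    def test_single_frame(self):
        pc = cluster_poses(np.random.default_rng(0).uniform(0, 1, (1, 4, 3)),
                           cutoff=2.0)
        assert len(pc.clusters) == 1
        assert pc.representative == 0

    def test_cutoff_limits(self):
        rng = np.random.default_rng(13)
        frames = rng.uniform(0, 8, (5, 4, 3))
        wide = cluster_poses(frames, cutoff=1e9)
        assert len(wide.clusters) == 1
        narrow = cluster_poses(frames, cutoff=1e-9)
        assert len(narrow.clusters) == 5

    def test_partition_property(self):
        rng = np.random.default_rng(14)
        frames = rng.uniform(0, 4, (12, 5, 3))
        pc = cluster_poses(frames, cutoff=3.0)
        members = np.sort(np.concatenate(pc.clusters))
        np.testing.assert_array_equal(members, np.arange(12))


class TestRegionContactFrequency:
    @pytest.mark.parametrize("dist,expect", [(0.40, 1.0), (0.50, 0.0)])
    def test_constant_distance(self, dist, expect):
        topo, traj = build_system([[1.0, 1.0, 1.0]],
                                  [[[1.0 + dist, 1.0, 1.0]]] * 4)
        lip_bead = topo.lipids[0].headgroup_bead_indices[0]
        out = region_contact_frequency(traj, topo, {"P4": [lip_bead]}, [1],
                                       cutoff=0.45)
        assert out["fraction"].iloc[0] == pytest.approx(expect)

    def test_half_frames_below(self):
        near, far = [[1.4, 1.0, 1.0]], [[3.0, 3.0, 3.0]]
        topo, traj = build_system([[1.0, 1.0, 1.0]], [near, far, near, far])
        lip_bead = topo.lipids[0].headgroup_bead_indices[0]
        out = region_contact_frequency(traj, topo, {"PO4": [lip_bead]}, [1],
                                       cutoff=0.45)
        assert out["fraction"].iloc[0] == pytest.approx(0.5)

    def test_empty_region_rejected(self):
        topo, traj = build_system([[1, 1, 1]], [[[2, 2, 2]]])
        with pytest.raises(ConfigError):
            region_contact_frequency(traj, topo, {"P4": []}, [1])


class TestMotifPocketDistance:
    def _topo_traj(self, motif_xyz_frames):
        residues = [
            Residue(residue_id=1, name="PHE", beads=(Bead(0, "BB", "backbone"),)),
            Residue(residue_id=2, name="LEU", beads=(Bead(1, "BB", "backbone"),)),
            Residue(residue_id=3, name="ILE", beads=(Bead(2, "BB", "backbone"),)),
            Residue(residue_id=4, name="ASN", beads=(Bead(3, "BB", "backbone"),)),
        ]
        topo = SystemTopology(residues=residues, lipids=[],
                              species_to_class={},
                              bead_names=("BB", "BB", "BB", "BB"))
        n = len(motif_xyz_frames)
        coords = np.zeros((n, 4, 3))
        coords[:, 1] = [0.0, 0.0, 0.0]
        coords[:, 2] = [1.0, 0.0, 0.0]
        coords[:, 3] = [2.0, 0.0, 0.0]
        coords[:, 0] = motif_xyz_frames
        traj = Trajectory(times=np.arange(n, dtype=float), coordinates=coords,
                          box=np.tile([20.0, 20, 20], (n, 1)))
        return topo, traj

    def test_centroid_arithmetic(self):
        topo, traj = self._topo_traj([[1.0, 1.0, 0.0]])
        dist, _ = motif_pocket_distance(traj, topo, 1, [2, 3, 4])
        assert dist[0] == pytest.approx(1.0)

    def test_coincident_centroids(self):
        topo, traj = self._topo_traj([[1.0, 0.0, 0.0]])
        dist, _ = motif_pocket_distance(traj, topo, 1, [2, 3, 4])
        assert dist[0] == pytest.approx(0.0)

    def test_two_state_motif_gives_bimodal_histogram(self):
        rng = np.random.default_rng(15)
        n = 2000
        states = rng.random(n) < 0.5
        motif = np.empty((n, 3))
        motif[states] = [1.0, 0.5, 0.0]   # tethered near the pocket
        motif[~states] = [1.0, 4.0, 0.0]  # displaced
        motif += rng.normal(0, 0.05, (n, 3))
        topo, traj = self._topo_traj(motif)
        dist, hist = motif_pocket_distance(traj, topo, 1, [2, 3, 4],
                                           bins=np.linspace(0, 5, 51))
        dens = hist["density"].to_numpy()
        centres = (hist["bin_lo"] + hist["bin_hi"]).to_numpy() / 2
        # modes at the planted tether distances (0.5 and 4.0)
        near_mode = centres[np.argmax(dens * (centres < 2))]
        far_mode = centres[np.argmax(dens * (centres > 2))]
        assert near_mode == pytest.approx(0.5, abs=0.15)
        assert far_mode == pytest.approx(4.0, abs=0.15)
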