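import numpy as np
import pytest
from scipy import stats

from mdinteract.errors import SelectionError, TopologyError
from mdinteract.fluctuations import (
    corrected_heatmap,
    ligand_rmsd_series,
    mean_sidechain_rmsd,
    per_residue_rmsd,
    PerResidueRMSDMatrix,
)
from mdinteract.structure_io import Selection, Trajectory
from mdinteract.synthetic_data import gen_fluctuating_protein

from conftest import make_trajectory, random_rotation


def complex_fixture(n_frames=5, ligand_shift=None, rigid_motion=None, seed=0):
    """Protein of 4 CA-anchored residues plus a 3-atom ligand.

    ``ligand_shift`` displaces only ligand atoms (per-frame vector);
    ``rigid_motion`` applies (rotation, translation) to whole frames.
    """
    rng = np.random.default_rng(seed)
    protein = np.array(
        [[0, 0, 0], [4, 0, 0], [8, 0, 0], [4, 4, 0], [4, 0, 4], [0, 4, 4]], dtype=float
    )
    ligand = np.array([[2, 2, 2], [3, 2, 2], [2, 3, 2]], dtype=float)
    frames = []
    for f in range(n_frames):
        lig = ligand + (ligand_shift(f) if ligand_shift else 0.0)
        frame = np.vstack([protein, lig])
        if rigid_motion:
            q, t = rigid_motion(f)
            frame = frame @ q.T + t
        frames.append(frame)
    topo_elems = ["C"] * 6 + ["C", "O", "N"]
    names = ["CA"] * 6 + ["C1", "O1", "N1"]
    resnums = [1, 2, 3, 4, 5, 6, 7, 7, 7]
    resnames = ["ALA"] * 6 + ["LIG"] * 3
    return make_trajectory(frames, elements=topo_elems, residue_numbers=resnums,
                           names=names, residue_names=resnames)


LIG = {"residue_name": "LIG"}
FIT = {"atom_name": "CA"}


class TestLigandRmsdSeries:
    def test_identical_frames_give_zero(self):
        traj = complex_fixture(4)
        series = ligand_rmsd_series(traj, LIG, FIT)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_rigid_body_motion_removed_by_protein_fit(self):
        rng = np.random.default_rng(1)
        rots = [(random_rotation(rng), rng.uniform(-10, 10, 3)) for _ in range(5)]
        traj = complex_fixture(5, rigid_motion=lambda f: rots[f])
        series = ligand_rmsd_series(traj, LIG, FIT)
        np.testing.assert_allclose(series, 0.0, atol=1e-8)

    def test_planted_ligand_displacement_measured_exactly(self):
        shift = lambda f: np.array([2.0, 0.0, 0.0]) if f > 0 else 0.0
        traj = complex_fixture(6, ligand_shift=shift)
        series = ligand_rmsd_series(traj, LIG, FIT)
        assert series[0] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(series[1:], 2.0, atol=1e-9)

    def test_too_few_fit_atoms_rejected(self):
        traj = complex_fixture(2)
        with pytest.raises(SelectionError):
            ligand_rmsd_series(traj, LIG, {"residue_number": 1})


class TestPerResidueRmsd:
    def test_self_comparison_is_zero_matrix(self):
        traj = complex_fixture(4)
        mat = per_residue_rmsd(traj, traj)
        np.testing.assert_allclose(mat.matrix, 0.0, atol=1e-9)

    def test_single_displaced_residue_dominates_its_column(self):
        # 20 one-atom residues spread in 3D so the global fit barely feels
        # the one displaced residue
        rng = np.random.default_rng(10)
        coords = rng.uniform(-10, 10, (20, 3))
        base = make_trajectory([coords], elements=["C"] * 20,
                               residue_numbers=list(range(1, 21)),
                               names=["CA"] * 20, residue_names=["ALA"] * 20)
        moved_frames = []
        for _ in range(5):
            f = coords.copy()
            f[2] += np.array([0.0, 1.0, 0.0])  # residue 3
            moved_frames.append(f)
        moved = Trajectory(base.topology, moved_frames)
        mat = per_residue_rmsd(moved, base)
        col = mat.residue_numbers.index(3)
        assert mat.matrix[:, col].mean() > 0.85
        others = np.delete(mat.matrix, col, axis=1)
        assert others.mean() < 0.15

    def test_unmatchable_residue_reported_not_fatal(self):
        traj = complex_fixture(2)
        ref_topo = [a for a in traj.topology if a.residue_number != 7]
        keep = [i for i, a in enumerate(traj.topology) if a.residue_number != 7]
        ref = Trajectory(ref_topo, [traj.frames[0][keep]])
        mat = per_residue_rmsd(traj, ref)
        assert 7 in mat.skipped_residues
        assert 7 not in mat.residue_numbers


class TestCorrectedHeatmap:
    def make_matrix(self, values, residues):
        return PerResidueRMSDMatrix(
            matrix=np.asarray(values, dtype=float),
            residue_numbers=list(residues), reference="test",
        )

    def test_self_correction_is_zero(self):
        m = self.make_matrix(np.random.default_rng(0).uniform(0, 2, (6, 4)), [1, 2, 3, 4])
        out = corrected_heatmap(m, m)
        # baseline is the column mean, so columns centre on zero then clamp
        assert out.matrix.min() >= 0.0
        const = self.make_matrix(np.full((6, 4), 1.3), [1, 2, 3, 4])
        np.testing.assert_allclose(corrected_heatmap(const, const).matrix, 0.0, atol=1e-12)

    def test_constant_offsets_subtract(self):
        loaded = self.make_matrix(np.full((3, 2), 1.5), [1, 2])
        empty = self.make_matrix(np.full((4, 2), 0.4), [1, 2])
        out = corrected_heatmap(loaded, empty)
        np.testing.assert_allclose(out.matrix, 1.1)
        np.testing.assert_allclose(out.baseline, 0.4)

    def test_baseline_exceeding_signal_clamps_to_zero(self):
        loaded = self.make_matrix(np.full((3, 1), 0.2), [1])
        empty = self.make_matrix(np.full((3, 1), 0.9), [1])
        assert np.all(corrected_heatmap(loaded, empty).matrix == 0.0)

    def test_column_mismatch_names_residues(self):
        a = self.make_matrix(np.zeros((2, 2)), [1, 2])
        b = self.make_matrix(np.zeros((2, 2)), [1, 3])
        with pytest.raises(TopologyError, match="3"):
            corrected_heatmap(a, b)


class TestSidechainRmsd:
    def test_static_trajectory_gives_zero(self):
        empty, loaded, _ = gen_fluctuating_protein(1, loud_residues=[5], seed=0)
        static = Trajectory(empty.topology, [empty.frames[0]] * 4)
        res = mean_sidechain_rmsd(static, [3, 4])
        assert res.mean == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_rotated_sidechain_matches_brute_force(self):
        empty, _, _ = gen_fluctuating_protein(1, loud_residues=[5], seed=1)
        base = empty.frames[0]
        topo = empty.topology
        side_idx = [i for i, a in enumerate(topo)
                    if a.residue_number == 4 and a.name in ("CB", "CG")]
        ca_idx = [i for i, a in enumerate(topo) if a.residue_number == 4 and a.name == "CA"][0]
        q = random_rotation(np.random.default_rng(2))
        moved = base.copy()
        moved[side_idx] = (moved[side_idx] - base[ca_idx]) @ q.T + base[ca_idx]
        traj = Trajectory(topo, [base, moved])
        res = mean_sidechain_rmsd(traj, [4])
        brute = np.sqrt(np.mean(np.sum((moved[side_idx] - base[side_idx]) ** 2, axis=1)))
        assert res.mean == pytest.approx(brute / 2.0, abs=1e-9)  # mean over 2 frames

    def test_residue_without_sidechain_is_skipped(self):
        frames = [np.array([[0, 0, 0], [4, 0, 0], [8, 0, 0]], dtype=float)] * 2
        traj = make_trajectory(frames, elements=["C"] * 3,
                               residue_numbers=[1, 2, 3],
                               names=["CA", "CA", "CA"], residue_names=["GLY"] * 3)
        res = mean_sidechain_rmsd(traj, [1, 2, 3])
        assert res.mean is None
        assert res.skipped_residues == [1, 2, 3]


class TestGeneratorRecovery:
    def test_loud_residues_dominate_corrected_heatmap(self):
        empty, loaded, gt = gen_fluctuating_protein(
            40, loud_residues=[7, 8, 9], drift=1.0, seed=4
        )
        raw = per_residue_rmsd(loaded, empty)
        selfm = per_residue_rmsd(empty, empty)
        out = corrected_heatmap(raw, selfm)
        means = out.matrix.mean(axis=0)
        top3 = {out.residue_numbers[i] for i in np.argsort(means)[::-1][:3]}
        assert top3 == {7, 8, 9}

    def test_null_generator_gives_near_zero_heatmap(self):
        # no drift: corrected heatmap indistinguishable from noise
        empty, loaded, _ = gen_fluctuating_protein(
            60, quiet_sd=0.1, loud_sd=0.100001, loud_residues=[5], drift=0.0, seed=8
        )
        raw = per_residue_rmsd(loaded, empty)
        selfm = per_residue_rmsd(empty, empty)
        out = corrected_heatmap(raw, selfm)
        assert np.abs(out.matrix.mean(axis=0)).max() < 0.15

    def test_two_regime_separation_across_seeds(self):
        # loud-residue corrected means exceed quiet ones, paired over 20 seeds
        louds, quiets = [], []
        for seed in range(20):
            empty, loaded, _ = gen_fluctuating_protein(
                15, quiet_sd=0.05, loud_sd=0.15, loud_residues=[7, 8, 9],
                drift=0.5, seed=seed, n_residues=12,
            )
            raw = per_residue_rmsd(loaded, empty)
            selfm = per_residue_rmsd(empty, empty)
            means = corrected_heatmap(raw, selfm).matrix.mean(axis=0)
            resnums = raw.residue_numbers
            loud_mean = np.mean([means[resnums.index(r)] for r in (7, 8, 9)])
            quiet_mean = np.mean(
                [means[i] for i, r in enumerate(resnums) if r not in (7, 8, 9)]
            )
            louds.append(loud_mean)
            quiets.append(quiet_mean)
        t = stats.ttest_rel(louds, quiets, alternative="greater")
        assert t.pvalue < 0.01

    def test_outputs_invariant_under_global_rigid_motion(self):
        empty, loaded, _ = gen_fluctuating_protein(10, loud_residues=[5], seed=3)
        rng = np.random.default_rng(5)
        q = random_rotation(rng)
        t = rng.uniform(-15, 15, 3)
        moved = Trajectory(loaded.topology, [f @ q.T + t for f in loaded.frames])
        a = per_residue_rmsd(loaded, empty).matrix
        b = per_residue_rmsd(moved, empty).matrix
        np.testing.assert_allclose(a, b, atol=1e-8)
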