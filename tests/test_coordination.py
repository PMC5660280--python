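import numpy as np
import pytest
from scipy import stats

from mdinteract.coordination import (
    RDFProfile,
    compute_rdf,
    coordination_series,
    denticity_fractions,
    detect_first_minimum,
    mean_count_within,
    peak_position,
)
from mdinteract.errors import DetectionError, SelectionError
from mdinteract.structure_io import Selection
from mdinteract.synthetic_data import gen_zn_site

from conftest import make_trajectory

ION = {"residue_name": "ZN"}
SHELL = {"residue_name": "LIG", "element": ["O", "N"]}


def shell_fixture(radii_per_frame):
    """Ion at origin plus partner atoms at given radii (along random fixed axes)."""
    rng = np.random.default_rng(42)
    n = len(radii_per_frame[0])
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    frames = []
    for radii in radii_per_frame:
        coords = np.vstack([np.zeros(3), dirs * np.asarray(radii)[:, None]])
        frames.append(coords)
    return make_trajectory(
        frames,
        elements=["Zn"] + ["O"] * n,
        residue_numbers=[1] + [2] * n,
        residue_names=["ZN"] + ["LIG"] * n,
    )


class TestComputeRdf:
    def test_counting_and_number_integral(self):
        traj = shell_fixture([[2.0] * 5 + [4.0] * 3])
        prof = compute_rdf(traj, ION, SHELL, bin_width=0.1, r_max=5.0)
        assert prof.integral_at(2.83) == pytest.approx(5.0)
        assert prof.integral_at(5.0) == pytest.approx(8.0)
        assert prof.density.sum() == pytest.approx(8.0)

    def test_mean_over_frames(self):
        traj = shell_fixture([[2.0] * 5 + [4.0], [2.0] * 6])
        prof = compute_rdf(traj, ION, SHELL, bin_width=0.1, r_max=5.0)
        assert prof.integral_at(2.83) == pytest.approx(5.5)

    def test_empty_partner_selection_gives_zero_profile(self):
        traj = shell_fixture([[2.0] * 3])
        prof = compute_rdf(traj, ION, {"residue_name": "XXX"}, 0.1, 5.0)
        assert prof.density.sum() == 0.0
        assert prof.integral_at(5.0) == 0.0

    def test_center_must_be_single_atom(self):
        traj = shell_fixture([[2.0] * 3])
        with pytest.raises(SelectionError):
            compute_rdf(traj, SHELL, ION, 0.1, 5.0)

    def test_number_integral_nondecreasing(self):
        traj, _ = gen_zn_site(20, seed=3)
        prof = compute_rdf(traj, ION, {"element": ["O", "N"]}, 0.05, 10.0)
        assert np.all(np.diff(prof.number_integral) >= -1e-12)

    def test_density_grows_quadratically_for_uniform_ball(self):
        # 10^4 points uniform in a ball: per-bin counts follow r^3 shell volumes
        rng = np.random.default_rng(8)
        n, radius = 10_000, 5.0
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = radius * rng.random(n) ** (1.0 / 3.0)
        coords = np.vstack([np.zeros(3), v * r[:, None]])
        traj = make_trajectory(
            [coords],
            elements=["Zn"] + ["O"] * n,
            residue_numbers=[1] + [2] * n,
            residue_names=["ZN"] + ["LIG"] * n,
        )
        prof = compute_rdf(traj, ION, {"residue_name": "LIG"}, bin_width=0.5, r_max=5.0)
        edges = prof.bin_edges
        expected = n * (edges[1:] ** 3 - edges[:-1] ** 3) / radius**3
        chi2 = stats.chisquare(prof.density, expected)
        assert chi2.pvalue > 0.01


class TestFirstMinimum:
    @staticmethod
    def profile_from_density(density, bin_width=0.1):
        density = np.asarray(density, dtype=float)
        edges = np.arange(len(density) + 1) * bin_width
        return RDFProfile(edges, density, np.cumsum(density), 1, edges[-1])

    def test_frozen_two_peak_histogram(self):
        # peaks centred near 2.0 and 3.9 A, zero density on [2.5, 3.0);
        # exhaustive scan of this histogram puts the minimum at 2.55 A
        centers = np.arange(50) * 0.1 + 0.05
        dens = np.zeros(50)
        for i, c in enumerate(centers):
            if 1.7 <= c < 2.5:
                dens[i] = max(0.1, 5.0 - 12 * abs(c - 2.05))
            elif 3.0 <= c <= 4.6:
                dens[i] = max(0.1, 4.0 - 6 * abs(c - 3.95))
        prof = self.profile_from_density(dens)
        assert detect_first_minimum(prof, smooth=False) == pytest.approx(2.55)
        scan_min = min(
            (dens[i], centers[i])
            for i in range(np.argmax(dens), 30)
        )[1]
        assert scan_min == pytest.approx(2.55)

    def test_smoothing_suppresses_single_bin_noise(self):
        dens = np.zeros(60)
        dens[18:23] = [2.0, 5.0, 4.8, 5.0, 2.0]  # shot-noise dip inside the peak
        dens[30:40] = 0.2
        dens[45:50] = 3.0
        prof = self.profile_from_density(dens)
        # raw scan stops at the single-bin dip inside the first peak ...
        assert detect_first_minimum(prof, smooth=False) == pytest.approx(2.05)
        # ... the smoothed scan passes it and finds the true inter-peak valley
        assert detect_first_minimum(prof, smooth=True) > 2.2

    def test_equal_minima_resolve_to_smaller_radius(self):
        dens = np.zeros(30)
        dens[10], dens[11], dens[12], dens[13] = 5.0, 1.0, 1.0, 4.0
        prof = self.profile_from_density(dens)
        assert detect_first_minimum(prof, smooth=False) == pytest.approx(1.15)

    def test_monotone_tail_has_no_minimum(self):
        dens = np.concatenate([np.linspace(0, 5, 10), np.linspace(5, 0.1, 20)])
        prof = self.profile_from_density(dens)
        with pytest.raises(DetectionError):
            detect_first_minimum(prof, smooth=False)


class TestCoordinationSeries:
    def test_generated_shell_recovered_exactly(self):
        traj, gt = gen_zn_site(100, n_coordinating=5, bond_length=2.0,
                               noise_sd=0.05, n_shell_waters=10, seed=7)
        res = coordination_series(traj, ION, SHELL, cutoff=2.83)
        assert res.mean_cn == pytest.approx(5.0)
        assert res.mean_cn == pytest.approx(gt["mean_cn"])

    def test_cutoff_below_all_distances(self):
        traj = shell_fixture([[2.0] * 4])
        res = coordination_series(traj, ION, SHELL, cutoff=1.0)
        assert res.mean_cn == 0.0

    def test_oscillating_partner_adds_fraction(self):
        traj, gt = gen_zn_site(50, n_coordinating=4, seed=9, oscillating_fraction=0.4)
        res = coordination_series(traj, ION, SHELL, cutoff=2.83)
        assert res.mean_cn == pytest.approx(4.4)
        np.testing.assert_array_equal(res.per_frame_cn, gt["per_frame_cn"])

    def test_mean_equals_mean_of_series(self):
        traj, _ = gen_zn_site(30, seed=2)
        res = coordination_series(traj, ION, SHELL, cutoff=2.83)
        assert res.mean_cn == pytest.approx(res.per_frame_cn.mean())


class TestDenticity:
    def pair_fixture(self, radii_pairs):
        frames = []
        for r1, r2 in radii_pairs:
            frames.append(np.array([[0.0, 0, 0], [r1, 0, 0], [0, r2, 0]]))
        return make_trajectory(
            frames, elements=["Zn", "O", "O"],
            residue_numbers=[1, 2, 2], residue_names=["ZN", "GLU", "GLU"],
        )

    def test_pure_modes(self):
        bident = self.pair_fixture([(2.0, 2.0)] * 5)
        res = denticity_fractions(bident, ION, {"residue_number": 2}, 2.83)
        assert res == {"bidentate": 1.0, "monodentate": 0.0, "unbound": 0.0}
        mono = self.pair_fixture([(2.0, 4.0)] * 5)
        res = denticity_fractions(mono, ION, {"residue_number": 2}, 2.83)
        assert res["monodentate"] == 1.0

    def test_alternating_frames_split_evenly(self):
        alt = self.pair_fixture([(2.0, 2.0), (2.0, 4.0)] * 10)
        res = denticity_fractions(alt, ION, {"residue_number": 2}, 2.83)
        assert res["bidentate"] == pytest.approx(0.5)
        assert res["monodentate"] == pytest.approx(0.5)
        assert sum(res.values()) == pytest.approx(1.0)

    def test_pair_cardinality_enforced(self):
        traj = self.pair_fixture([(2.0, 2.0)])
        with pytest.raises(SelectionError):
            denticity_fractions(traj, ION, {"element": "Zn"}, 2.83)


class TestMeanCountWithin:
    def test_rare_visitor_counted_as_fraction(self):
        frames = []
        for f in range(100):
            r = 4.0 if f in (3, 50, 97) else 8.0
            frames.append(np.array([[0.0, 0, 0], [r, 0, 0]]))
        traj = make_trajectory(frames, elements=["Zn", "O"],
                               residue_numbers=[1, 2], residue_names=["ZN", "HOH"])
        got = mean_count_within(traj, ION, {"residue_name": "HOH"}, 5.0)
        assert got == pytest.approx(0.03)

    def test_zero_radius(self):
        traj, _ = gen_zn_site(5, seed=1)
        assert mean_count_within(traj, ION, SHELL, 0.0) == 0.0

    def test_consistency_with_rdf_integral_at_bin_edges(self):
        traj, _ = gen_zn_site(40, seed=6)
        prof = compute_rdf(traj, ION, {"element": ["O", "N"]}, 0.05, 10.0)
        for r in (1.0, 2.5, 3.0, 5.0, 10.0):
            assert mean_count_within(traj, ION, {"element": ["O", "N"]}, r) == pytest.approx(
                prof.integral_at(r), abs=1e-12
            )

    def test_nondecreasing_in_radius(self):
        traj, _ = gen_zn_site(20, seed=4)
        counts = [mean_count_within(traj, ION, {"element": ["O", "N"]}, r)
                  for r in np.linspace(0.5, 10.0, 25)]
        assert np.all(np.diff(counts) >= 0.0)


def test_peak_position_matches_generated_bond_length():
    traj, _ = gen_zn_site(200, bond_length=2.0, noise_sd=0.05, seed=12)
    prof = compute_rdf(traj, ION, SHELL, 0.05, 10.0)
    assert peak_position(prof) == pytest.approx(2.0, abs=0.1)
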