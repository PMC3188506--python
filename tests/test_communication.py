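"""Communication propensity, threshold, efficiency and LRCC profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import allocomm as ac
from allocomm.communication import (
    CommunicationPropensityMatrix,
    EfficiencyMatrix,
    MeanDistanceMatrix,
    pairwise_distances,
)
from allocomm.ensemble import CoordinateEnsemble, ResidueTopology
from allocomm.synthetic import straight_chain

from conftest import random_rigid_transform


def ensemble_from_coords(coords):
    return CoordinateEnsemble(
        topology=ResidueTopology.simple_chain(coords.shape[1]), coords=coords
    )


class TestMeanDistance:
    def test_static_straight_chain_distances_are_multiples_of_spacing(self):
        coords = np.repeat(straight_chain(6, 4.0)[None], 2, axis=0)
        dist = ac.mean_distance_matrix(ensemble_from_coords(coords))
        assert dist.values[0, 5] == pytest.approx(20.0)
        np.testing.assert_allclose(dist.values[0], 4.0 * np.arange(6), atol=1e-12)

    def test_two_frame_mean_of_9_and_11_is_10(self):
        coords = np.zeros((2, 2, 3))
        coords[0, 1, 0] = 9.0
        coords[1, 1, 0] = 11.0
        dist = ac.mean_distance_matrix(ensemble_from_coords(coords))
        assert dist.values[0, 1] == pytest.approx(10.0)

    def test_rigid_ensemble_mean_equals_single_frame_distances(self, helix20, rng):
        ens = ac.sample_rigid_body(helix20, 20, seed=5)
        dist = ac.mean_distance_matrix(ens)
        np.testing.assert_allclose(dist.values, pairwise_distances(helix20), atol=1e-9)


class TestCommunicationPropensity:
    def test_rigid_body_ensemble_has_zero_cp(self, helix20):
        ens = ac.sample_rigid_body(helix20, 50, seed=0)
        assert np.abs(ac.communication_propensity(ens).values).max() <= 1e-9

    def test_two_frame_toy_cp_is_one(self):
        # distances 9 and 11 A: population variance ((−1)^2 + 1^2)/2 = 1
        coords = np.zeros((2, 2, 3))
        coords[0, 1, 0] = 9.0
        coords[1, 1, 0] = 11.0
        cp = ac.communication_propensity(ensemble_from_coords(coords))
        assert cp.values[0, 1] == pytest.approx(1.0)

    def test_symmetry_zero_diagonal_nonnegative(self, helix20):
        ens = ac.sample_iid_jitter(helix20, 0.4, 200, seed=3)
        cp = ac.communication_propensity(ens).values
        np.testing.assert_allclose(cp, cp.T, atol=1e-12)
        assert np.diag(cp).max() == 0.0
        assert cp.min() >= 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_cp_invariant_under_per_frame_rigid_transforms(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=5.0, size=(6, 8, 3))
        base = ac.communication_propensity(ensemble_from_coords(coords)).values
        moved = coords.copy()
        for f in range(coords.shape[0]):
            rot, trans = random_rigid_transform(rng)
            moved[f] = coords[f] @ rot.T + trans
        transformed = ac.communication_propensity(ensemble_from_coords(moved)).values
        np.testing.assert_allclose(transformed, base, atol=1e-9)

    def test_cp_matches_direct_per_pair_variance(self, rng):
        # oracle: loop over pairs, numpy variance of the distance series
        coords = rng.normal(scale=3.0, size=(40, 5, 3))
        cp = ac.communication_propensity(ensemble_from_coords(coords)).values
        for i in range(5):
            for j in range(5):
                series = np.linalg.norm(coords[:, i] - coords[:, j], axis=1)
                assert cp[i, j] == pytest.approx(np.var(series), abs=1e-10)


def brute_force_threshold(cp: np.ndarray, window: int = 4) -> float:
    """Independent oracle: explicit double loop over truncated windows."""
    n = cp.shape[0]
    per_res = []
    for i in range(n):
        vals = []
        for j in range(i - window, i + window + 1):
            if j == i or j < 0 or j >= n:
                continue
            vals.append(cp[i, j])
        per_res.append(np.mean(vals) if vals else 0.0)
    return float(np.mean(per_res))


class TestThreshold:
    def test_uniform_neighbor_cp_gives_that_threshold(self):
        cp = CommunicationPropensityMatrix(np.full((9, 9), 0.04) - 0.04 * np.eye(9))
        assert ac.communication_threshold(cp).value == pytest.approx(0.04)

    def test_three_residue_truncated_window_formula(self):
        a, b, c = 0.3, 0.7, 0.2
        m = np.array([[0, a, b], [a, 0, c], [b, c, 0.0]])
        thr = ac.communication_threshold(CommunicationPropensityMatrix(m))
        expected = ((a + b) / 2 + (a + c) / 2 + (b + c) / 2) / 3
        assert thr.value == pytest.approx(expected)
        np.testing.assert_array_equal(thr.terms_per_residue, [2, 2, 2])

    @pytest.mark.parametrize("n", [2, 5, 17, 50])
    def test_equals_brute_force_on_random_matrices(self, n, rng):
        for _ in range(10):
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            cp = CommunicationPropensityMatrix(m)
            assert ac.communication_threshold(cp).value == brute_force_threshold(m)

    def test_window_does_not_cross_chain_boundaries(self):
        # two chains of 3; neighbors of residue 2 (chain X) must exclude 3-5
        m = np.zeros((6, 6))
        m[2, 3] = m[3, 2] = 100.0  # inter-chain pair: must not enter any window
        m[0, 1] = m[1, 0] = m[1, 2] = m[2, 1] = m[0, 2] = m[2, 0] = 0.1
        m[3, 4] = m[4, 3] = m[4, 5] = m[5, 4] = m[3, 5] = m[5, 3] = 0.1
        chains = np.array(["X", "X", "X", "Y", "Y", "Y"], dtype=object)
        thr = ac.communication_threshold(
            CommunicationPropensityMatrix(m), chain_ids=chains
        )
        assert thr.value == pytest.approx(0.1)

    def test_rigid_ensemble_threshold_zero(self, helix20):
        cp = ac.communication_propensity(ac.sample_rigid_body(helix20, 10, seed=1))
        assert ac.communication_threshold(cp).value <= 1e-9


class TestEfficiency:
    def test_equality_counts_as_efficient(self):
        m = np.array([[0, 0.025], [0.025, 0.0]])
        eff = ac.efficient_pairs(CommunicationPropensityMatrix(m), 0.025)
        assert eff.values[0, 1]

    def test_rigid_ensemble_all_offdiagonal_pairs_efficient(self, helix20):
        ens = ac.sample_rigid_body(helix20, 10, seed=2)
        cp = ac.communication_propensity(ens)
        thr = ac.communication_threshold(cp)
        eff = ac.efficient_pairs(cp, thr)
        expected = ~np.eye(20, dtype=bool)
        np.testing.assert_array_equal(eff.values, expected)


class TestLRCC:
    def test_rigid_chain_residue1_density_is_4_of_9(self, chain10):
        # partners of residue 1 sit at 4,8,...,36 A: four exceed delta=20
        ens = ac.sample_rigid_body(chain10, 5, seed=0)
        cp = ac.communication_propensity(ens)
        eff = ac.efficient_pairs(cp, ac.communication_threshold(cp))
        prof = ac.lrcc_profile(eff, ac.mean_distance_matrix(ens), 20.0)
        assert prof.densities[0] == pytest.approx(4 / 9)

    def test_delta_beyond_max_distance_gives_zero_everywhere(self, chain10):
        ens = ac.sample_rigid_body(chain10, 5, seed=0)
        cp = ac.communication_propensity(ens)
        eff = ac.efficient_pairs(cp, ac.communication_threshold(cp))
        prof = ac.lrcc_profile(eff, ac.mean_distance_matrix(ens), 100.0)
        assert prof.densities.max() == 0.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_lrcc_monotone_nonincreasing_in_delta(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=15.0, size=(8, 12, 3))
        ens = ensemble_from_coords(coords)
        cp = ac.communication_propensity(ens)
        eff = ac.efficient_pairs(cp, ac.communication_threshold(cp))
        dist = ac.mean_distance_matrix(ens)
        grid = [20.0, 30.0, 40.0, 50.0, 60.0, 70.0]
        profs = [ac.lrcc_profile(eff, dist, d).densities for d in grid]
        for smaller, larger in zip(profs, profs[1:]):
            assert (smaller >= larger).all()

    def test_lrcc_matches_brute_force_count(self, rng):
        coords = rng.normal(scale=12.0, size=(10, 15, 3))
        ens = ensemble_from_coords(coords)
        cp = ac.communication_propensity(ens)
        thr = ac.communication_threshold(cp)
        eff = ac.efficient_pairs(cp, thr)
        dist = ac.mean_distance_matrix(ens)
        prof = ac.lrcc_profile(eff, dist, 25.0)
        n = 15
        for i in range(n):
            count = sum(
                1
                for j in range(n)
                if j != i and eff.values[i, j] and dist.values[i, j] > 25.0
            )
            assert prof.densities[i] == pytest.approx(count / (n - 1))


class TestRelativeLRCC:
    def _profile(self, values, delta=30.0, label=""):
        return ac.LRCCProfile(np.asarray(values, float), delta, label)

    def test_identical_profiles_give_zero(self):
        a = self._profile([0.1, 0.5, 0.9])
        assert np.all(ac.relative_lrcc(a, a).deltas == 0.0)

    def test_constant_difference(self):
        rel = ac.relative_lrcc(self._profile([0.5] * 4), self._profile([0.2] * 4))
        np.testing.assert_allclose(rel.deltas, 0.3)

    def test_mismatched_delta_is_fatal(self):
        with pytest.raises(ValueError, match="delta"):
            ac.relative_lrcc(self._profile([0.1], 20.0), self._profile([0.1], 30.0))

    def test_mismatched_length_is_fatal(self):
        with pytest.raises(ValueError):
            ac.relative_lrcc(self._profile([0.1, 0.2]), self._profile([0.1]))


class TestPeakClusters:
    def _profile(self, values):
        return ac.LRCCProfile(np.asarray(values, float), 30.0)

    def test_flat_profile_has_no_clusters(self):
        assert len(ac.detect_peak_clusters(self._profile([0.4] * 20))) == 0

    def test_single_block_detected_exactly(self):
        d = np.full(30, 0.1)
        d[10:15] = 0.9
        peaks = ac.detect_peak_clusters(self._profile(d), z_cut=1.0, min_run=3)
        assert len(peaks) == 1
        assert (peaks.clusters[0].start, peaks.clusters[0].stop) == (10, 14)

    def test_blocks_split_by_background_residue_stay_separate(self):
        d = np.full(30, 0.1)
        d[5:9] = 0.9
        d[10:14] = 0.9  # residue 9 is background: two clusters, not one
        peaks = ac.detect_peak_clusters(self._profile(d), z_cut=1.0, min_run=3)
        assert [(c.start, c.stop) for c in peaks.clusters] == [(5, 8), (10, 13)]

    def test_runs_shorter_than_min_run_discarded(self):
        d = np.full(30, 0.1)
        d[5:7] = 0.9
        peaks = ac.detect_peak_clusters(self._profile(d), z_cut=1.0, min_run=3)
        assert len(peaks) == 0

    def test_matches_brute_force_segmentation(self, rng):
        d = rng.random(50)
        peaks = ac.detect_peak_clusters(self._profile(d), z_cut=0.5, min_run=2)
        cutoff = d.mean() + 0.5 * d.std()
        # oracle: label contiguous above-cutoff runs directly
        member = np.zeros(50, dtype=bool)
        run = []
        for i in range(51):
            if i < 50 and d[i] > cutoff:
                run.append(i)
            else:
                if len(run) >= 2:
                    member[run] = True
                run = []
        np.testing.assert_array_equal(np.flatnonzero(member), peaks.member_indices())
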