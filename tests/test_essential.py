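"""Essential dynamics: covariance, correlation maps, modes, flexibility."""

import numpy as np
import pytest

import allocomm as ac
from allocomm.ensemble import CoordinateEnsemble, ResidueTopology
from allocomm.essential import subsample_frames
from allocomm.synthetic import gnm_residue_covariance, straight_chain


def ensemble_from_coords(coords):
    return CoordinateEnsemble(
        topology=ResidueTopology.simple_chain(coords.shape[1]), coords=coords
    )


def single_mode_ensemble(n_frames=300, n_res=8, seed=0):
    """Frames = mean + a_t * v for Gaussian scalars a_t: rank-1 covariance."""
    rng = np.random.default_rng(seed)
    mean = ac.make_helix_coordinates(n_res)
    v = rng.normal(size=(n_res, 3))
    v /= np.linalg.norm(v)
    a = rng.normal(scale=2.0, size=n_frames)
    coords = mean[None] + a[:, None, None] * v[None]
    return ensemble_from_coords(coords), v, a


class TestCovariance:
    def test_static_ensemble_gives_zero_matrix(self, helix20):
        ens = ac.sample_iid_jitter(helix20, 0.0, 5, seed=1)
        cov = ac.coordinate_covariance(ens)
        assert np.abs(cov.matrix).max() <= 1e-15

    def test_single_mode_rank_one(self):
        ens, v, _ = single_mode_ensemble()
        cov = ac.coordinate_covariance(ens)
        evals = np.linalg.eigvalsh(cov.matrix)
        assert evals[-1] > 0
        assert evals[-2] <= 1e-10 * evals[-1]

    def test_positive_semidefinite_on_random_ensemble(self, rng):
        coords = rng.normal(scale=2.0, size=(30, 6, 3))
        cov = ac.coordinate_covariance(ensemble_from_coords(coords))
        evals = np.linalg.eigvalsh(cov.matrix)
        assert evals.min() >= -1e-8 * np.trace(cov.matrix)

    def test_gnm_covariance_recovered(self, helix20):
        scale = 0.25
        ens = ac.sample_gnm(helix20, 7.5, scale, 20000, seed=30)
        cov = ac.coordinate_covariance(ens)
        target = gnm_residue_covariance(helix20, 7.5, scale)
        # isotropic GNM: each Cartesian component has the same N x N covariance
        for k in range(3):
            comp = cov.matrix[k::3, k::3]
            assert np.abs(comp - target).max() <= 0.05 * np.abs(target).max()

    def test_unsuperposed_ensemble_warns_but_runs(self, helix20, caplog):
        ens = ac.sample_rigid_body(helix20, 10, seed=31)
        with caplog.at_level("WARNING"):
            ac.coordinate_covariance(ens)
        assert any("unsuperposed" in r.message for r in caplog.records)

    def test_subsampling_consistency_with_full_ensemble(self, helix20):
        ens = ac.sample_iid_jitter(helix20, 0.5, 20000, seed=32)
        full = ac.coordinate_covariance(ens)
        sub = ac.coordinate_covariance(ens, n_snapshots=500)
        # elementwise 3-SE agreement for >= 99% of entries; SE of a
        # covariance entry ~ sqrt((c_ii c_jj + c_ij^2) / F)
        diag = np.diag(full.matrix)
        se = np.sqrt((np.outer(diag, diag) + full.matrix**2) / sub.n_frames_used)
        frac_ok = (np.abs(sub.matrix - full.matrix) <= 3 * se).mean()
        assert frac_ok >= 0.99

    def test_evenly_spaced_subsample_indices(self):
        idx = subsample_frames(10, 5)
        assert idx[0] == 0 and idx[-1] == 9 and len(idx) == 5
        np.testing.assert_array_equal(subsample_frames(5, 10), np.arange(5))


class TestCorrelation:
    def test_diagonal_is_one_for_fluctuating_residues(self, helix20):
        ens = ac.sample_iid_jitter(helix20, 0.3, 50, seed=1)
        corr = ac.residue_correlation(ac.coordinate_covariance(ens))
        np.testing.assert_allclose(np.diag(corr.matrix), 1.0, atol=1e-12)

    def test_duplicated_residue_has_correlation_one(self, rng):
        base = rng.normal(size=(40, 3, 3))
        coords = np.concatenate([base, base[:, :1, :] + 5.0], axis=1)  # residue 3 copies residue 0
        corr = ac.residue_correlation(
            ac.coordinate_covariance(ensemble_from_coords(coords))
        )
        assert corr.matrix[0, 3] == pytest.approx(1.0, abs=1e-10)

    def test_mirror_phase_pair_has_correlation_minus_one(self, rng):
        base = rng.normal(size=(40, 1, 3))
        coords = np.concatenate([base, -base + 5.0], axis=1)
        corr = ac.residue_correlation(
            ac.coordinate_covariance(ensemble_from_coords(coords))
        )
        assert corr.matrix[0, 1] == pytest.approx(-1.0, abs=1e-10)

    def test_zero_variance_residue_gets_zero_with_warning(self, caplog, rng):
        coords = rng.normal(size=(20, 3, 3))
        coords[:, 1, :] = 7.0  # frozen residue
        with caplog.at_level("WARNING"):
            corr = ac.residue_correlation(
                ac.coordinate_covariance(ensemble_from_coords(coords))
            )
        assert corr.matrix[1, 0] == 0.0
        assert corr.matrix[1, 1] == 0.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_values_bounded_and_symmetric(self, helix20):
        ens = ac.sample_gnm(helix20, 7.5, 0.2, 500, seed=2)
        corr = ac.residue_correlation(ac.coordinate_covariance(ens)).matrix
        assert corr.min() >= -1.0 and corr.max() <= 1.0
        np.testing.assert_allclose(corr, corr.T, atol=1e-10)


class TestModes:
    def test_eigenvalue_sum_equals_trace(self, helix20):
        ens = ac.sample_gnm(helix20, 7.5, 0.2, 400, seed=3)
        cov = ac.coordinate_covariance(ens)
        modes = ac.essential_modes(cov)
        assert modes.eigenvalues.sum() == pytest.approx(
            np.trace(cov.matrix), rel=1e-6
        )

    def test_eigenvectors_orthonormal(self, helix20):
        ens = ac.sample_iid_jitter(helix20, 0.3, 100, seed=4)
        modes = ac.essential_modes(ac.coordinate_covariance(ens))
        gram = modes.eigenvectors.T @ modes.eigenvectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_rank_one_construction_captured_by_pc1(self):
        ens, v, _ = single_mode_ensemble()
        modes = ac.essential_modes(ac.coordinate_covariance(ens))
        assert modes.cumulative_variance_fractions[0] >= 0.999
        cosine = abs(modes.eigenvectors[:, 0] @ v.ravel())
        assert cosine > 0.999999

    def test_sign_convention_largest_component_positive(self, helix20):
        ens = ac.sample_gnm(helix20, 7.5, 0.2, 200, seed=5)
        modes = ac.essential_modes(ac.coordinate_covariance(ens))
        for k in range(5):
            vec = modes.eigenvectors[:, k]
            assert vec[np.argmax(np.abs(vec))] > 0

    def test_gnm_top_mode_lies_in_analytic_eigenspace(self, helix20):
        # isotropic GNM: the top coordinate-covariance eigenvalue is triply
        # degenerate (x, y, z copies of the top Kirchhoff pseudo-inverse
        # mode v), so the sampled top mode must lie in span{v (x) e_c}
        scale = 0.25
        ens = ac.sample_gnm(helix20, 7.5, scale, 20000, seed=33)
        modes = ac.essential_modes(ac.coordinate_covariance(ens))
        target = gnm_residue_covariance(helix20, 7.5, scale)
        tvals, tvecs = np.linalg.eigh(target)
        v = tvecs[:, -1]
        w = modes.eigenvectors[:, 0].reshape(-1, 3)
        proj_norm = np.sqrt(sum((v @ w[:, c]) ** 2 for c in range(3)))
        assert proj_norm > 0.95


class TestProjections:
    def test_projection_variance_equals_eigenvalue(self, helix20):
        ens = ac.sample_gnm(helix20, 7.5, 0.3, 300, seed=6)
        cov = ac.coordinate_covariance(ens)
        modes = ac.essential_modes(cov)
        for k in range(6):
            series = ac.project_frames(ens, modes, k)
            assert np.var(series) == pytest.approx(modes.eigenvalues[k], rel=1e-6, abs=1e-12)

    def test_projections_on_distinct_modes_uncorrelated(self, helix20):
        ens = ac.sample_gnm(helix20, 7.5, 0.3, 300, seed=7)
        modes = ac.essential_modes(ac.coordinate_covariance(ens))
        p0 = ac.project_frames(ens, modes, 0)
        p1 = ac.project_frames(ens, modes, 1)
        cov01 = np.mean((p0 - p0.mean()) * (p1 - p1.mean()))
        assert abs(cov01) <= 1e-8 * np.std(p0) * np.std(p1) + 1e-12

    def test_single_mode_projection_recovers_generating_scalars(self):
        ens, v, a = single_mode_ensemble()
        modes = ac.essential_modes(ac.coordinate_covariance(ens))
        series = ac.project_frames(ens, modes, 0)
        centered = a - a.mean()
        sign = np.sign(series @ centered)
        np.testing.assert_allclose(sign * series, centered, atol=1e-6)

    def test_mode_index_out_of_range_is_fatal(self, helix20):
        ens = ac.sample_iid_jitter(helix20, 0.2, 20, seed=8)
        modes = ac.essential_modes(ac.coordinate_covariance(ens))
        with pytest.raises(IndexError):
            ac.project_frames(ens, modes, 60)


class TestFlexibility:
    def test_static_ensemble_all_zero(self, helix20):
        ens = ac.sample_iid_jitter(helix20, 0.0, 5, seed=1)
        flex = ac.flexibility_profile(ens, helix20)
        assert flex.rmsd_per_frame.max() <= 1e-12
        assert flex.rmsf_per_residue.max() <= 1e-12

    def test_rigid_body_after_superposition_zero_rmsf(self, helix20):
        ens = ac.sample_rigid_body(helix20, 20, seed=2)
        aligned = ac.superpose_ensemble(ens, helix20)
        flex = ac.flexibility_profile(aligned, helix20)
        assert flex.rmsf_per_residue.max() < 1e-6

    def test_iid_jitter_rmsf_closed_form(self):
        ref = straight_chain(30, 10.0)
        ens = ac.sample_iid_jitter(ref, 0.5, 20000, seed=3)
        flex = ac.flexibility_profile(ens, ref)
        assert flex.rmsf_per_residue.mean() == pytest.approx(0.5 * np.sqrt(3), rel=0.03)

    def test_segment_flexibility_local_vs_global(self, rng):
        # a rigid segment riding a floppy hinge: locally superposed segment
        # RMSF must be far below the globally framed value
        ref = ac.make_helix_coordinates(40)
        ens = ac.sample_hinge(ref, 20, 15.0, 0.0, 400, seed=9)
        aligned = ac.superpose_ensemble(ens, ref, selection=np.arange(20))
        seg = np.arange(25, 40)
        glob = ac.segment_flexibility(aligned, ref, seg, local_superposition=False)
        loc = ac.segment_flexibility(aligned, ref, seg, local_superposition=True)
        assert loc.rmsf_per_residue.max() < 1e-6
        assert glob.rmsf_per_residue.mean() > 1.0
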