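"""The four sparse-to-dense reconstruction methods."""

import numpy as np
import pytest

from lvfiber.coordinates import LocalFrame
from lvfiber.dti import spd_exp, spd_log
from lvfiber.interpolation import (
    HfcKernel,
    PgdModel,
    PodModel,
    hfc_interpolate,
    hfc_optimize_kernel,
    hfc_weights,
    pgd_build_basis,
    pgd_evaluate,
    pgd_fit,
    pgd_predict_projections,
    pod_build_basis,
    pod_evaluate,
    pod_fit_gappy,
    pod_predict_projections,
    rbm_evaluate,
    rbm_fit,
)
from lvfiber.synthetic import dense_grid_hearts


def _const_frames(n):
    return LocalFrame(
        e_t=np.tile([1.0, 0, 0], (n, 1)),
        e_c=np.tile([0, 1.0, 0], (n, 1)),
        e_l=np.tile([0, 0, 1.0], (n, 1)),
    )


def _random_spd(rng, n, scale=1e-3):
    M = rng.normal(size=(n, 3, 3))
    return scale * (np.einsum("nij,nkj->nik", M, M) + 0.2 * np.eye(3))


class TestHfcWeights:
    def test_zero_distance_is_maximal(self):
        k = HfcKernel.diagonal(0.2, 0.1, 0.2)
        data = np.array([[0.5, 0.5, 0.5], [0.7, 0.5, 0.5]])
        w = hfc_weights(np.array([[0.5, 0.5, 0.5]]), data, k)
        assert w[0, 0] > w[0, 1]

    def test_isotropic_kernel_e_minus_one_ratio(self):
        sigma = 0.2
        k = HfcKernel(sigma * np.eye(3))
        tgt = np.array([[0.5, 0.5, 0.5]])
        data = np.array([[0.5, 0.5, 0.5], [0.5 + sigma, 0.5, 0.5]])
        w = hfc_weights(tgt, data, k)
        assert w[0, 1] / w[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_monotone_in_mahalanobis_distance(self):
        rng = np.random.default_rng(4)
        k = HfcKernel.diagonal(0.3, 0.15, 0.25)
        Hinv2 = np.linalg.inv(k.H @ k.H)
        tgt = np.array([[0.5, 0.5, 0.5]])
        data = rng.uniform(0.1, 0.9, size=(50, 3))
        w = hfc_weights(tgt, data, k)[0]
        d = tgt - data
        d[:, 1] = (d[:, 1] + 0.5) % 1.0 - 0.5
        m = np.einsum("id,de,ie->i", d, Hinv2, d)
        order = np.argsort(m)
        assert (np.diff(w[order]) <= 1e-15).all()

    def test_periodic_wrap_in_c(self):
        k = HfcKernel.diagonal(0.2, 0.1, 0.2)
        w_near = hfc_weights(np.array([[0.5, 0.02, 0.5]]), np.array([[0.5, 0.98, 0.5]]), k)
        w_far = hfc_weights(np.array([[0.5, 0.02, 0.5]]), np.array([[0.5, 0.5, 0.5]]), k)
        assert w_near[0, 0] > w_far[0, 0]

    def test_singular_h_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            HfcKernel(np.diag([0.1, 0.0, 0.1]))


class TestHfcInterpolate:
    def test_single_datum_returned_exactly(self):
        rng = np.random.default_rng(0)
        D = _random_spd(rng, 1)
        fr = _const_frames(1)
        out, _ = hfc_interpolate(
            np.array([[0.4, 0.2, 0.6]]), D, fr, np.array([[0.8, 0.9, 0.1]]), fr,
            HfcKernel.diagonal(0.2, 0.1, 0.2),
        )
        np.testing.assert_allclose(out[0], D[0], rtol=1e-9)

    def test_identical_data_reproduced_everywhere(self):
        rng = np.random.default_rng(1)
        D = np.tile(_random_spd(rng, 1), (6, 1, 1))
        fr = _const_frames(6)
        tgt = rng.uniform(0, 1, size=(4, 3))
        out, _ = hfc_interpolate(rng.uniform(0, 1, (6, 3)), D, fr, tgt, _const_frames(4),
                                 HfcKernel.diagonal(0.3, 0.2, 0.3))
        for o in out:
            np.testing.assert_allclose(o, D[0], rtol=1e-9)

    def test_equal_weights_match_log_euclidean_mean_oracle(self):
        """Equidistant data -> exp(mean(log D_i)), brute-force on <= 10 tensors."""
        rng = np.random.default_rng(2)
        n = 10
        D = _random_spd(rng, n)
        fr = _const_frames(n)
        # all data at the same coordinates -> equal weights
        data_coords = np.tile([0.3, 0.4, 0.5], (n, 1))
        out, _ = hfc_interpolate(data_coords, D, fr, np.array([[0.35, 0.45, 0.55]]),
                                 _const_frames(1), HfcKernel.diagonal(0.2, 0.1, 0.2))
        oracle = spd_exp(sum(spd_log(D[i]) for i in range(n)) / n)
        np.testing.assert_allclose(out[0], oracle, rtol=1e-9)

    def test_bandwidth_to_zero_selects_nearest_datum(self):
        rng = np.random.default_rng(3)
        D = _random_spd(rng, 3)
        fr = _const_frames(3)
        data_coords = np.array([[0.2, 0.2, 0.2], [0.5, 0.5, 0.5], [0.8, 0.8, 0.8]])
        out, _ = hfc_interpolate(data_coords, D, fr, np.array([[0.45, 0.45, 0.45]]),
                                 _const_frames(1), HfcKernel.diagonal(1e-3, 1e-3, 1e-3))
        np.testing.assert_allclose(out[0], D[1], rtol=1e-6)

    def test_weighted_mean_stays_spd(self):
        rng = np.random.default_rng(5)
        D = _random_spd(rng, 20)
        fr = _const_frames(20)
        out, _ = hfc_interpolate(rng.uniform(0, 1, (20, 3)), D, fr,
                                 rng.uniform(0, 1, (15, 3)), _const_frames(15),
                                 HfcKernel.diagonal(0.3, 0.2, 0.3))
        assert np.linalg.eigvalsh(out).min() > 0


class TestHfcOptimize:
    def test_argmin_contract_and_interior_optimum(self, study_dataset):
        bw = np.geomspace(0.03, 0.8, 5)
        kern, info = hfc_optimize_kernel(study_dataset, bandwidths=bw, n_refine=1, holdout="mid")
        assert info["error"] <= min(info["curve"].values()) + 1e-12
        assert np.all(np.diag(kern.H) > 0)

    def test_single_slice_rejected(self, study_dataset):
        from lvfiber.synthetic import SparseCdtiDataset

        one = SparseCdtiDataset(slices=study_dataset.slices[:1])
        with pytest.raises(ValueError, match="2 slices"):
            hfc_optimize_kernel(one)


@pytest.fixture(scope="module")
def small_basis():
    fields, grids = dense_grid_hearts(4, grid_shape=(16, 30, 16), seed=0)
    return pgd_build_basis(fields, grids, n_pgd=3, n_svd=3)


@pytest.fixture(scope="module")
def small_pod():
    fields, grids = dense_grid_hearts(4, grid_shape=(16, 30, 16), seed=0)
    return pod_build_basis(fields, grids, n_pod=4)


class TestPgd:
    def test_full_tensor_product_dof_for_stated_grids(self):
        assert PgdModel().tensor_product_dof == 3360

    def test_separable_input_captured_by_first_mode(self):
        from lvfiber.interpolation import hat_matrix

        grids = (np.linspace(0, 1, 16), np.arange(30) / 30, np.linspace(0, 1, 16))
        F = np.linspace(0.2, 1.0, 16)
        G = 1 + 0.3 * np.sin(2 * np.pi * np.arange(30) / 30)
        H = np.linspace(1.0, 2.0, 16)
        sep = np.einsum("t,c,l->tcl", F, G, H)
        fields = np.stack([np.stack([sep] * 3)] * 2)
        m = pgd_build_basis(fields, grids, n_pgd=2, n_svd=1)
        Pt = hat_matrix(grids[0], 14)
        Pc = hat_matrix(grids[1], 24, periodic=True)
        Pl = hat_matrix(grids[2], 10)
        rec = np.einsum("t,c,l->tcl", Pt @ m.mean[0][0][0], Pc @ m.mean[0][0][1], Pl @ m.mean[0][0][2])
        resid = np.linalg.norm(sep - rec) / np.linalg.norm(sep)
        assert resid < np.sqrt(1e-3)  # mode 1 captures >= 99.9% of the energy

    def test_identical_hearts_have_no_variation_modes(self):
        fields, grids = dense_grid_hearts(1, grid_shape=(12, 24, 12), seed=1, noise_sigma=0)
        fields = np.tile(fields, (3, 1, 1, 1, 1))
        m = pgd_build_basis(fields, grids, n_pgd=2, n_svd=2)
        # SVD of zero-centered identical rows keeps no modes above tolerance
        assert all(
            len(m.svd[d][mm][v]) == 0
            for d in range(3) for mm in range(2) for v in range(3)
        )

    def test_svd_bases_orthonormal(self, small_basis):
        for d in range(3):
            for m in range(small_basis.n_pgd):
                for v in range(3):
                    B = small_basis.svd[d][m][v]
                    if len(B):
                        np.testing.assert_allclose(B @ B.T, np.eye(len(B)), atol=1e-10)

    def test_too_few_hearts_rejected(self):
        fields, grids = dense_grid_hearts(1, grid_shape=(8, 12, 8), seed=0)
        with pytest.raises(ValueError, match="K >= 2"):
            pgd_build_basis(fields, grids)

    def test_in_span_recovery(self, small_basis):
        """Data synthesized from the basis is reconstructed to 1e-8."""
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 1, size=(600, 3))
        true = PgdModel(
            grid_sizes=small_basis.grid_sizes, n_pgd=small_basis.n_pgd,
            n_svd=small_basis.n_svd, mean=small_basis.mean, svd=small_basis.svd,
        )
        true.weights = [
            [
                [np.concatenate([[1.0], 0.3 * rng.normal(size=len(small_basis.svd[d][m][v]))])
                 for v in range(3)]
                for m in range(small_basis.n_pgd)
            ]
            for d in range(3)
        ]
        y = pgd_predict_projections(true, coords)
        fit = pgd_fit(coords, y, small_basis, max_sweeps=4000, tol=0.0)
        yhat = pgd_predict_projections(fit, coords)
        assert np.linalg.norm(yhat - y) / np.linalg.norm(y) < 1e-8

    def test_zero_data_gives_zero_weights(self, small_basis):
        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 1, size=(100, 3))
        fit = pgd_fit(coords, np.zeros((100, 3)), small_basis)
        yhat = pgd_predict_projections(fit, coords)
        np.testing.assert_allclose(yhat, 0.0, atol=1e-12)

    def test_evaluate_returns_unit_sign_fixed_fibers(self, small_basis, study_coords, study_frames):
        rng = np.random.default_rng(9)
        coords = np.column_stack([study_coords.t, study_coords.c, study_coords.l])[::10]
        frames = LocalFrame(study_frames.e_t[::10], study_frames.e_c[::10], study_frames.e_l[::10])
        proj = np.column_stack([0.1 * np.ones(len(coords)), np.ones(len(coords)), 0.5 - coords[:, 0]])
        fit = pgd_fit(coords, proj, small_basis)
        f = pgd_evaluate(fit, coords, frames)
        np.testing.assert_allclose(np.linalg.norm(f, axis=1), 1.0, atol=1e-12)
        assert (np.einsum("ij,ij->i", f, frames.e_c) >= 0).all()


class TestPod:
    def test_basis_orthonormal(self, small_pod):
        for d in range(3):
            np.testing.assert_allclose(
                small_pod.basis[d] @ small_pod.basis[d].T, np.eye(4), atol=1e-10
            )

    def test_singular_values_non_increasing(self, small_pod):
        for sv in small_pod.singular_values:
            assert (np.diff(sv) <= 1e-12).all()

    def test_snapshots_reconstructed_when_rank_covered(self):
        """r-dimensional snapshot family, n_pod >= r -> exact reconstruction."""
        rng = np.random.default_rng(3)
        nt, nc, nl = 6, 12, 8
        grids = (np.linspace(0, 1, nt), np.arange(nc) / nc, np.linspace(0, 1, nl))
        base = rng.normal(size=(3, nc * nl))  # rank-3 family
        mix = rng.normal(size=(2, 3, nt, 3))
        fields = np.einsum("kdtr,rx->kdtx", mix, base).reshape(2, 3, nt, nc, nl)
        m = pod_build_basis(fields, grids, n_pod=3)
        for d in range(3):
            snaps = fields[:, d].reshape(-1, nc * nl)
            proj = snaps @ m.basis[d].T @ m.basis[d]
            np.testing.assert_allclose(proj, snaps, atol=1e-10)

    def test_grid_mismatch_rejected(self):
        fields, grids = dense_grid_hearts(2, grid_shape=(8, 12, 8), seed=0)
        bad = (np.linspace(0, 1, 9), grids[1], grids[2])
        with pytest.raises(ValueError, match="mismatch"):
            pod_build_basis(fields, bad, n_pod=2)

    def test_full_mask_equals_projection_coefficients(self, small_pod):
        """All grid points observed -> weights are the orthogonal projections."""
        rng = np.random.default_rng(4)
        tg, cg, lg = small_pod.grid
        T, C, L = np.meshgrid(tg, cg, lg, indexing="ij")
        coords = np.column_stack([T.ravel(), C.ravel(), L.ravel()])
        W = rng.normal(size=(3, len(tg), 4))
        true = PodModel(grid=small_pod.grid, n_pod=4, basis=small_pod.basis, weights=W)
        y = pod_predict_projections(true, coords)
        fit = pod_fit_gappy(coords, y, small_pod)
        np.testing.assert_allclose(fit.weights, W, atol=1e-8)

    def test_in_span_recovery_from_sparse_grid_samples(self, small_pod):
        rng = np.random.default_rng(5)
        tg, cg, lg = small_pod.grid
        ii = rng.integers(0, len(tg), 3000)
        jj = rng.integers(0, len(cg), 3000)
        kk = rng.integers(0, len(lg), 3000)
        coords = np.column_stack([tg[ii], cg[jj], lg[kk]])
        W = rng.normal(size=(3, len(tg), 4))
        true = PodModel(grid=small_pod.grid, n_pod=4, basis=small_pod.basis, weights=W)
        y = pod_predict_projections(true, coords)
        fit = pod_fit_gappy(coords, y, small_pod)
        yhat = pod_predict_projections(fit, coords)
        assert np.linalg.norm(yhat - y) / np.linalg.norm(y) < 1e-8

    def test_empty_transmural_index_filled_by_interpolation(self, small_pod):
        rng = np.random.default_rng(6)
        tg, cg, lg = small_pod.grid
        # observe only the first and last transmural levels
        jj = rng.integers(0, len(cg), 2000)
        kk = rng.integers(0, len(lg), 2000)
        half = 1000
        coords = np.column_stack([
            np.concatenate([np.full(half, tg[0]), np.full(half, tg[-1])]),
            cg[jj], lg[kk],
        ])
        W = rng.normal(size=(3, len(tg), 4))
        true = PodModel(grid=small_pod.grid, n_pod=4, basis=small_pod.basis, weights=W)
        y = pod_predict_projections(true, coords)
        fit = pod_fit_gappy(coords, y, small_pod)
        mid = len(tg) // 2
        frac = mid / (len(tg) - 1)
        expect = (1 - frac) * fit.weights[:, 0] + frac * fit.weights[:, -1]
        np.testing.assert_allclose(fit.weights[:, mid], expect, atol=1e-8)


class TestRbm:
    def test_exact_recovery_on_linear_truth(self):
        t = np.linspace(0, 1, 30)
        p = rbm_fit(t, 60.0 - 120.0 * t, np.zeros_like(t))
        assert p.alpha_endo == pytest.approx(60.0, abs=1e-10)
        assert p.alpha_epi == pytest.approx(-60.0, abs=1e-10)
        assert p.beta_endo == pytest.approx(0.0, abs=1e-10)
        assert p.beta_epi == pytest.approx(0.0, abs=1e-10)
        assert p.n_parameters == 4

    def test_constant_angles(self):
        t = np.linspace(0, 1, 10)
        p = rbm_fit(t, np.full_like(t, 30.0), np.full_like(t, -5.0))
        assert p.alpha_endo == pytest.approx(p.alpha_epi) == pytest.approx(30.0)
        assert p.beta_endo == pytest.approx(p.beta_epi) == pytest.approx(-5.0)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        t = rng.uniform(0, 1, 200)
        h = 50 - 100 * t + rng.normal(scale=8, size=200)
        b = 5 - 12 * t + rng.normal(scale=4, size=200)
        p = rbm_fit(t, h, b)
        X = np.column_stack([1 - t, t])
        ah = np.linalg.solve(X.T @ X, X.T @ h)
        ab = np.linalg.solve(X.T @ X, X.T @ b)
        assert (p.alpha_endo, p.alpha_epi) == pytest.approx(tuple(ah), abs=1e-10)
        assert (p.beta_endo, p.beta_epi) == pytest.approx(tuple(ab), abs=1e-10)

    def test_single_transmural_position_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            rbm_fit(np.full(5, 0.5), np.zeros(5), np.zeros(5))

    def test_evaluate_helix_boundary_values(self, study_frames):
        from lvfiber.angles import helix_angle
        from lvfiber.interpolation import RbmParams

        p = RbmParams(55.0, -65.0, 0.0, 0.0)
        n = 50
        fr = LocalFrame(study_frames.e_t[:n], study_frames.e_c[:n], study_frames.e_l[:n])
        f_endo = rbm_evaluate(p, np.zeros(n), fr)
        h = helix_angle(f_endo, fr.e_t, fr.e_c, fr.e_l)
        np.testing.assert_allclose(h, 55.0, atol=1e-9)
        f0 = rbm_evaluate(RbmParams(0, 0, 0, 0), np.linspace(0, 1, n), fr)
        np.testing.assert_allclose(f0, fr.e_c, atol=1e-12)
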