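"""Synthetic microstructure, diffusion forward model, slice sampling."""

import numpy as np
import pytest

from lvfiber.coordinates import LocalFrame
from lvfiber.synthetic import (
    DwiAcquisition,
    make_ground_truth_fibers,
    invivo_acquisition,
    sample_short_axis_slices,
    simulate_dwi,
    tensors_from_fibers,
)


class TestGroundTruthFibers:
    def test_zero_profile_gives_circumferential_fibers(self, study_coords, study_frames):
        gt = make_ground_truth_fibers(
            study_coords, study_frames, helix_profile=(0.0, 0.0), transverse_profile=(0.0, 0.0)
        )
        np.testing.assert_allclose(gt.fibers, study_frames.e_c, atol=1e-12)

    def test_helix_round_trip_exact(self, study_coords, study_frames):
        from lvfiber.angles import helix_angle

        gt = make_ground_truth_fibers(study_coords, study_frames, helix_profile=(60.0, -60.0))
        h = helix_angle(gt.fibers, study_frames.e_t, study_frames.e_c, study_frames.e_l)
        np.testing.assert_allclose(h, 60.0 - 120.0 * study_coords.t, atol=1e-6)

    def test_perturbation_determinism_contract(self, study_lv, study_coords, study_frames):
        kw = dict(perturbation_sigma=10.0, nodes=study_lv.nodes)
        a = make_ground_truth_fibers(study_coords, study_frames, seed=1, **kw)
        b = make_ground_truth_fibers(study_coords, study_frames, seed=1, **kw)
        c = make_ground_truth_fibers(study_coords, study_frames, seed=2, **kw)
        np.testing.assert_array_equal(a.fibers, b.fibers)
        assert not np.allclose(a.fibers, c.fibers)

    def test_perturbation_zero_mean_and_unit_norm(self, study_lv, study_coords, study_frames):
        gt = make_ground_truth_fibers(
            study_coords, study_frames, perturbation_sigma=10.0, seed=3, nodes=study_lv.nodes
        )
        assert abs(gt.helix_noise.mean()) < 1.0  # degrees
        np.testing.assert_allclose(np.linalg.norm(gt.fibers, axis=1), 1.0, atol=1e-12)


class TestTensorsFromFibers:
    FRAMES = LocalFrame(
        e_t=np.tile([1.0, 0, 0], (5, 1)),
        e_c=np.tile([0, 1.0, 0], (5, 1)),
        e_l=np.tile([0, 0, 1.0], (5, 1)),
    )

    def _fibers(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=(5, 3))
        return f / np.linalg.norm(f, axis=1, keepdims=True)

    def test_principal_eigenvector_is_fiber(self):
        f = self._fibers()
        D = tensors_from_fibers(f, self.FRAMES)
        w, V = np.linalg.eigh(D)
        lead = V[:, :, -1]
        np.testing.assert_allclose(np.abs(np.einsum("ij,ij->i", lead, f)), 1.0, atol=1e-10)

    def test_trace_conserved_exactly(self):
        D = tensors_from_fibers(self._fibers(), self.FRAMES, (1.5e-3, 0.8e-3, 0.5e-3))
        np.testing.assert_allclose(np.trace(D, axis1=1, axis2=2), 2.8e-3, atol=1e-18)

    def test_repeated_eigenvalues_rejected(self):
        with pytest.raises(ValueError, match="l1 > l2 > l3"):
            tensors_from_fibers(self._fibers(), self.FRAMES, (1.0e-3, 1.0e-3, 0.5e-3))


class TestSimulateDwi:
    def test_noiseless_signal_exact(self):
        acq = invivo_acquisition(seed=0, noise_model="none")
        D = np.diag([1.5e-3, 0.8e-3, 0.5e-3])[None]
        S = simulate_dwi(D, acq)
        quad = np.einsum("vi,ij,vj->v", acq.bvecs, D[0], acq.bvecs)
        np.testing.assert_allclose(S[0], acq.s0 * np.exp(-acq.bvals * quad), rtol=1e-14)

    def test_isotropic_tensor_direction_independent(self):
        acq = invivo_acquisition(seed=0, noise_model="none")
        S = simulate_dwi(1e-3 * np.eye(3)[None], acq)[0]
        for b in (100, 200, 450):
            vals = S[acq.bvals == b]
            np.testing.assert_allclose(vals, vals[0], rtol=1e-12)

    def test_averaging_shrinks_standard_error(self):
        """Eight averages cut the per-voxel noise by about 1/sqrt(8)."""
        D = np.tile(np.diag([1.5e-3, 0.8e-3, 0.5e-3]), (1500, 1, 1))
        acq1 = invivo_acquisition(seed=0, snr=10.0, n_averages=1, noise_model="rician")
        acq8 = invivo_acquisition(seed=0, snr=10.0, n_averages=8, noise_model="rician")
        S1 = simulate_dwi(D, acq1, seed=5)
        S8 = simulate_dwi(D, acq8, seed=5)
        ratio = S8[:, 0].std() / S1[:, 0].std()
        assert ratio == pytest.approx(1.0 / np.sqrt(8.0), rel=0.10)

    def test_invalid_snr_raises(self):
        with pytest.raises(ValueError, match="snr"):
            invivo_acquisition(seed=0, snr=0.0, noise_model="rician")

    def test_bad_bvec_norm_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            DwiAcquisition(bvals=np.array([100.0]), bvecs=np.array([[2.0, 0, 0]]))


class TestSliceSampling:
    def test_samples_inside_myocardium(self, study_dataset):
        for sl in study_dataset.slices:
            assert sl.coords[:, 0].min() >= 0.0 and sl.coords[:, 0].max() <= 1.0
            assert sl.coords[:, 2].min() >= 0.0 and sl.coords[:, 2].max() <= 1.0

    def test_slices_ordered_apex_to_base(self, study_dataset):
        z = [sl.slice_position for sl in study_dataset.slices]
        assert z == sorted(z)
        med_l = [float(np.median(sl.coords[:, 2])) for sl in study_dataset.slices]
        assert med_l == sorted(med_l)

    def test_single_slice_shares_longitudinal_band(self, study_lv, study_coords, study_frames):
        gt = make_ground_truth_fibers(study_coords, study_frames)
        D = tensors_from_fibers(gt.fibers, study_frames)
        ds = sample_short_axis_slices(study_lv, study_coords, study_frames, D, n_slices=1)
        sl = ds.slices[0]
        np.testing.assert_allclose(sl.positions[:, 2], sl.slice_position)
        # one 8 mm slab spans a limited longitudinal band
        assert np.ptp(sl.coords[:, 2]) < 0.25

    def test_sample_count_scales_linearly(self, study_lv, study_coords, study_frames):
        gt = make_ground_truth_fibers(study_coords, study_frames)
        D = tensors_from_fibers(gt.fibers, study_frames)
        counts = {}
        for n in (3, 6):
            ds = sample_short_axis_slices(
                study_lv, study_coords, study_frames, D, n_slices=n, in_plane_spacing=3.0
            )
            counts[n] = ds.n_samples
        assert counts[6] == pytest.approx(2 * counts[3], rel=0.35)

    def test_zero_slices_rejected(self, study_lv, study_coords, study_frames):
        gt = make_ground_truth_fibers(study_coords, study_frames)
        D = tensors_from_fibers(gt.fibers, study_frames)
        with pytest.raises(ValueError, match="n_slices"):
            sample_short_axis_slices(study_lv, study_coords, study_frames, D, n_slices=0)

    def test_oversized_stack_rejected(self, study_lv, study_coords, study_frames):
        gt = make_ground_truth_fibers(study_coords, study_frames)
        D = tensors_from_fibers(gt.fibers, study_frames)
        with pytest.raises(ValueError, match="does not fit"):
            sample_short_axis_slices(study_lv, study_coords, study_frames, D, n_slices=30)

    def test_tensor_samples_spd(self, study_dataset):
        for sl in study_dataset.slices:
            w = np.linalg.eigvalsh(sl.tensors)
            assert w.min() > 0
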