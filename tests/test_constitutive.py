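"""Holzapfel-Ogden passive law, volumetric penalty, active elastance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvfiber.constitutive import (
    ActiveParams,
    HoParams,
    active_stress_tensor,
    active_tension,
    fiber_sheet_stress,
    ho_isochoric_energy,
    passive_cauchy_stress,
    volumetric_energy,
)

F0 = np.array([1.0, 0.0, 0.0])
S0 = np.array([0.0, 1.0, 0.0])


def _random_structure(seed):
    rng = np.random.default_rng(seed)
    f = rng.normal(size=3)
    f /= np.linalg.norm(f)
    s = np.cross(f, rng.normal(size=3))
    s /= np.linalg.norm(s)
    F = np.eye(3) + 0.08 * rng.normal(size=(3, 3))
    if np.linalg.det(F) <= 0.1:
        F = np.eye(3) + 0.02 * rng.normal(size=(3, 3))
    return F, f, s


class TestPassiveEnergy:
    def test_reference_state_energy_is_isotropic_offset(self):
        p = HoParams()
        e = ho_isochoric_energy(np.eye(3), F0, S0, p)
        assert e == pytest.approx(p.A * p.a_iso / (2 * p.b_iso), rel=1e-14)

    def test_energy_linear_in_scaling_A(self):
        F, f, s = _random_structure(0)
        C = F.T @ F
        e1 = ho_isochoric_energy(C, f, s, HoParams(A=1.0))
        e2 = ho_isochoric_energy(C, f, s, HoParams(A=2.0))
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_non_spd_C_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            ho_isochoric_energy(np.diag([1.0, -0.5, 1.0]), F0, S0)

    def test_fiber_term_inactive_in_compression(self):
        """Shortening along the fiber must not add fiber-exponential energy."""
        C = np.diag([0.9**2, 1.0 / 0.9, 1.0 / 0.9])  # isochoric fiber shortening
        p = HoParams()
        e = ho_isochoric_energy(C, F0, S0, p)
        p_no_f = HoParams(a_f=0.0)
        assert e == pytest.approx(
            ho_isochoric_energy(C, F0, S0, p_no_f)
            + 0.0,
            rel=1e-12,
        )


class TestVolumetricEnergy:
    def test_incompressible_state_zero(self):
        assert volumetric_energy(1.0, 0.1) == 0.0

    def test_printed_form_spot_value(self):
        # (1/D)((J^2-1)/2 - ln J) at J = 1.1, D = 0.1
        assert volumetric_energy(1.1, 0.1) == pytest.approx(
            10.0 * ((1.1**2 - 1) / 2 - np.log(1.1)), rel=1e-14
        )
        assert volumetric_energy(1.1, 0.1) == pytest.approx(0.09690, abs=5e-6)

    def test_convex_near_identity(self):
        h = 1e-3
        second = (
            volumetric_energy(1 + h, 0.1) - 2 * volumetric_energy(1.0, 0.1)
            + volumetric_energy(1 - h, 0.1)
        )
        assert second > 0

    def test_nonpositive_jacobian_rejected(self):
        with pytest.raises(ValueError, match="J"):
            volumetric_energy(0.0, 0.1)


class TestPassiveStress:
    def test_zero_at_identity(self):
        sig = passive_cauchy_stress(np.eye(3), F0, S0)
        assert np.abs(sig).max() < 1e-10

    def test_pure_rotation_zero_stress(self):
        rng = np.random.default_rng(1)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        sig = passive_cauchy_stress(Q, F0, S0)
        assert np.abs(sig).max() < 1e-10

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_finite_difference_of_energy(self, seed):
        F, f, s = _random_structure(seed)
        p = HoParams()

        def energy(Fm):
            return ho_isochoric_energy(Fm.T @ Fm, f, s, p) + volumetric_energy(
                np.linalg.det(Fm), p.D
            )

        h = 1e-6
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                P[i, j] = (energy(Fp) - energy(Fm)) / (2 * h)
        sig_fd = P @ F.T / np.linalg.det(F)
        sig_fd = 0.5 * (sig_fd + sig_fd.T)
        sig = passive_cauchy_stress(F, f, s, p)
        scale = max(np.abs(sig_fd).max(), 1e-12)
        assert np.abs(sig - sig_fd).max() / scale < 1e-6

    def test_objectivity_under_simultaneous_rotation(self):
        F, f, s = _random_structure(2)
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        sig = passive_cauchy_stress(F, f, s)
        sig_rot = passive_cauchy_stress(Q @ F, f, s)  # material vectors unchanged
        np.testing.assert_allclose(sig_rot, Q @ sig @ Q.T, atol=1e-10)

    def test_inverted_deformation_rejected(self):
        with pytest.raises(ValueError, match="det F"):
            passive_cauchy_stress(-np.eye(3), F0, S0)


class TestActiveTension:
    def test_zero_at_activation_onset(self):
        assert active_tension(0.0, 0.0) == 0.0

    def test_zero_after_relaxation_ends(self):
        p = ActiveParams()
        l = p.l_r  # E_ff = 0
        t_r = p.m * l + p.b
        assert active_tension(p.t0 + t_r, 0.0, p) == 0.0
        assert active_tension(p.t0 + t_r + 100.0, 0.0, p) == 0.0

    def test_peak_value_at_t0_matches_direct_evaluation(self):
        """Closed-form check of the elastance at peak activation."""
        p = ActiveParams()
        l = p.l_r
        eca50 = p.Ca0_max / np.sqrt(np.exp(p.B * 1e-3 * (l - p.l0)) - 1.0)
        expect = p.T_max * p.Ca0**2 / (p.Ca0**2 + eca50**2)
        assert active_tension(p.t0, 0.0, p) == pytest.approx(expect, rel=1e-12)
        assert expect / p.T_max == pytest.approx(0.9942, abs=1e-4)

    def test_continuous_across_phase_boundaries(self):
        p = ActiveParams()
        t_r = p.m * p.l_r + p.b
        for t_star in (p.t0, p.t0 + t_r):
            below = active_tension(t_star - 1e-9, 0.0, p)
            above = active_tension(t_star + 1e-9, 0.0, p)
            assert above == pytest.approx(below, abs=1e-6)

    def test_non_negative_everywhere(self):
        p = ActiveParams()
        for t in np.linspace(0, 1200, 60):
            for eff in (-0.1, 0.0, 0.15):
                assert active_tension(t, eff, p) >= 0.0

    def test_switch_kills_tension_below_threshold_length(self):
        p = ActiveParams()
        # E_ff chosen so l < l0
        eff = 0.5 * ((p.l0 * 0.9 / p.l_r) ** 2 - 1.0)
        assert active_tension(p.t0, eff, p) == 0.0

    def test_unphysical_compression_rejected(self):
        with pytest.raises(ValueError, match="compression"):
            active_tension(10.0, -0.75)


class TestFiberSheetStress:
    def test_no_sheet_term_when_n_zero(self):
        act = active_stress_tensor(3.0, F0, S0, 0.0)
        np.testing.assert_allclose(act, 3.0 * np.outer(F0, F0), atol=1e-14)

    def test_equal_magnitudes_when_n_one(self):
        act = active_stress_tensor(3.0, F0, S0, 1.0)
        assert act[0, 0] == act[1, 1] == 3.0

    def test_trace_identity(self):
        T, n = 2.5, 0.4
        act = active_stress_tensor(T, F0, S0, n)
        assert np.trace(act) == pytest.approx(T * (1 + n), rel=1e-14)

    def test_total_is_passive_plus_active(self):
        sig_p = np.diag([1.0, 2.0, 3.0])
        total = fiber_sheet_stress(sig_p, 2.0, F0, S0, 0.5)
        np.testing.assert_allclose(total, sig_p + active_stress_tensor(2.0, F0, S0, 0.5))

    def test_n_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="n_sheet"):
            active_stress_tensor(1.0, F0, S0, 1.5)
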