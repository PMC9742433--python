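"""Material-point constitutive laws of the LV model.

Passive response: orthotropic Holzapfel-Ogden strain energy on the
isochoric invariants of the right Cauchy-Green tensor, scaled by a
personalization factor A, plus a volumetric penalty controlled by the
inverse-bulk parameter D.  Active response: a Guccione-type time-varying
elastance model with length-dependent calcium sensitivity; the active
stress acts in the fiber direction and, scaled by n in [0, 1], in the
sheet direction.

Units: the passive stiffness parameters a_* are in kPa (energies and
passive stresses come out in kPa); T_max is specified in MPa as is
conventional for this model, and active_tension returns the same unit as
T_max.  Convert explicitly (1 MPa = 1000 kPa) before mixing the two; the
helper :func:`active_stress_tensor` takes the tension in kPa.
Sarcomere lengths are in micrometers, times in milliseconds; B is given
per millimeter and converted internally (4750 mm^-1 = 4.75 um^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HoParams",
    "ActiveParams",
    "ho_isochoric_energy",
    "volumetric_energy",
    "passive_cauchy_stress",
    "active_tension",
    "active_stress_tensor",
    "fiber_sheet_stress",
]


@dataclass
class HoParams:
    """Holzapfel-Ogden parameters (a_* in kPa, b_* dimensionless).

    Defaults are the porcine-calibrated values used as initial setting of
    the LV model; A linearly scales the stress-like coefficients and D is
    the inverse multiple of the bulk modulus (D = 2/K).
    """

    a_iso: float = 0.0943
    b_iso: float = 5.874
    a_f: float = 0.311
    b_f: float = 11.271
    a_s: float = 0.0431
    b_s: float = 9.772
    a_fs: float = 0.0254
    b_fs: float = 2.405
    A: float = 1.0
    D: float = 0.1

    def __post_init__(self):
        if min(self.a_iso, self.a_f, self.a_s, self.a_fs) < 0:
            raise ValueError("stress-like parameters a_* must be non-negative")
        if min(self.b_iso, self.b_f, self.b_s, self.b_fs) <= 0:
            raise ValueError("exponents b_* must be positive")
        if self.A <= 0 or self.D <= 0:
            raise ValueError("A and D must be positive")


@dataclass
class ActiveParams:
    """Time-varying elastance parameters.

    T_max (MPa) and t0 (ms) are personalization targets with no canonical
    value; their defaults here are physiologically typical placeholders.
    """

    T_max: float = 0.1  # MPa
    Ca0: float = 4.35  # umol/L
    Ca0_max: float = 4.35  # umol/L
    B: float = 4750.0  # mm^-1 (= 4.75 um^-1)
    l0: float = 0.75  # um
    l_r: float = 1.835  # um
    t0: float = 150.0  # ms
    m: float = 300.0  # ms/um
    b: float = -0.38  # ms
    n_sheet: float = 0.5  # dimensionless, in [0, 1]
    switch_delta: float = 0.01  # um, smooth-ramp width above l0

    def __post_init__(self):
        if not 0.0 <= self.n_sheet <= 1.0:
            raise ValueError("n_sheet must lie in [0, 1]")
        if self.l_r <= self.l0:
            raise ValueError("resting sarcomere length must exceed the zero-force length")


def _invariants(Cb: np.ndarray, f: np.ndarray, s: np.ndarray):
    I1 = np.trace(Cb)
    I4f = f @ Cb @ f
    I4s = s @ Cb @ s
    I8 = f @ Cb @ s
    return I1, I4f, I4s, I8


def _check_unit(v, name):
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-8:
        raise ValueError(f"{name} must be a unit vector")
    return v


def ho_isochoric_energy(C: np.ndarray, f: np.ndarray, s: np.ndarray,
                        params: HoParams | None = None) -> float:
    """Isochoric Holzapfel-Ogden energy density (kPa).

    Evaluated on the isochoric invariants of C_bar = J^(-2/3) C; the
    fiber and sheet exponential terms contribute only in tension
    (I4 > 1), the standard convention for this model.
    """
    p = params or HoParams()
    C = np.asarray(C, dtype=float)
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    w = np.linalg.eigvalsh(C)
    if np.any(w <= 0):
        raise ValueError("C must be positive definite")
    f = _check_unit(f, "f")
    s = _check_unit(s, "s")
    J2 = np.linalg.det(C)  # = J^2
    Cb = J2 ** (-1.0 / 3.0) * C
    I1, I4f, I4s, I8 = _invariants(Cb, f, s)
    psi = p.A * p.a_iso / (2 * p.b_iso) * np.exp(p.b_iso * (I1 - 3.0))
    for a_i, b_i, I4 in ((p.a_f, p.b_f, I4f), (p.a_s, p.b_s, I4s)):
        if I4 > 1.0:
            psi += p.A * a_i / (2 * b_i) * (np.exp(b_i * (I4 - 1.0) ** 2) - 1.0)
    psi += p.A * p.a_fs / (2 * p.b_fs) * (np.exp(p.b_fs * I8**2) - 1.0)
    return float(psi)


def volumetric_energy(J: float, D: float = 0.1) -> float:
    """Volumetric penalty (1/D) ((J^2 - 1)/2 - ln J); zero at J = 1."""
    if J <= 0:
        raise ValueError("J must be positive")
    if D <= 0:
        raise ValueError("D must be positive")
    return (1.0 / D) * ((J**2 - 1.0) / 2.0 - np.log(J))


def passive_cauchy_stress(F: np.ndarray, f: np.ndarray, s: np.ndarray,
                          params: HoParams | None = None) -> np.ndarray:
    """Passive Cauchy stress sigma = (2/J) F dPsi/dC F^T (kPa).

    Analytic derivative of the isochoric energy (with the deviatoric
    projection of the isochoric split) plus the volumetric pressure term.
    The structural vectors f, s are material (reference) directions.
    """
    p = params or HoParams()
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if J <= 0:
        raise ValueError("det F must be positive")
    f = _check_unit(f, "f")
    s = _check_unit(s, "s")
    C = F.T @ F
    Cinv = np.linalg.inv(C)
    Cb = J ** (-2.0 / 3.0) * C
    I1, I4f, I4s, I8 = _invariants(Cb, f, s)

    dpsi1 = p.A * p.a_iso / 2.0 * np.exp(p.b_iso * (I1 - 3.0))
    Sbar = 2.0 * dpsi1 * np.eye(3)
    for a_i, b_i, I4, v in ((p.a_f, p.b_f, I4f, f), (p.a_s, p.b_s, I4s, s)):
        if I4 > 1.0:
            dpsi4 = p.A * a_i * (I4 - 1.0) * np.exp(b_i * (I4 - 1.0) ** 2)
            Sbar += 2.0 * dpsi4 * np.outer(v, v)
    dpsi8 = p.A * p.a_fs * I8 * np.exp(p.b_fs * I8**2)
    Sbar += dpsi8 * (np.outer(f, s) + np.outer(s, f))

    S_iso = J ** (-2.0 / 3.0) * (Sbar - (np.tensordot(Sbar, C) / 3.0) * Cinv)
    pressure = (1.0 / p.D) * (J - 1.0 / J)  # dPsi_vol/dJ
    S_vol = J * pressure * Cinv
    sigma = (F @ (S_iso + S_vol) @ F.T) / J
    return 0.5 * (sigma + sigma.T)


def _omega(t: float, t0: float, t_r: float) -> float:
    """Phase angle of the cosine elastance: rise over [0, t0), relaxation
    over [t0, t0 + t_r), zero tension afterwards."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if t < t0:
        return np.pi * t / t0
    if t < t0 + t_r:
        return np.pi * (t - t0 + t_r) / t_r
    return 0.0


def active_tension(t: float, E_ff: float, params: ActiveParams | None = None) -> float:
    """Active fiber tension at time t (ms) after activation (unit of T_max).

    T = T_max * Ca0^2 / (Ca0^2 + ECa50(l)^2) * (1 - cos(omega(t))) / 2 with
    sarcomere length l = l_r sqrt(2 E_ff + 1), length-dependent calcium
    sensitivity ECa50 = Ca0_max / sqrt(exp(B (l - l0)) - 1), and relaxation
    time t_r = m l + b.  Below the zero-force length l0 the tension is
    switched off, with a smooth linear ramp over [l0, l0 + switch_delta].
    """
    p = params or ActiveParams()
    if 2.0 * E_ff + 1.0 < 0:
        raise ValueError("2 E_ff + 1 < 0: unphysical fiber compression")
    l = p.l_r * np.sqrt(2.0 * E_ff + 1.0)
    if l <= p.l0:
        return 0.0
    ramp = min(1.0, (l - p.l0) / p.switch_delta) if p.switch_delta > 0 else 1.0
    B_um = p.B * 1e-3  # mm^-1 -> um^-1
    denom = np.exp(B_um * (l - p.l0)) - 1.0
    eca50 = p.Ca0_max / np.sqrt(denom)
    t_r = p.m * l + p.b
    ct = 0.5 * (1.0 - np.cos(_omega(float(t), p.t0, t_r)))
    return float(p.T_max * p.Ca0**2 / (p.Ca0**2 + eca50**2) * ct * ramp)


def active_stress_tensor(T_active: float, f: np.ndarray, s: np.ndarray,
                         n_sheet: float) -> np.ndarray:
    """Active stress T f (x) f + n T s (x) s (unit of T_active)."""
    if not 0.0 <= n_sheet <= 1.0:
        raise ValueError("n_sheet must lie in [0, 1]")
    f = _check_unit(f, "f")
    s = _check_unit(s, "s")
    return T_active * np.outer(f, f) + n_sheet * T_active * np.outer(s, s)


def fiber_sheet_stress(sigma_passive: np.ndarray, T_active: float, f: np.ndarray,
                       s: np.ndarray, n_sheet: float) -> np.ndarray:
    """Total stress: passive plus active fiber/sheet contributions.

    ``sigma_passive`` and ``T_active`` must share one unit (kPa
    recommended; convert T_max from MPa first).
    """
    return np.asarray(sigma_passive, dtype=float) + active_stress_tensor(T_active, f, s, n_sheet)
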