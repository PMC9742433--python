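"""Diffusion-tensor estimation and SPD matrix utilities.

The diffusion tensor D (mm^2/s) is fitted per voxel from multi-b-value
DWI signals by inverting the log-linear signal model

    ln S = ln S0 - b g^T D g

with the Moore-Penrose pseudo-inverse; ln S0 is co-estimated as a seventh
unknown (the acquisition has no b = 0 volume).  The matrix logarithm and
exponential on the SPD cone back the log-Euclidean tensor interpolation.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "fit_tensor_pinv",
    "principal_fiber",
    "spd_log",
    "spd_exp",
    "clamp_spd",
    "fractional_anisotropy",
]

# order of the 6 unique tensor components in the design matrix
_IJ = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows ``[1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]``."""
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    cols = [np.ones_like(bvals)]
    for i, j in _IJ:
        fac = 1.0 if i == j else 2.0
        cols.append(-bvals * fac * bvecs[:, i] * bvecs[:, j])
    return np.column_stack(cols)


def fit_tensor_pinv(signals: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray):
    """Fit (D, ln S0) from DWI signals by pseudo-inverse.

    Parameters
    ----------
    signals : (V,) or (n_voxels, V) positive array
    bvals : (V,) array, s/mm^2
    bvecs : (V, 3) unit gradient directions

    Returns
    -------
    D : (3, 3) or (n_voxels, 3, 3) symmetric tensors, clamped to SPD
    ln_s0 : scalar or (n_voxels,)

    Raises on a rank-deficient design matrix.  Voxels containing
    non-positive signals are returned as NaN tensors with a warning.
    """
    signals = np.asarray(signals, dtype=float)
    single = signals.ndim == 1
    S = np.atleast_2d(signals)
    A = design_matrix(bvals, bvecs)
    if len(bvals) < 7:
        raise ValueError(f"need >= 7 volumes to fit 6 tensor components + ln S0, got {len(bvals)}")
    rank = np.linalg.matrix_rank(A)
    if rank < 7:
        raise ValueError(f"rank-deficient design matrix (rank {rank} < 7); add encoding directions")
    ok = np.all(S > 0, axis=1)
    if not ok.all():
        warnings.warn(f"{np.sum(~ok)} voxels with non-positive signals skipped (NaN output)")
    pinv = np.linalg.pinv(A)
    x = np.full((len(S), 7), np.nan)
    x[ok] = (pinv @ np.log(S[ok]).T).T
    D = np.empty((len(S), 3, 3))
    for n, (i, j) in enumerate(_IJ):
        D[:, i, j] = D[:, j, i] = x[:, 1 + n]
    D[ok] = clamp_spd(D[ok])
    ln_s0 = x[:, 0]
    if single:
        return D[0], float(ln_s0[0])
    return D, ln_s0


def clamp_spd(D: np.ndarray, floor_rel: float = 1e-9) -> np.ndarray:
    """Clamp eigenvalues to >= floor_rel * trace (with an absolute floor)."""
    D = 0.5 * (D + np.swapaxes(D, -1, -2))
    w, V = np.linalg.eigh(D)
    tr = np.clip(np.trace(D, axis1=-2, axis2=-1), 1e-30, None)
    floor = floor_rel * tr
    w = np.maximum(w, floor[..., None])
    return np.einsum("...ik,...k,...jk->...ij", V, w, V)


def spd_log(D: np.ndarray) -> np.ndarray:
    """Matrix logarithm of SPD tensors via eigendecomposition."""
    D = np.asarray(D, dtype=float)
    if not np.allclose(D, np.swapaxes(D, -1, -2), atol=1e-10 * max(1.0, float(np.abs(D).max()))):
        raise ValueError("spd_log requires a symmetric matrix")
    w, V = np.linalg.eigh(0.5 * (D + np.swapaxes(D, -1, -2)))
    if np.any(w <= 0):
        raise ValueError("spd_log requires positive eigenvalues; clamp_spd the input first")
    return np.einsum("...ik,...k,...jk->...ij", V, np.log(w), V)


def spd_exp(M: np.ndarray) -> np.ndarray:
    """Matrix exponential of symmetric matrices (lands on the SPD cone)."""
    M = np.asarray(M, dtype=float)
    if not np.allclose(M, np.swapaxes(M, -1, -2), atol=1e-10 * max(1.0, float(np.abs(M).max()))):
        raise ValueError("spd_exp requires a symmetric matrix")
    w, V = np.linalg.eigh(0.5 * (M + np.swapaxes(M, -1, -2)))
    return np.einsum("...ik,...k,...jk->...ij", V, np.exp(w), V)


def principal_fiber(D: np.ndarray, e_c: np.ndarray, e_l: np.ndarray | None = None,
                    e_t: np.ndarray | None = None, gap_rel: float = 1e-12):
    """First eigenvector with the sign fixed to a positive circumferential
    component; ties broken by e_l, then e_t components.

    Works on single tensors or stacked arrays.  Voxels with a degenerate
    leading eigenvalue (gap <= gap_rel * trace) are flagged with a warning
    but still returned.
    """
    D = np.asarray(D, dtype=float)
    single = D.ndim == 2
    Ds = D[None] if single else D
    e_c = np.atleast_2d(e_c)
    w, V = np.linalg.eigh(Ds)
    f = V[..., -1]  # eigenvector of the largest eigenvalue
    gap = w[..., -1] - w[..., -2]
    tr = np.trace(Ds, axis1=-2, axis2=-1)
    degen = gap <= gap_rel * np.abs(tr)
    if degen.any():
        warnings.warn(f"{int(degen.sum())} tensors have a degenerate leading eigenvalue")
    dot = np.einsum("ij,ij->i", f, np.broadcast_to(e_c, f.shape))
    sign = np.sign(dot)
    if e_l is not None:
        e_l = np.atleast_2d(e_l)
        tie = sign == 0
        sign[tie] = np.sign(np.einsum("ij,ij->i", f, np.broadcast_to(e_l, f.shape)))[tie]
    if e_t is not None:
        e_t = np.atleast_2d(e_t)
        tie = sign == 0
        sign[tie] = np.sign(np.einsum("ij,ij->i", f, np.broadcast_to(e_t, f.shape)))[tie]
    sign[sign == 0] = 1.0
    f = f * sign[:, None]
    f /= np.linalg.norm(f, axis=1, keepdims=True)
    return (f[0], bool(degen[0])) if single else (f, degen)


def fractional_anisotropy(D: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(np.asarray(D, dtype=float))
    mean = w.mean(axis=-1, keepdims=True)
    num = np.sum((w - mean) ** 2, axis=-1)
    den = np.sum(w**2, axis=-1)
    return np.sqrt(1.5 * num / np.where(den == 0, 1.0, den))
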