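"""Interpolation-quality analyses.

The central protocol is leave-one-slice-out: exclude one mid-ventricular
short-axis slice, interpolate the remaining sparse data onto the excluded
slice's coordinates, and compare the interpolated fibers with the held-out
first eigenvectors by the absolute (sign-invariant) angular difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import helix_angle, line_angle_diff, transverse_angle
from .coordinates import LocalFrame
from .dti import clamp_spd, principal_fiber
from .interpolation import (
    HfcKernel,
    hfc_interpolate,
    pgd_evaluate,
    pgd_fit,
    pod_evaluate,
    pod_fit_gappy,
    rbm_evaluate,
    rbm_fit,
)
from .synthetic import SparseCdtiDataset

__all__ = [
    "LooResult",
    "leave_one_slice_out",
    "mutual_difference",
    "angle_summary",
]

_PCTS = (5, 25, 50, 75, 95)


@dataclass
class LooResult:
    """Per-voxel leave-one-slice-out errors and summary statistics."""

    errors_deg: np.ndarray
    median_deg: float
    percentiles_deg: dict
    slice_index: int
    n_excluded: int  # flagged/degenerate voxels excluded from the stats


def _dataset_fiber_projections(dataset: SparseCdtiDataset):
    """Sign-fixed first eigenvectors and their frame projections for all samples."""
    coords, tensors, frames, _, _ = dataset.stacked()
    fibers, degen = principal_fiber(clamp_spd(tensors), frames.e_c, frames.e_l, frames.e_t)
    proj = np.column_stack([
        np.einsum("ij,ij->i", fibers, frames.e_t),
        np.einsum("ij,ij->i", fibers, frames.e_c),
        np.einsum("ij,ij->i", fibers, frames.e_l),
    ])
    return coords, fibers, proj, frames, degen


def interpolate_with_method(
    dataset: SparseCdtiDataset,
    method: str,
    target_coords: np.ndarray,
    target_frames: LocalFrame,
    config: dict | None = None,
) -> np.ndarray:
    """Fit one of the four methods on a sparse dataset and evaluate it.

    ``method``: "hfc", "pgd", "pod" or "rbm".  ``config`` carries the
    method's model/kernel: HFC needs ``{"kernel": HfcKernel}`` (or uses a
    moderate default), PGD/POD need ``{"model": <built basis>}``, RBM
    needs nothing.  A callable may be passed instead of a method name for
    oracle tests: it receives (dataset, target_coords, target_frames).
    """
    config = config or {}
    if callable(method):
        return method(dataset, target_coords, target_frames)
    coords, fibers, proj, frames, _ = _dataset_fiber_projections(dataset)
    if method == "hfc":
        kernel = config.get("kernel") or HfcKernel.diagonal(0.15, 0.08, 0.15)
        _, tensors, dframes, _, _ = dataset.stacked()
        _, fib = hfc_interpolate(coords, tensors, dframes, target_coords, target_frames, kernel)
        return fib
    if method == "pgd":
        model = pgd_fit(coords, proj, config["model"])
        return pgd_evaluate(model, target_coords, target_frames)
    if method == "pod":
        model = pod_fit_gappy(coords, proj, config["model"])
        return pod_evaluate(model, target_coords, target_frames)
    if method == "rbm":
        h = helix_angle(fibers, frames.e_t, frames.e_c, frames.e_l)
        tv = transverse_angle(fibers, frames.e_t, frames.e_c, frames.e_l)
        params = rbm_fit(coords[:, 0], h, tv)
        return rbm_evaluate(params, target_coords[:, 0], target_frames)
    raise ValueError(f"unknown method '{method}'")


def leave_one_slice_out(
    dataset: SparseCdtiDataset,
    method,
    config: dict | None = None,
    slice_index: int | None = None,
) -> LooResult:
    """Leave-one-slice-out interpolation error of a method.

    Excludes the mid-ventricular slice (or ``slice_index``), fits the
    method on the remaining slices, interpolates onto the excluded
    slice's coordinates, and reports per-voxel line-angle differences
    against the held-out first eigenvectors.  Voxels flagged as
    degenerate (near-equal leading eigenvalues) are excluded from the
    statistics; their count is reported.
    """
    if len(dataset.slices) < 2:
        raise ValueError("leave-one-slice-out needs at least 2 slices")
    idx = dataset.mid_ventricular_index() if slice_index is None else slice_index
    held = dataset.slices[idx]
    rest = dataset.without_slice(idx)
    tgt_frames = LocalFrame(held.frames_e_t, held.frames_e_c, held.frames_e_l)
    truth, degen = principal_fiber(
        clamp_spd(held.tensors), held.frames_e_c, held.frames_e_l, held.frames_e_t
    )
    try:
        fib = interpolate_with_method(rest, method, held.coords, tgt_frames, config)
    except Exception as exc:
        raise RuntimeError(
            f"method {method!r} failed on the reduced dataset (held-out slice {idx})"
        ) from exc
    errs = line_angle_diff(fib, truth)
    ok = ~degen & np.isfinite(errs)
    kept = errs[ok]
    return LooResult(
        errors_deg=kept,
        median_deg=float(np.median(kept)),
        percentiles_deg={p: float(np.percentile(kept, p)) for p in _PCTS},
        slice_index=idx,
        n_excluded=int((~ok).sum()),
    )


def mutual_difference(field_a: np.ndarray, field_b: np.ndarray) -> np.ndarray:
    """Pointwise line-angle differences between two fiber fields (deg).

    Symmetric in its arguments and invariant to per-point sign flips;
    both fields must live on the same point set.
    """
    a = np.asarray(field_a, dtype=float)
    b = np.asarray(field_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"fields live on different point sets: {a.shape} vs {b.shape}")
    return line_angle_diff(a, b)


def angle_summary(
    fibers: np.ndarray,
    frames: LocalFrame,
    bin_width_deg: float = 5.0,
) -> dict:
    """Helix/transverse histograms and percentile summaries.

    Percentiles use linear interpolation between order statistics.
    Histogram bins span [-90, 90] with the given width.  NaN angles
    (degenerate projections) are dropped and counted.
    """
    fibers = np.asarray(fibers, dtype=float)
    if fibers.size == 0:
        raise ValueError("empty fiber field")
    edges = np.arange(-90.0, 90.0 + bin_width_deg, bin_width_deg)
    out = {"bin_edges_deg": edges}
    for name, fn in (("helix", helix_angle), ("transverse", transverse_angle)):
        ang = fn(fibers, frames.e_t, frames.e_c, frames.e_l)
        ok = np.isfinite(ang)
        vals = ang[ok]
        out[name] = {
            "histogram": np.histogram(vals, bins=edges)[0],
            "median_deg": float(np.median(vals)),
            "percentiles_deg": {p: float(np.percentile(vals, p)) for p in _PCTS},
            "n_dropped": int((~ok).sum()),
        }
    return out
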