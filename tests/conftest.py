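"""Shared fixtures: small meshes, coordinates, frames, synthetic datasets.

All geometry is generated at module import time from code (no stored
fixtures); session scope keeps the expensive Laplace solves to one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from lvfiber.coordinates import compute_local_frames, compute_ventricular_coords
from lvfiber.mesh import TetMesh, _kuhn_split, make_box_mesh, make_lv_mesh, tet_volumes
from lvfiber.synthetic import (
    DEFAULT_ENDO_RADII,
    DEFAULT_EPI_RADII,
    DEFAULT_TRUNCATION,
    make_ground_truth_fibers,
    sample_short_axis_slices,
    tensors_from_fibers,
)


@pytest.fixture(scope="session")
def small_lv():
    """Coarse spherical-cap shell: fast, with an exact analytic volume."""
    return make_lv_mesh((20, 20, 20), (30, 30, 30), 5.0, 3.0)


@pytest.fixture(scope="session")
def study_lv():
    """Porcine-scale idealized LV accommodating a 9-slice 8 mm stack."""
    return make_lv_mesh(DEFAULT_ENDO_RADII, DEFAULT_EPI_RADII, DEFAULT_TRUNCATION, 3.5)


@pytest.fixture(scope="session")
def study_coords(study_lv):
    return compute_ventricular_coords(study_lv)


@pytest.fixture(scope="session")
def study_frames(study_lv, study_coords):
    return compute_local_frames(study_lv, study_coords)


@pytest.fixture(scope="session")
def study_dataset(study_lv, study_coords, study_frames):
    """Noise-free 9-slice sparse dataset from the smooth rule-based truth."""
    gt = make_ground_truth_fibers(study_coords, study_frames)
    D = tensors_from_fibers(gt.fibers, study_frames)
    return sample_short_axis_slices(
        study_lv, study_coords, study_frames, D, n_slices=9, in_plane_spacing=2.5,
        fibers=gt.fibers,
    )


def perturbed_dataset(study_lv, study_coords, study_frames, sigma, seed, n_slices=9,
                      spacing=2.5):
    gt = make_ground_truth_fibers(
        study_coords, study_frames, perturbation_sigma=sigma, seed=seed,
        nodes=study_lv.nodes,
    )
    D = tensors_from_fibers(gt.fibers, study_frames)
    return sample_short_axis_slices(
        study_lv, study_coords, study_frames, D, n_slices=n_slices, in_plane_spacing=spacing,
        fibers=gt.fibers,
    )


@pytest.fixture(scope="session")
def small_basis_acceptance():
    from lvfiber.interpolation import pgd_build_basis
    from lvfiber.synthetic import dense_grid_hearts

    fields, grids = dense_grid_hearts(4, grid_shape=(16, 30, 16), seed=0)
    return pgd_build_basis(fields, grids, n_pgd=3, n_svd=3)


@pytest.fixture(scope="session")
def box():
    return make_box_mesh((4, 4, 4))


def make_annulus_mesh(r1=1.0, r2=2.0, nr=6, ntheta=48, nz=6, height=1.0) -> TetMesh:
    """Structured tet mesh of a cylindrical annulus (periodic Kuhn split)."""
    rs = np.linspace(r1, r2, nr + 1)
    thetas = np.arange(ntheta) * 2 * np.pi / ntheta
    zs = np.linspace(0, height, nz + 1)

    def nid(i, j, k):
        return (i * ntheta + (j % ntheta)) * (nz + 1) + k

    nodes = np.empty(((nr + 1) * ntheta * (nz + 1), 3))
    for i, r in enumerate(rs):
        for j, th in enumerate(thetas):
            for k, z in enumerate(zs):
                nodes[nid(i, j, k)] = (r * np.cos(th), r * np.sin(th), z)
    tets = []
    for i in range(nr):
        for j in range(ntheta):
            for k in range(nz):
                corner = {
                    (a, b, c): nid(i + a, j + b, k + c)
                    for a in (0, 1) for b in (0, 1) for c in (0, 1)
                }
                tets.extend(_kuhn_split(corner))
    tets = np.asarray(tets, dtype=np.int64)
    vols = tet_volumes(nodes, tets)
    tets[vols < 0] = tets[vols < 0][:, [1, 0, 2, 3]]
    inner = np.nonzero(np.isclose(np.hypot(nodes[:, 0], nodes[:, 1]), r1))[0]
    return TetMesh(
        nodes=nodes, tets=tets,
        surface_labels={
            "endo": np.empty((0, 3), dtype=np.int64),
            "epi": np.empty((0, 3), dtype=np.int64),
            "base": np.empty((0, 3), dtype=np.int64),
        },
        apex_region=inner[:1],
    )


@pytest.fixture(scope="session")
def annulus():
    return make_annulus_mesh()
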