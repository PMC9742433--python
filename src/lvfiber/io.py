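"""File formats: ASCII VTU meshes/fields, CSV/JSON sparse datasets,
validated run configuration with provenance.

The VTU support is a deliberately small reader/writer for ASCII
unstructured grids containing tetrahedra and labeled triangles — enough
for lossless round trips of this package's meshes and nodal fields.
Sparse cDTI datasets are stored as a JSON header (slice geometry,
provenance) plus one CSV row per voxel sample:

    slice_id, x, y, z, t, c, l, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz,
    et_x, et_y, et_z, ec_x, ec_y, ec_z, el_x, el_y, el_z

(the frame columns extend the minimal schema so a dataset is
self-contained for frame-aware interpolation).
"""

from __future__ import annotations

import hashlib
import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coordinates import LocalFrame
from .mesh import TetMesh
from .synthetic import SliceSamples, SparseCdtiDataset

__all__ = [
    "write_mesh",
    "read_mesh",
    "write_dataset",
    "read_dataset",
    "load_config",
    "provenance_block",
]

_TET = 10
_TRI = 5
_LABEL_IDS = {"endo": 1, "epi": 2, "base": 3}


def _fmt(a: np.ndarray) -> str:
    return " ".join(repr(x) if isinstance(x, float) else str(x) for x in np.asarray(a).ravel().tolist())


def write_mesh(path, mesh: TetMesh, point_data: dict | None = None) -> None:
    """Write a labeled tet mesh (+ nodal arrays) as ASCII VTU.

    Labeled surface triangles are stored as extra cells with the integer
    cell array ``surface_label`` (0 = tet); the apex region as the point
    array ``apex_region`` (0/1).
    """
    path = Path(path)
    if path.suffix.lower() != ".vtu":
        raise ValueError(f"unknown format '{path.suffix}'; supported: .vtu")
    point_data = dict(point_data or {})
    point_data["apex_region"] = np.isin(np.arange(mesh.n_nodes), mesh.apex_region).astype(int)

    cells = [mesh.tets]
    labels = [np.zeros(mesh.n_tets, dtype=int)]
    types = [np.full(mesh.n_tets, _TET, dtype=int)]
    for name, lid in _LABEL_IDS.items():
        tris = np.asarray(mesh.surface_labels.get(name, np.empty((0, 3), dtype=int)))
        if len(tris):
            cells.append(tris)
            labels.append(np.full(len(tris), lid, dtype=int))
            types.append(np.full(len(tris), _TRI, dtype=int))
    conn = np.concatenate([c.ravel() for c in cells])
    sizes = np.concatenate([np.full(len(c), c.shape[1], dtype=int) for c in cells])
    offsets = np.cumsum(sizes)
    ctypes = np.concatenate(types)
    labarr = np.concatenate(labels)
    n_cells = len(ctypes)

    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{n_cells}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        _fmt(mesh.nodes),
        "</DataArray>",
        "</Points>",
        "<Cells>",
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        _fmt(conn),
        "</DataArray>",
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        _fmt(offsets),
        "</DataArray>",
        '<DataArray type="UInt8" Name="types" format="ascii">',
        _fmt(ctypes),
        "</DataArray>",
        "</Cells>",
        "<PointData>",
    ]
    for name, arr in point_data.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        dtype = "Int64" if np.issubdtype(arr.dtype, np.integer) else "Float64"
        lines += [
            f'<DataArray type="{dtype}" Name="{name}" NumberOfComponents="{ncomp}" format="ascii">',
            _fmt(arr),
            "</DataArray>",
        ]
    lines += [
        "</PointData>",
        "<CellData>",
        '<DataArray type="Int64" Name="surface_label" NumberOfComponents="1" format="ascii">',
        _fmt(labarr),
        "</DataArray>",
        "</CellData>",
        "</Piece>",
        "</UnstructuredGrid>",
        "</VTKFile>",
    ]
    path.write_text("\n".join(lines))


def read_mesh(path):
    """Read an ASCII VTU written by :func:`write_mesh`.

    Returns ``(mesh, point_data)``; validates that all three surface
    labels are present.
    """
    path = Path(path)
    if path.suffix.lower() != ".vtu":
        raise ValueError(f"unknown format '{path.suffix}'; supported: .vtu")
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    nodes = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.findall("Cells/DataArray")}
    conn = np.fromstring(arrays["connectivity"].text, sep=" ", dtype=np.int64)
    offsets = np.fromstring(arrays["offsets"].text, sep=" ", dtype=np.int64)
    ctypes = np.fromstring(arrays["types"].text, sep=" ", dtype=np.int64)
    lab_da = piece.find("CellData/DataArray[@Name='surface_label']")
    labels_arr = (
        np.fromstring(lab_da.text, sep=" ", dtype=np.int64)
        if lab_da is not None
        else np.zeros(len(ctypes), dtype=np.int64)
    )
    starts = np.concatenate([[0], offsets[:-1]])
    tets, tris = [], {name: [] for name in _LABEL_IDS}
    rev = {v: k for k, v in _LABEL_IDS.items()}
    for s, e, ct, lb in zip(starts, offsets, ctypes, labels_arr):
        if ct == _TET:
            tets.append(conn[s:e])
        elif ct == _TRI and lb in rev:
            tris[rev[lb]].append(conn[s:e])
    point_data = {}
    for da in piece.findall("PointData/DataArray"):
        arr = np.fromstring(da.text, sep=" ")
        ncomp = int(da.get("NumberOfComponents", "1"))
        if ncomp > 1:
            arr = arr.reshape(-1, ncomp)
        if da.get("type") == "Int64":
            arr = arr.astype(np.int64)
        point_data[da.get("Name")] = arr
    apex = (
        np.nonzero(point_data.pop("apex_region"))[0]
        if "apex_region" in point_data
        else np.array([], dtype=np.int64)
    )
    surface_labels = {k: np.asarray(v, dtype=np.int64).reshape(-1, 3) for k, v in tris.items()}
    for name in _LABEL_IDS:
        if len(surface_labels[name]) == 0:
            raise ValueError(f"mesh file is missing surface label '{name}'")
    mesh = TetMesh(
        nodes=nodes,
        tets=np.asarray(tets, dtype=np.int64),
        surface_labels=surface_labels,
        apex_region=apex,
    )
    return mesh, point_data


# ---------------------------------------------------------------------------
# sparse dataset CSV/JSON
# ---------------------------------------------------------------------------

_D_COLS = ["Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz"]
_D_IJ = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
_F_COLS = [f"{v}_{a}" for v in ("et", "ec", "el") for a in "xyz"]


def write_dataset(prefix, dataset: SparseCdtiDataset, provenance: dict | None = None) -> None:
    """Write a sparse dataset as ``<prefix>.json`` + ``<prefix>.csv``."""
    prefix = Path(prefix)
    rows = []
    meta = {"slices": [], "n_samples": dataset.n_samples, "provenance": provenance or {}}
    for sid, sl in enumerate(dataset.slices):
        meta["slices"].append({
            "slice_id": sid, "slice_position_mm": sl.slice_position, "thickness_mm": sl.thickness,
            "n_voxels": len(sl.positions),
        })
        for v in range(len(sl.positions)):
            row = {"slice_id": sid}
            row.update(dict(zip("xyz", sl.positions[v])))
            row.update(dict(zip("tcl", sl.coords[v])))
            for col, (i, j) in zip(_D_COLS, _D_IJ):
                row[col] = sl.tensors[v, i, j]
            for col, val in zip(_F_COLS, np.concatenate([sl.frames_e_t[v], sl.frames_e_c[v], sl.frames_e_l[v]])):
                row[col] = val
            rows.append(row)
    pd.DataFrame(rows).to_csv(prefix.with_suffix(".csv"), index=False)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_dataset(prefix) -> SparseCdtiDataset:
    """Read a sparse dataset written by :func:`write_dataset`."""
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".csv"))
    slices = []
    for s in meta["slices"]:
        sub = df[df["slice_id"] == s["slice_id"]]
        D = np.zeros((len(sub), 3, 3))
        for col, (i, j) in zip(_D_COLS, _D_IJ):
            D[:, i, j] = D[:, j, i] = sub[col].to_numpy()
        slices.append(SliceSamples(
            slice_position=s["slice_position_mm"],
            thickness=s["thickness_mm"],
            positions=sub[["x", "y", "z"]].to_numpy(),
            coords=sub[["t", "c", "l"]].to_numpy(),
            tensors=D,
            frames_e_t=sub[[f"et_{a}" for a in "xyz"]].to_numpy(),
            frames_e_c=sub[[f"ec_{a}" for a in "xyz"]].to_numpy(),
            frames_e_l=sub[[f"el_{a}" for a in "xyz"]].to_numpy(),
        ))
    return SparseCdtiDataset(slices=slices)


def write_nifti_tensor_volume(path, dataset: SparseCdtiDataset, spacing: float = 2.0) -> None:
    """Optional 4-D NIfTI export of a sparse dataset (requires nibabel).

    Voxels are binned onto a regular grid at ``spacing`` mm; the 4th axis
    carries the six unique tensor components in the order
    Dxx, Dxy, Dxz, Dyy, Dyz, Dzz (mm^2/s); unobserved voxels are NaN.
    """
    import nibabel as nib

    pos = np.vstack([s.positions for s in dataset.slices])
    D = np.vstack([s.tensors for s in dataset.slices])
    origin = pos.min(axis=0)
    idx = np.round((pos - origin) / spacing).astype(int)
    shape = idx.max(axis=0) + 1
    vol = np.full((*shape, 6), np.nan)
    for n, (i, j) in enumerate(_D_IJ):
        vol[idx[:, 0], idx[:, 1], idx[:, 2], n] = D[:, i, j]
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = origin
    nib.save(nib.Nifti1Image(vol, affine), str(path))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SCHEMA = {
    "geometry": {
        "endo_radii": list, "epi_radii": list, "truncation_height": (int, float),
        "edge_length": (int, float), "apex_diameter": (int, float),
    },
    "microstructure": {
        "helix_endo": (int, float), "helix_epi": (int, float),
        "transverse_endo": (int, float), "transverse_epi": (int, float),
        "perturbation_sigma": (int, float), "correlation_length": (int, float),
        "eigenvalues": list,
    },
    "acquisition": {
        "bvals": list, "bvecs": list, "snr": (int, float), "n_averages": int,
        "noise_model": str, "s0": (int, float),
    },
    "sampling": {
        "n_slices": int, "thickness": (int, float), "in_plane_spacing": (int, float),
        "gap": (int, float), "thickness_average": bool,
    },
    "method": {
        "name": str, "h_t": (int, float), "h_c": (int, float), "h_l": (int, float),
        "n_pgd": int, "n_svd": int, "n_pod": int, "n_hearts": int,
    },
    "seed": int,
}

DEFAULTS = {
    "geometry": {
        "endo_radii": [25.0, 25.0, 60.0],
        "epi_radii": [33.0, 33.0, 68.0],
        "truncation_height": 15.0,
        "edge_length": 3.0,
        "apex_diameter": 2.0,
    },
    "microstructure": {
        "helix_endo": 60.0, "helix_epi": -60.0,
        "transverse_endo": 0.0, "transverse_epi": 0.0,
        "perturbation_sigma": 0.0, "correlation_length": 5.0,
        "eigenvalues": [1.5e-3, 0.8e-3, 0.5e-3],
    },
    "acquisition": {
        "bvals": [100.0] * 3 + [200.0] * 3 + [450.0] * 12,
        "bvecs": None,  # generated from the seed when absent
        "snr": 20.0, "n_averages": 8, "noise_model": "rician", "s0": 1000.0,
    },
    "sampling": {
        "n_slices": 9, "thickness": 8.0, "in_plane_spacing": 2.0, "gap": 0.0,
        "thickness_average": False,
    },
    "method": {
        "name": "hfc", "h_t": 0.15, "h_c": 0.08, "h_l": 0.15,
        "n_pgd": 6, "n_svd": 6, "n_pod": 8, "n_hearts": 8,
    },
    "seed": 0,
}


def load_config(path_or_dict) -> dict:
    """Load and validate a JSON/YAML run configuration.

    Unknown keys and type mismatches raise with the offending key path;
    missing keys are filled from the defaults.
    """
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    for section, val in raw.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown configuration key '{section}'")
        if section == "seed":
            if not isinstance(val, int) or isinstance(val, bool):
                raise ValueError("'seed' must be an integer")
            cfg["seed"] = val
            continue
        if not isinstance(val, dict):
            raise ValueError(f"'{section}' must be a mapping")
        for key, v in val.items():
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown configuration key '{section}.{key}'")
            expected = _SCHEMA[section][key]
            if v is not None and not isinstance(v, expected):
                raise ValueError(
                    f"'{section}.{key}' has type {type(v).__name__}, expected {expected}"
                )
            cfg[section][key] = v
    acq = cfg["acquisition"]
    if acq.get("bvecs") is not None and len(acq["bvecs"]) != len(acq["bvals"]):
        raise ValueError(
            f"'acquisition.bvecs' length {len(acq['bvecs'])} does not match bvals length {len(acq['bvals'])}"
        )
    return cfg


def provenance_block(config: dict, seed: int) -> dict:
    """Reproducibility record embedded in every output."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "lvfiber_version": __version__,
        "config": config,
    }
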