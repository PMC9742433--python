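"""Labeled tetrahedral left-ventricular meshes.

The idealized geometry is a truncated prolate ellipsoidal shell: the
myocardium lies between an endocardial and an epicardial ellipsoid sharing
a common long axis (z), truncated by a flat basal plane at z = h.  The
analytic volume of this shape makes it a convenient oracle for the
discrete volume computations used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TetMesh",
    "make_lv_mesh",
    "cavity_volume",
    "tet_volumes",
    "truncated_shell_volume",
]


@dataclass
class TetMesh:
    """Tetrahedral mesh with labeled boundary surfaces.

    Attributes
    ----------
    nodes : (N, 3) float array
        Node positions in mm.
    tets : (M, 4) int array
        Tetrahedra as node-index 4-tuples, positively oriented.
    surface_labels : dict
        Named triangle sets ``{"endo", "epi", "base"}``; each an (K, 3)
        int array of node indices.
    apex_region : (J,) int array
        Nodes inside the transmural apex cylinder (2 mm diameter by
        default) used as a Dirichlet/insulation region for the
        ventricular-coordinate problems.
    """

    nodes: np.ndarray
    tets: np.ndarray
    surface_labels: dict[str, np.ndarray]
    apex_region: np.ndarray
    _centroid_tree: cKDTree | None = field(default=None, repr=False, compare=False)
    _v0: np.ndarray | None = field(default=None, repr=False, compare=False)
    _tinv: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.apex_region = np.asarray(self.apex_region, dtype=np.int64)

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on failure."""
        if self.apex_region.size == 0:
            raise ValueError("apex_region is empty")
        vols = tet_volumes(self.nodes, self.tets)
        if np.any(vols <= 0):
            raise ValueError(f"{np.sum(vols <= 0)} tetrahedra have non-positive volume")
        seen: set[int] = set()
        for name in ("endo", "epi", "base"):
            if name not in self.surface_labels:
                raise ValueError(f"missing surface label '{name}'")
            tris = np.asarray(self.surface_labels[name])
            if tris.size and (tris.min() < 0 or tris.max() >= self.n_nodes):
                raise ValueError(f"surface '{name}' references invalid nodes")
            keys = {tuple(sorted(t)) for t in tris}
            if keys & seen:
                raise ValueError(f"surface '{name}' overlaps another labeled surface")
            seen |= keys

    def myocardial_volume(self) -> float:
        """Total mesh volume in mm^3."""
        return float(tet_volumes(self.nodes, self.tets).sum())

    def mean_edge_length(self) -> float:
        e = self.nodes[self.tets[:, [0, 0, 0, 1, 1, 2]]] - self.nodes[self.tets[:, [1, 2, 3, 2, 3, 3]]]
        return float(np.linalg.norm(e, axis=2).mean())

    def surface_nodes(self, name: str) -> np.ndarray:
        """Sorted unique node ids of a labeled surface."""
        return np.unique(np.asarray(self.surface_labels[name]).ravel())

    # -- point location ------------------------------------------------

    def locate(self, points: np.ndarray, k: int = 40, tol: float = 1e-9):
        """Find containing tets and barycentric coordinates.

        Returns ``(tet_idx, bary)`` with ``tet_idx = -1`` for points
        outside the mesh.  Uses a centroid KD-tree with a barycentric
        check over the nearest candidates.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._centroid_tree is None:
            centroids = self.nodes[self.tets].mean(axis=1)
            object.__setattr__(self, "_centroid_tree", cKDTree(centroids))
        k = min(k, self.n_tets)
        _, cand = self._centroid_tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        n = len(points)
        best_t = np.full(n, -1, dtype=np.int64)
        best_b = np.zeros((n, 4))
        best_min = np.full(n, -np.inf)
        unresolved = np.ones(n, dtype=bool)
        if getattr(self, "_tinv", None) is None:
            v0 = self.nodes[self.tets[:, 0]]
            T = np.stack(
                [self.nodes[self.tets[:, a]] - v0 for a in (1, 2, 3)], axis=2
            )
            object.__setattr__(self, "_v0", v0)
            object.__setattr__(self, "_tinv", np.linalg.inv(T))
        v0, Tinv = self._v0, self._tinv
        for r in range(cand.shape[1]):
            idx = np.nonzero(unresolved)[0]
            if idx.size == 0:
                break
            t_r = cand[idx, r]
            lam = np.einsum("nij,nj->ni", Tinv[t_r], points[idx] - v0[t_r])
            b = np.concatenate([(1.0 - lam.sum(axis=1))[:, None], lam], axis=1)
            m = b.min(axis=1)
            better = m > best_min[idx]
            upd = idx[better]
            best_min[upd] = m[better]
            best_t[upd] = t_r[better]
            best_b[upd] = b[better]
            unresolved[idx[m >= -tol]] = False
        ok = best_min >= -1e-6  # accept slight boundary overshoot
        tet_idx = np.where(ok, best_t, -1)
        bary = np.clip(best_b, 0.0, None)
        ssum = bary.sum(axis=1, keepdims=True)
        bary = np.where(ok[:, None], bary / np.where(ssum == 0, 1.0, ssum), 0.0)
        return tet_idx, bary

    def _barycentric(self, t: int, p: np.ndarray) -> np.ndarray:
        v = self.nodes[self.tets[t]]
        T = (v[1:] - v[0]).T
        try:
            lam = np.linalg.solve(T, p - v[0])
        except np.linalg.LinAlgError:
            return np.full(4, -np.inf)
        return np.concatenate([[1.0 - lam.sum()], lam])

    def interpolate(self, nodal_field: np.ndarray, points: np.ndarray):
        """Barycentric interpolation of a nodal field at physical points.

        Points outside the mesh get NaN.  Returns ``(values, inside_mask)``.
        """
        tet_idx, bary = self.locate(points)
        inside = tet_idx >= 0
        f = np.asarray(nodal_field, dtype=float)
        out_shape = (len(np.atleast_2d(points)),) + f.shape[1:]
        vals = np.full(out_shape, np.nan)
        if inside.any():
            conn = self.tets[tet_idx[inside]]
            w = bary[inside]
            vals[inside] = np.einsum("ij,ij...->i...", w, f[conn])
        return vals, inside


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for right-handed ordering)."""
    v = nodes[tets]
    return np.einsum(
        "ij,ij->i", v[:, 1] - v[:, 0], np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0])
    ) / 6.0


def _ellipsoid_cap_volume(a: float, b: float, c: float, h: float) -> float:
    """Volume of the ellipsoid region z < h, semi-axes (a, b, c), |h| <= c."""
    return np.pi * a * b * (h - h**3 / (3 * c**2) + 2 * c / 3)


def truncated_shell_volume(endo_radii, epi_radii, truncation_height: float) -> float:
    """Analytic myocardial volume (mm^3) of the truncated ellipsoidal shell."""
    ae, be, ce = endo_radii
    aE, bE, cE = epi_radii
    h = truncation_height
    return _ellipsoid_cap_volume(aE, bE, cE, h) - _ellipsoid_cap_volume(ae, be, ce, h)


_KUHN_PERMS = list(permutations(range(3)))


def _kuhn_split(corner) -> list[tuple[int, int, int, int]]:
    """Kuhn 6-tet subdivision of a hexahedron.

    ``corner[(x, y, z)]`` maps local binary coordinates to node ids.  The
    split is conforming across neighboring cells (face diagonals always run
    from the face's local-minimum to local-maximum corner), including across
    a periodic wrap.  Degenerate tets (repeated nodes, from collapsed apex
    cells) are dropped.
    """
    tets = []
    for perm in _KUHN_PERMS:
        path = [(0, 0, 0)]
        cur = [0, 0, 0]
        for ax in perm:
            cur[ax] = 1
            path.append(tuple(cur))
        ids = [corner[p] for p in (path[0], path[1], path[2], path[3])]
        if len(set(ids)) == 4:
            tets.append(tuple(ids))
    return tets


def make_lv_mesh(
    endo_radii,
    epi_radii,
    truncation_height: float,
    edge_length: float,
    seed: int = 0,
    apex_diameter: float = 2.0,
) -> TetMesh:
    """Build an idealized truncated-ellipsoid LV shell mesh.

    Parameters
    ----------
    endo_radii, epi_radii : 3-tuples (mm)
        Semi-axes (a, b, c) of the endo- and epicardial ellipsoids; the
        long axis is z, the apex sits at z = -c and the basal plane at
        z = ``truncation_height``.
    truncation_height : float (mm)
        Height of the flat basal plane above the ellipsoid center;
        must satisfy ``truncation_height < min(c_endo, c_epi)``.
    edge_length : float (mm)
        Target edge length controlling the resolution.
    seed : int
        Kept for interface uniformity; the mesh itself is deterministic.
    apex_diameter : float (mm)
        Diameter of the transmural apex cylinder stored as ``apex_region``.
    """
    endo_radii = np.asarray(endo_radii, dtype=float)
    epi_radii = np.asarray(epi_radii, dtype=float)
    if endo_radii.shape != (3,) or epi_radii.shape != (3,):
        raise ValueError("endo_radii and epi_radii must be 3-vectors (a, b, c)")
    if np.any(endo_radii <= 0):
        raise ValueError(f"endo_radii must be positive, got {tuple(endo_radii)}")
    if np.any(epi_radii <= endo_radii):
        bad = ["abc"[i] for i in np.nonzero(epi_radii <= endo_radii)[0]]
        raise ValueError(f"epi_radii must exceed endo_radii component-wise (offending axis: {','.join(bad)})")
    if edge_length <= 0:
        raise ValueError(f"edge_length must be positive, got {edge_length}")
    h = float(truncation_height)
    if h >= endo_radii[2]:
        raise ValueError(
            f"truncation_height={h} must lie below the endocardial pole c_endo={endo_radii[2]}"
        )
    if h <= -endo_radii[2]:
        raise ValueError("truncation_height lies below the apex; shell is empty")

    wall = float(np.mean(epi_radii - endo_radii))
    n_t = max(2, int(round(wall / edge_length)))
    # mid-wall meridian arc (numeric) and equatorial circumference set the
    # longitudinal / circumferential resolution
    mid = 0.5 * (endo_radii + epi_radii)
    phi_base_mid = np.arccos(np.clip(h / mid[2], -1, 1))
    phi_s = np.linspace(phi_base_mid, np.pi, 200)
    arc = np.sum(
        np.hypot(
            np.diff(mid[0] * np.sin(phi_s)), np.diff(mid[2] * np.cos(phi_s))
        )
    )
    n_phi = max(3, int(round(arc / edge_length)))
    circ = 2 * np.pi * 0.5 * (mid[0] + mid[1])
    n_theta = max(8, int(round(circ / edge_length)))
    n_theta += n_theta % 2  # even so the split plane hits nodes at theta = 0, pi

    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)

    n_ring_nodes = (n_t + 1) * n_phi * n_theta
    nodes = np.empty((n_ring_nodes + n_t + 1, 3))

    def nid(i: int, j: int, k: int) -> int:
        return i * n_phi * n_theta + j * n_theta + (k % n_theta)

    def apex_id(i: int) -> int:
        return n_ring_nodes + i

    for i in range(n_t + 1):
        u = i / n_t
        a, b, c = endo_radii + u * (epi_radii - endo_radii)
        phi_base = np.arccos(np.clip(h / c, -1, 1))
        phis = np.linspace(phi_base, np.pi, n_phi + 1)[:-1]
        for j, phi in enumerate(phis):
            sp, cp = np.sin(phi), np.cos(phi)
            for k, th in enumerate(thetas):
                nodes[nid(i, j, k)] = (a * sp * np.cos(th), b * sp * np.sin(th), c * cp)
        nodes[apex_id(i)] = (0.0, 0.0, -c)

    tets: list[tuple[int, int, int, int]] = []
    for i in range(n_t):
        for j in range(n_phi - 1):
            for k in range(n_theta):
                corner = {
                    (x, y, z): nid(i + x, j + y, k + z)
                    for x in (0, 1)
                    for y in (0, 1)
                    for z in (0, 1)
                }
                tets.extend(_kuhn_split(corner))
        # apex wedge layer: ring j = n_phi - 1 collapsed to the axis nodes
        j = n_phi - 1
        for k in range(n_theta):
            corner = {}
            for x in (0, 1):
                for z in (0, 1):
                    corner[(x, 0, z)] = nid(i + x, j, k + z)
                    corner[(x, 1, z)] = apex_id(i + x)
            tets.extend(_kuhn_split(corner))

    tets_arr = np.asarray(tets, dtype=np.int64)
    vols = tet_volumes(nodes, tets_arr)
    flip = vols < 0
    tets_arr[flip] = tets_arr[flip][:, [1, 0, 2, 3]]
    keep = np.abs(vols) > 1e-12
    tets_arr = tets_arr[keep]

    # boundary triangles -> labels by node membership
    faces: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    counts: dict[tuple[int, int, int], int] = {}
    local_faces = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]  # outward for +vol
    for tet in tets_arr:
        for lf in local_faces:
            tri = (int(tet[lf[0]]), int(tet[lf[1]]), int(tet[lf[2]]))
            key = tuple(sorted(tri))
            counts[key] = counts.get(key, 0) + 1
            faces[key] = tri
    boundary = [faces[k] for k, c in counts.items() if c == 1]

    endo_set = set(range(0, n_phi * n_theta)) | {apex_id(0)}
    epi_set = set(range(n_t * n_phi * n_theta, (n_t + 1) * n_phi * n_theta)) | {apex_id(n_t)}
    base_set = {nid(i, 0, k) for i in range(n_t + 1) for k in range(n_theta)}
    endo_tris, epi_tris, base_tris = [], [], []
    for tri in boundary:
        s = set(tri)
        if s <= endo_set:
            endo_tris.append(tri)
        elif s <= epi_set:
            epi_tris.append(tri)
        elif s <= base_set:
            base_tris.append(tri)
    labels = {
        "endo": np.asarray(endo_tris, dtype=np.int64),
        "epi": np.asarray(epi_tris, dtype=np.int64),
        "base": np.asarray(base_tris, dtype=np.int64),
    }

    r_xy = np.hypot(nodes[:, 0], nodes[:, 1])
    apex_region = np.nonzero(r_xy <= apex_diameter / 2.0 + 1e-9)[0]

    mesh = TetMesh(nodes=nodes, tets=tets_arr, surface_labels=labels, apex_region=apex_region)
    mesh.validate()
    return mesh


def make_box_mesh(shape=(4, 4, 4), lengths=(1.0, 1.0, 1.0)) -> TetMesh:
    """Structured tet mesh of a box (Kuhn split); handy as a test domain.

    Surfaces are labeled ``endo`` (x = 0), ``epi`` (x = Lx) and ``base``
    (z = Lz) so the mesh can stand in for a trivial 'ventricle'.
    """
    nx, ny, nz = shape
    Lx, Ly, Lz = lengths
    xs = np.linspace(0, Lx, nx + 1)
    ys = np.linspace(0, Ly, ny + 1)
    zs = np.linspace(0, Lz, nz + 1)
    nid = lambda i, j, k: (i * (ny + 1) + j) * (nz + 1) + k
    nodes = np.array([[x, y, z] for x in xs for y in ys for z in zs])
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = {
                    (a, b, c): nid(i + a, j + b, k + c)
                    for a in (0, 1) for b in (0, 1) for c in (0, 1)
                }
                tets.extend(_kuhn_split(corner))
    tets = np.asarray(tets, dtype=np.int64)
    vols = tet_volumes(nodes, tets)
    tets[vols < 0] = tets[vols < 0][:, [1, 0, 2, 3]]

    def face_tris(mask):
        idx = np.nonzero(mask)[0]
        sel = np.isin(tets, idx).sum(axis=1) >= 3
        tris = []
        for tet in tets[sel]:
            on = [v for v in tet if mask[v]]
            if len(on) == 3:
                tris.append(on)
        return np.asarray(tris, dtype=np.int64)

    labels = {
        "endo": face_tris(nodes[:, 0] < 1e-12),
        "epi": face_tris(nodes[:, 0] > Lx - 1e-12),
        "base": face_tris(nodes[:, 2] > Lz - 1e-12),
    }
    apex = np.nonzero((nodes[:, 2] < 1e-12))[0]
    return TetMesh(nodes=nodes, tets=tets, surface_labels=labels, apex_region=apex)


def cavity_volume(endo_nodes: np.ndarray, endo_tris: np.ndarray, basal_center) -> float:
    """Cavity volume (ml) by tetrahedral partition of the endocardial surface.

    Every surface triangle is connected to ``basal_center`` (a point on
    the basal plane); the signed tetra volumes are summed.  The surface
    must be closed against the basal plane: any boundary edge of the
    triangle set has to lie in the plane through ``basal_center`` fitted
    to the boundary nodes.
    """
    endo_nodes = np.asarray(endo_nodes, dtype=float)
    endo_tris = np.asarray(endo_tris, dtype=np.int64)
    center = np.asarray(basal_center, dtype=float)
    if endo_tris.ndim != 2 or endo_tris.shape[1] != 3:
        raise ValueError("endo_tris must be an (K, 3) triangle array")

    edge_count: dict[tuple[int, int], int] = {}
    for tri in endo_tris:
        for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (int(min(e)), int(max(e)))
            edge_count[key] = edge_count.get(key, 0) + 1
    open_edges = [e for e, c in edge_count.items() if c == 1]
    if open_edges:
        ring = np.unique(np.asarray(open_edges).ravel())
        pts = endo_nodes[ring] - center
        # plane through basal_center: smallest singular direction
        _, sv, vt = np.linalg.svd(pts, full_matrices=False)
        normal = vt[-1]
        dist = np.abs(pts @ normal)
        scale = max(1.0, np.abs(pts).max())
        bad = [
            e for e in open_edges
            if max(abs((endo_nodes[e[0]] - center) @ normal), abs((endo_nodes[e[1]] - center) @ normal))
            > 1e-6 * scale
        ]
        if bad:
            raise ValueError(
                f"endocardial surface is open off the basal plane; offending edges: {bad[:10]}"
                + ("..." if len(bad) > 10 else "")
            )
    v = endo_nodes[endo_tris]
    signed = np.einsum(
        "ij,ij->i",
        v[:, 0] - center,
        np.cross(v[:, 1] - center, v[:, 2] - center),
    ) / 6.0
    return abs(float(signed.sum())) / 1000.0  # mm^3 -> ml
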