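"""Shape-adapted ventricular coordinates and local frames.

Four Laplace (steady heat-transfer) problems with Dirichlet boundaries on
the labeled surfaces of a ventricular tet mesh yield:

* a transmural coordinate t (endo: t = 0, epi: t = 1),
* a longitudinal coordinate l (base: l = 1, apex cylinder: l = 0),
* a circumferential coordinate c assembled from two half-domain problems
  split at the anterior plane, with the transmural apex cylinder treated
  as insulation and filled with the local cylindrical angle.

Nodal gradients of the three fields, re-orthogonalized, give the local
orthonormal frame (e_t, e_c, e_l).  An optional streamline normalization
replaces a Laplace field by normalized arc length along the streamlines
of its gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .mesh import TetMesh, tet_volumes

__all__ = [
    "VentricularCoordinates",
    "LocalFrame",
    "solve_laplace",
    "compute_ventricular_coords",
    "compute_local_frames",
    "streamline_normalize",
    "element_gradients",
    "nodal_gradient",
]

logger = logging.getLogger(__name__)


@dataclass
class VentricularCoordinates:
    """Per-node (t, c, l): transmural in [0, 1], circumferential in [0, 1)
    (periodic, seam at the anterior split plane), longitudinal in [0, 1]."""

    t: np.ndarray
    c: np.ndarray
    l: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.t, self.c, self.l])


@dataclass
class LocalFrame:
    """Per-node orthonormal triads; e_c = e_l x e_t (right-handed)."""

    e_t: np.ndarray
    e_c: np.ndarray
    e_l: np.ndarray


# ---------------------------------------------------------------------------
# linear tet FEM
# ---------------------------------------------------------------------------

def _element_shape_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Gradients of the four linear shape functions per tet: (M, 4, 3)."""
    v = nodes[tets]
    T = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]], axis=2)
    Tinv = np.linalg.inv(T)  # rows: grad of lambda_1..3
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = Tinv  # row j = grad of barycentric coord j+1
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    return g


def assemble_stiffness(mesh: TetMesh) -> sp.csr_matrix:
    """Assemble the P1 Laplace stiffness matrix on a tet mesh (or sub-mesh)."""
    return _assemble(mesh.nodes, mesh.tets)


def _assemble(nodes: np.ndarray, tets: np.ndarray) -> sp.csr_matrix:
    vols = np.abs(tet_volumes(nodes, tets))
    g = _element_shape_gradients(nodes, tets)
    # K_e[a, b] = vol * grad_a . grad_b
    Ke = np.einsum("eai,ebi->eab", g, g) * vols[:, None, None]
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(len(nodes), len(nodes)))
    return K.tocsr()


def _solve_dirichlet(K: sp.csr_matrix, dirichlet: dict[int, float], n: int) -> np.ndarray:
    fixed = np.fromiter(dirichlet.keys(), dtype=np.int64)
    vals = np.fromiter((dirichlet[int(i)] for i in fixed), dtype=float)
    free = np.setdiff1d(np.arange(n), fixed)
    u = np.zeros(n)
    u[fixed] = vals
    if free.size:
        rhs = -K[free][:, fixed] @ vals
        u[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
    return u


def solve_laplace(mesh: TetMesh, dirichlet_sets: dict) -> np.ndarray:
    """Solve the Laplace equation with Dirichlet boundary node sets.

    ``dirichlet_sets`` maps a value to a node-id array (``{value: nodes}``)
    or a named tuple of ``(nodes, value)`` pairs; here we accept a
    dict ``{value: node_array}``.
    """
    items = [(float(v), np.asarray(ns, dtype=np.int64)) for v, ns in dirichlet_sets.items()]
    all_nodes = np.concatenate([ns for _, ns in items]) if items else np.array([], dtype=np.int64)
    if all_nodes.size == 0:
        raise ValueError("no Dirichlet nodes given; Laplace system is singular")
    if len({float(v) for v, _ in items}) < 2:
        # constant field is still well posed, return it directly
        return np.full(mesh.n_nodes, items[0][0])
    dirichlet: dict[int, float] = {}
    for v, ns in items:
        for i in ns:
            dirichlet[int(i)] = v
    K = assemble_stiffness(mesh)
    return _solve_dirichlet(K, dirichlet, mesh.n_nodes)


# ---------------------------------------------------------------------------
# ventricular coordinates
# ---------------------------------------------------------------------------

def _long_axis(mesh: TetMesh):
    """Unit long-axis direction (apex -> base) and a point on it (apex)."""
    base_nodes = mesh.surface_nodes("base")
    base_center = mesh.nodes[base_nodes].mean(axis=0)
    apex_center = mesh.nodes[mesh.apex_region].mean(axis=0)
    axis = base_center - apex_center
    return axis / np.linalg.norm(axis), apex_center, base_center


def compute_ventricular_coords(
    mesh: TetMesh,
    seam_tol: float | None = None,
) -> VentricularCoordinates:
    """Compute (t, c, l) from the four Laplace problems.

    t: endo = 0 / epi = 1.  l: base = 1 / apex cylinder = 0.  c: two
    half-domain problems split at the anterior plane (c = 0 seam) and the
    posterior plane (c = 0.5), stitched into one periodic coordinate; the
    apex cylinder is excluded from the half problems (zero-flux) and
    filled with the cylindrical angle about the long axis.
    """
    for name in ("endo", "epi", "base"):
        if name not in mesh.surface_labels:
            raise ValueError(f"mesh is missing required surface label '{name}'")
    if mesh.apex_region.size == 0:
        raise ValueError("mesh has an empty apex_region")

    n = mesh.n_nodes
    K = assemble_stiffness(mesh)
    endo = mesh.surface_nodes("endo")
    epi = mesh.surface_nodes("epi")
    base = mesh.surface_nodes("base")
    apex = mesh.apex_region

    t = _solve_dirichlet(K, {**{int(i): 0.0 for i in endo}, **{int(i): 1.0 for i in epi}}, n)
    l = _solve_dirichlet(K, {**{int(i): 1.0 for i in base}, **{int(i): 0.0 for i in apex}}, n)

    axis, apex_pt, base_pt = _long_axis(mesh)
    rel = mesh.nodes - apex_pt
    ax_comp = rel @ axis
    radial = rel - np.outer(ax_comp, axis)
    # in-plane basis: x-like direction = anterior (theta = 0)
    ref = np.array([1.0, 0.0, 0.0])
    ref = ref - (ref @ axis) * axis
    if np.linalg.norm(ref) < 1e-8:
        ref = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ axis) * axis
    ref /= np.linalg.norm(ref)
    ref2 = np.cross(axis, ref)
    theta = np.arctan2(radial @ ref2, radial @ ref)  # (-pi, pi]

    if seam_tol is None:
        seam_tol = 0.25 * mesh.mean_edge_length()
    r_inplane = np.linalg.norm(radial, axis=1)
    apex_set = set(int(i) for i in apex)
    on_anterior = (np.abs(radial @ ref2) <= seam_tol) & (radial @ ref > 0)
    on_posterior = (np.abs(radial @ ref2) <= seam_tol) & (radial @ ref < 0)

    c = np.full(n, np.nan)
    # two half domains split by the plane through the long axis and 'ref'
    side = radial @ ref2
    for half, sgn in ((0, 1.0), (1, -1.0)):
        tet_side = side[mesh.tets].mean(axis=1) * sgn
        keep_tets = mesh.tets[tet_side > 0]
        # insulate the apex cylinder: drop tets fully inside it
        inside = np.isin(keep_tets, apex).all(axis=1)
        keep_tets = keep_tets[~inside]
        sub_nodes = np.unique(keep_tets)
        remap = -np.ones(n, dtype=np.int64)
        remap[sub_nodes] = np.arange(len(sub_nodes))
        Ksub = _assemble(mesh.nodes[sub_nodes], remap[keep_tets])
        dir_sub: dict[int, float] = {}
        for i in sub_nodes:
            if on_anterior[i] and int(i) not in apex_set:
                dir_sub[int(remap[i])] = 0.0
            elif on_posterior[i] and int(i) not in apex_set:
                dir_sub[int(remap[i])] = 0.5
        if len(dir_sub) < 2:
            raise ValueError("could not find anterior/posterior seam nodes for the circumferential problem")
        u = _solve_dirichlet(Ksub, dir_sub, len(sub_nodes))
        vals = u if sgn > 0 else (1.0 - u) % 1.0
        mask = np.zeros(n, dtype=bool)
        mask[sub_nodes] = True
        # nodes shared by both halves (seam planes) keep the first assignment
        assign = mask & np.isnan(c)
        c[assign] = vals[remap[assign.nonzero()[0]]]

    # apex cylinder: cylindrical angle about the long axis
    c_theta = (theta / (2 * np.pi)) % 1.0
    c[apex] = c_theta[apex]
    missing = np.isnan(c)
    if missing.any():
        c[missing] = c_theta[missing]
    c = c % 1.0

    return VentricularCoordinates(t=t, c=c, l=l)


# ---------------------------------------------------------------------------
# gradients and frames
# ---------------------------------------------------------------------------

def element_gradients(mesh: TetMesh, field: np.ndarray, periodic: bool = False) -> np.ndarray:
    """Constant per-element gradient of a P1 nodal field.

    With ``periodic=True`` the field is treated as periodic on [0, 1):
    nodal values within an element are unwrapped to lie within 0.5 of the
    element's first node before differentiating (circumferential seam).
    """
    g = _element_shape_gradients(mesh.nodes, mesh.tets)
    f = field[mesh.tets].astype(float)
    if periodic:
        ref = f[:, :1]
        f = ref + ((f - ref + 0.5) % 1.0) - 0.5
    return np.einsum("ea,eai->ei", f, g)


def nodal_gradient(mesh: TetMesh, field: np.ndarray, periodic: bool = False) -> np.ndarray:
    """Volume-weighted average of element gradients at nodes."""
    eg = element_gradients(mesh, field, periodic=periodic)
    w = np.abs(tet_volumes(mesh.nodes, mesh.tets))
    out = np.zeros((mesh.n_nodes, 3))
    wsum = np.zeros(mesh.n_nodes)
    for a in range(4):
        np.add.at(out, mesh.tets[:, a], eg * w[:, None])
        np.add.at(wsum, mesh.tets[:, a], w)
    return out / wsum[:, None]


def compute_local_frames(
    mesh: TetMesh,
    coords: VentricularCoordinates,
    tol: float = 1e-12,
    degenerate: str = "nearest",
) -> LocalFrame:
    """Orthonormal (e_t, e_c, e_l) from re-orthogonalized coordinate gradients.

    Gram-Schmidt order: e_t (transmural gradient, most reliable on thin
    walls), then e_l orthogonalized against e_t, then e_c = e_l x e_t.

    The apex axis is a singular point of the longitudinal field, so its
    nodes have no well-defined frame.  ``degenerate="nearest"`` (default)
    copies the frame of the nearest non-degenerate node there;
    ``degenerate="raise"`` raises a ValueError naming the nodes.
    """
    gt = nodal_gradient(mesh, coords.t)
    gl = nodal_gradient(mesh, coords.l)
    nt = np.linalg.norm(gt, axis=1)
    nl = np.linalg.norm(gl, axis=1)
    # collinearity of the two gradients also leaves the frame undefined
    cross_n = np.linalg.norm(np.cross(gt, gl), axis=1)
    bad = (nt < tol) | (nl < tol) | (cross_n < tol * np.maximum(nt * nl, tol))
    if bad.any():
        bad_ids = np.nonzero(bad)[0]
        if degenerate == "raise" or bad.all():
            raise ValueError(
                f"zero/degenerate coordinate gradient at nodes {bad_ids[:10].tolist()}; frame undefined"
            )
        good_ids = np.nonzero(~bad)[0]
        tree = cKDTree(mesh.nodes[good_ids])
        _, nn = tree.query(mesh.nodes[bad_ids])
        src = good_ids[nn]
        gt[bad_ids], gl[bad_ids] = gt[src], gl[src]
        nt[bad_ids], nl[bad_ids] = nt[src], nl[src]
    e_t = gt / nt[:, None]
    gl_o = gl - np.einsum("ij,ij->i", gl, e_t)[:, None] * e_t
    e_l = gl_o / np.linalg.norm(gl_o, axis=1)[:, None]
    e_c = np.cross(e_l, e_t)
    return LocalFrame(e_t=e_t, e_c=e_c, e_l=e_l)


# ---------------------------------------------------------------------------
# streamline normalization
# ---------------------------------------------------------------------------

def streamline_normalize(
    mesh: TetMesh,
    field: np.ndarray,
    step: float | None = None,
    max_steps: int = 4000,
    nodes: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized arc length along streamlines of a Laplace field's gradient.

    For each node, a streamline of the (unit) gradient direction field is
    traced with fixed-step RK4 forward (increasing field values) and
    backward until leaving the mesh; the node's coordinate is its arc
    length from the 0-end divided by the streamline's total length
    (per-streamline normalization).  Nodes whose streamline exhausts the
    step budget fall back to the raw Laplace value (logged).
    """
    direction = nodal_gradient(mesh, field)
    norms = np.linalg.norm(direction, axis=1)
    if np.any(norms < 1e-14):
        raise ValueError("direction field vanishes at some nodes")
    unit = direction / norms[:, None]
    if step is None:
        step = 0.25 * mesh.mean_edge_length()
    node_ids = np.arange(mesh.n_nodes) if nodes is None else np.asarray(nodes)

    def vel(p, sign):
        v, inside = mesh.interpolate(unit, p[None, :])
        if not inside[0]:
            return None
        v = v[0]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            return None
        return sign * v / nv

    def trace(p0, sign):
        """Arc length until the streamline exits the mesh; None on budget."""
        p = p0.copy()
        length = 0.0
        for _ in range(max_steps):
            k1 = vel(p, sign)
            if k1 is None:
                return length
            k2 = vel(p + 0.5 * step * k1, sign)
            k3 = vel(p + 0.5 * step * (k2 if k2 is not None else k1), sign)
            k4 = vel(p + step * (k3 if k3 is not None else k1), sign)
            if k2 is None or k3 is None or k4 is None:
                d = k1  # Euler fallback while straddling the boundary
            else:
                d = (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
            pn = p + step * d
            if vel(pn, sign) is None:
                # bisect the exit point on the segment [p, pn]
                lo, hi = 0.0, 1.0
                for _ in range(40):
                    mid = 0.5 * (lo + hi)
                    if vel(p + mid * (pn - p), sign) is None:
                        hi = mid
                    else:
                        lo = mid
                return length + hi * float(np.linalg.norm(pn - p))
            p = pn
            length += step * float(np.linalg.norm(d))
        return None

    out = field.astype(float).copy()
    n_fallback = 0
    for i in node_ids:
        p0 = mesh.nodes[i]
        down = trace(p0, -1.0)  # toward the 0-boundary
        up = trace(p0, +1.0)
        if down is None or up is None or (down + up) < 1e-12:
            n_fallback += 1
            continue
        out[i] = down / (down + up)
    if n_fallback:
        logger.warning(
            "streamline normalization fell back to raw Laplace values at %d nodes", n_fallback
        )
    if nodes is None:
        out = np.clip(out, 0.0, 1.0)
    return out
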