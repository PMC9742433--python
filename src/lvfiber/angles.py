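"""Myocardial angle conventions: helix, transverse, E2A, and the
sign-invariant line-angle metric.

All angles are in degrees.  Helix: angle between the fiber's projection
onto the circumferential-longitudinal plane and the circumferential axis,
positive when fiber and longitudinal axis share a half-space.  Transverse:
analogous in the transmural-circumferential plane, signed by the
transmural half-space.  E2A: angle between the sheet direction's
projection onto the cross-myocyte plane and the cross-myocyte direction,
reported as an unsigned magnitude in [0, 90].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FiberField",
    "helix_angle",
    "transverse_angle",
    "sheet_from_e2a",
    "e2a_angle",
    "line_angle_diff",
]

_EPS = 1e-12


@dataclass
class FiberField:
    """Unit fiber / sheet / sheet-normal triads per point (n = f x s)."""

    f: np.ndarray
    s: np.ndarray
    n: np.ndarray

    def validate(self, tol: float = 1e-8) -> None:
        for name, v in (("f", self.f), ("s", self.s), ("n", self.n)):
            if np.abs(np.linalg.norm(v, axis=-1) - 1).max() > tol:
                raise ValueError(f"{name} is not unit length everywhere")
        if np.abs(np.einsum("...i,...i->...", self.f, self.s)).max() > tol:
            raise ValueError("f and s are not orthogonal")
        if np.abs(self.n - np.cross(self.f, self.s)).max() > 10 * tol:
            raise ValueError("n != f x s")


def _dots(f, e):
    return np.einsum("...i,...i->...", f, e)


def helix_angle(f: np.ndarray, e_t: np.ndarray, e_c: np.ndarray, e_l: np.ndarray) -> np.ndarray:
    """Helix angle in (-90, 90] degrees; NaN where the fiber is purely
    transmural (projection onto the c-l plane vanishes)."""
    fc, fl = _dots(f, e_c), _dots(f, e_l)
    proj = np.hypot(fc, fl)
    ang = np.degrees(np.arctan2(fl, fc))
    # map to (-90, 90] treating the fiber as an axis; exactly +/-90 -> +90
    ang = np.where(ang > 90.0, ang - 180.0, ang)
    ang = np.where(ang <= -90.0, ang + 180.0, ang)
    return np.where(proj < _EPS, np.nan, ang)


def transverse_angle(f: np.ndarray, e_t: np.ndarray, e_c: np.ndarray, e_l: np.ndarray) -> np.ndarray:
    """Transverse angle in (-90, 90] degrees; NaN for purely longitudinal
    fibers (projection onto the t-c plane vanishes)."""
    fc, ft = _dots(f, e_c), _dots(f, e_t)
    proj = np.hypot(fc, ft)
    ang = np.degrees(np.arctan2(ft, fc))
    ang = np.where(ang > 90.0, ang - 180.0, ang)
    ang = np.where(ang <= -90.0, ang + 180.0, ang)
    return np.where(proj < _EPS, np.nan, ang)


def _cross_myocyte(f, e_t, e_c, e_l):
    """Unit cross-myocyte direction: e_t x (projection of f onto c-l plane)."""
    fp = _dots(f, e_c)[..., None] * e_c + _dots(f, e_l)[..., None] * e_l
    nrm = np.linalg.norm(fp, axis=-1, keepdims=True)
    if np.any(nrm < _EPS):
        raise ValueError("fiber parallel to the transmural axis; cross-myocyte direction undefined")
    fp = fp / nrm
    cm = np.cross(e_t, fp)
    return cm / np.linalg.norm(cm, axis=-1, keepdims=True), fp


def sheet_from_e2a(f: np.ndarray, e_t: np.ndarray, e_c: np.ndarray, e_l: np.ndarray,
                   e2a_target: float):
    """Construct (s, n) so the sheet realizes a target E2A angle.

    The sheet is placed in the cross-myocyte plane (spanned by the
    cross-myocyte direction cm and e_t) at ``e2a_target`` degrees from cm,
    rotated toward +e_t, and carries the unique out-of-plane component
    along the fiber's c-l projection that makes s exactly orthogonal to f.
    Its projection back onto the cross-myocyte plane therefore recovers
    the target angle exactly for every non-degenerate fiber.
    """
    f = np.asarray(f, dtype=float)
    cm, fp = _cross_myocyte(f, e_t, e_c, e_l)
    gamma = np.radians(float(e2a_target))
    p = np.cos(gamma)
    q = np.sin(gamma)
    ft = _dots(f, e_t)
    fpn = _dots(f, fp)  # in-plane fiber magnitude (norm of the c-l projection)
    r = -q * ft / fpn
    s = p * cm + q * e_t + r[..., None] * fp
    s = s / np.linalg.norm(s, axis=-1, keepdims=True)
    n = np.cross(f, s)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    return s, n


def e2a_angle(s: np.ndarray, f: np.ndarray, e_t: np.ndarray, e_c: np.ndarray,
              e_l: np.ndarray) -> np.ndarray:
    """E2A magnitude in [0, 90] degrees.

    Angle between the projection of the sheet direction onto the
    cross-myocyte plane and the cross-myocyte direction.  NaN where the
    sheet is perpendicular to the cross-myocyte plane.
    """
    cm, _ = _cross_myocyte(f, e_t, e_c, e_l)
    sc = _dots(s, cm)
    st = _dots(s, e_t)
    proj = np.hypot(sc, st)
    ang = np.degrees(np.arctan2(np.abs(st), np.abs(sc)))
    return np.where(proj < _EPS, np.nan, ang)


def line_angle_diff(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Acute angle between two lines (sign-invariant), degrees in [0, 90]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < _EPS) or np.any(nv < _EPS):
        raise ValueError("zero vector has no direction")
    cosang = np.abs(np.einsum("...i,...i->...", u, v)) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
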