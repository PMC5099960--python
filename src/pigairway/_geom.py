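"""Small 3-D geometry helpers shared by the generator and the measurement code.

All vectors are numpy arrays of shape (3,), units mm, right-handed frame.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "rotate_about_axis",
    "angle_between_deg",
    "fit_line_direction",
    "plane_rotation_deg",
    "polyline_length",
    "resample_polyline",
]


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise the zero vector")
    return v / n


def rotate_about_axis(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about ``axis`` (right-hand rule)."""
    k = unit(axis)
    v = np.asarray(v, dtype=float)
    th = np.deg2rad(angle_deg)
    return (
        v * np.cos(th)
        + np.cross(k, v) * np.sin(th)
        + k * np.dot(k, v) * (1.0 - np.cos(th))
    )


def angle_between_deg(a: np.ndarray, b: np.ndarray) -> float:
    c = float(np.clip(np.dot(unit(a), unit(b)), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def fit_line_direction(points: np.ndarray, along: np.ndarray | None = None) -> np.ndarray:
    """Principal direction of a point cloud, oriented to follow ``along``.

    With two points this is simply the segment direction.  ``along`` defaults
    to first-to-last point order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two points to fit a direction")
    if along is None:
        along = pts[-1] - pts[0]
    if pts.shape[0] == 2:
        d = pts[1] - pts[0]
    else:
        centred = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        d = vt[0]
    if np.dot(d, along) < 0:
        d = -d
    return unit(d)


def plane_rotation_deg(parent_dir: np.ndarray, minor_dir: np.ndarray,
                       reference_normal: np.ndarray) -> float:
    """Signed rotation of the bifurcation plane relative to the reference plane.

    The bifurcation plane is spanned by the parent's (distal) direction and the
    minor daughter's (proximal) direction.  The magnitude is the dihedral angle
    between that plane and the reference plane, folded to [0, 90] (a plane is
    only defined up to a half-turn); the sign says which side of the reference
    plane the minor daughter grows toward (+: along the reference normal).
    Taking the sign from the minor daughter keeps it well defined at exactly
    90 degrees, where the dihedral's own sign is numerically degenerate.
    """
    u = unit(parent_dir)
    v = unit(minor_dir)
    n_bif = np.cross(u, v)
    nb = np.linalg.norm(n_bif)
    if nb < 1e-12:
        raise ValueError("minor daughter parallel to parent: bifurcation plane undefined")
    n_bif = n_bif / nb
    n_ref = unit(reference_normal)
    s = float(np.dot(np.cross(n_ref, n_bif), u))
    c = float(np.dot(n_ref, n_bif))
    ang = float(np.degrees(np.arctan2(s, c)))
    if ang > 90.0:
        ang -= 180.0
    elif ang < -90.0:
        ang += 180.0
    side = float(np.dot(v, n_ref))
    if abs(side) > 1e-12:
        return float(np.copysign(abs(ang), side))
    return ang


def trim_polyline(points: np.ndarray, trim_start_mm: float,
                  trim_end_mm: float, max_fraction: float = 0.35) -> np.ndarray:
    """Drop points within a trim distance of either end (by arc length).

    Each trim is capped at ``max_fraction`` of the total length so short
    polylines keep a usable interior; if fewer than two points survive the
    original polyline is returned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        return pts
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0),
                                                        axis=1))])
    total = s[-1]
    if total <= 0:
        return pts
    sel = ((s >= min(trim_start_mm, max_fraction * total))
           & (s <= total - min(trim_end_mm, max_fraction * total)))
    out = pts[sel]
    return out if out.shape[0] >= 2 else pts


def polyline_length(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def resample_polyline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline at approximately uniform arc-length spacing.

    Endpoints are preserved exactly; interior samples are linear interpolants.
    """
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0 or pts.shape[0] < 2:
        return pts.copy()
    n = max(2, int(np.ceil(total / step_mm)) + 1)
    s_old = np.concatenate([[0.0], np.cumsum(seg)])
    s_new = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(s_new, s_old, pts[:, k])
    return out
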