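"""Ellipse geometry for receptive-field / task-location overlap.

The fitted receptive field is summarised by its two-sigma ellipse; overlap
with a 15-deg-radius grating patch is decided from the signed minimum
distance D between the ellipse and the disk (overlap iff D <= 0).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def ellipse_boundary(center, semi_axes, angle, phi):
    """Points on an ellipse boundary at parameter angles ``phi``.

    Parameters
    ----------
    center : (2,) array-like
        Ellipse centre (azimuth, elevation) in degrees.
    semi_axes : (a, b)
        Semi-major and semi-minor axes.
    angle : float
        Rotation of the major axis, radians, counter-clockwise.
    phi : array-like
        Parameter angles.
    """
    cx, cy = center
    a, b = semi_axes
    ca, sa = np.cos(angle), np.sin(angle)
    x = a * np.cos(phi)
    y = b * np.sin(phi)
    return np.column_stack([cx + x * ca - y * sa, cy + x * sa + y * ca])


def point_in_ellipse(point, center, semi_axes, angle):
    """True if ``point`` lies strictly inside the ellipse."""
    a, b = semi_axes
    ca, sa = np.cos(angle), np.sin(angle)
    dx = point[0] - center[0]
    dy = point[1] - center[1]
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a) ** 2 + (v / b) ** 2 < 1.0


def _boundary_distance(center, semi_axes, angle, point, n_coarse=720):
    """Minimum distance from ``point`` to the ellipse boundary.

    Dense sampling followed by bounded 1-D refinement of the best bracket.
    """
    phi = np.linspace(0.0, 2 * np.pi, n_coarse, endpoint=False)
    pts = ellipse_boundary(center, semi_axes, angle, phi)
    d2 = np.sum((pts - np.asarray(point)) ** 2, axis=1)
    k = int(np.argmin(d2))
    step = 2 * np.pi / n_coarse

    def objective(p):
        q = ellipse_boundary(center, semi_axes, angle, np.atleast_1d(p))[0]
        return np.hypot(q[0] - point[0], q[1] - point[1])

    res = minimize_scalar(
        objective,
        bounds=(phi[k] - step, phi[k] + step),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return min(res.fun, float(np.sqrt(d2[k])))


def ellipse_disk_distance(center, semi_axes, angle, disk_center, disk_radius=15.0):
    """Signed minimum distance D between an ellipse and a disk.

    D is the distance from the disk centre to the nearest point of the
    ellipse boundary (negated when the disk centre lies inside the ellipse)
    minus the disk radius.  D <= 0 exactly when the ellipse and the disk
    intersect, touch, or one contains the other.
    """
    a, b = semi_axes
    if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
        raise ValueError(f"degenerate ellipse semi-axes {semi_axes}")
    d = _boundary_distance(center, semi_axes, angle, disk_center)
    if point_in_ellipse(disk_center, center, semi_axes, angle):
        d = -d
    return d - disk_radius


def ellipse_disk_distance_bruteforce(
    center, semi_axes, angle, disk_center, disk_radius=15.0, n_points=10_000
):
    """Brute-force reference: same signed distance from dense boundary sampling."""
    phi = np.linspace(0.0, 2 * np.pi, n_points, endpoint=False)
    pts = ellipse_boundary(center, semi_axes, angle, phi)
    d = float(np.min(np.hypot(pts[:, 0] - disk_center[0], pts[:, 1] - disk_center[1])))
    if point_in_ellipse(disk_center, center, semi_axes, angle):
        d = -d
    return d - disk_radius
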