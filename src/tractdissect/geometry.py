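"""Centerline geometry helpers for synthetic bundles.

A bundle centerline is an ordered list of control points in world millimetres;
it is interpolated with a natural cubic spline, resampled densely, and
re-parametrised by arclength.  Occupancy and tangent queries use the nearest
dense sample (cKDTree), which is accurate to the resampling step (0.25 mm).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

_DENSE_STEP_MM = 0.25


class Centerline:
    """Arclength-parametrised smooth curve through control points."""

    def __init__(self, control_points: np.ndarray):
        cp = np.asarray(control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 3 or len(cp) < 2:
            raise ValueError("centerline needs >= 2 control points of dim 3")
        # chord-length parametrisation
        chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
        spline = CubicSpline(chord, cp, axis=0)
        # densify, then re-parametrise by true arclength
        t = np.linspace(0.0, chord[-1], max(int(chord[-1] / 0.05), 16))
        fine = spline(t)
        seg = np.linalg.norm(np.diff(fine, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(arc[-1])
        n = max(int(self.length / _DENSE_STEP_MM), 8)
        s = np.linspace(0.0, self.length, n)
        self.points = np.column_stack([np.interp(s, arc, fine[:, k]) for k in range(3)])
        tang = np.gradient(self.points, s, axis=0)
        self.tangents = tang / np.linalg.norm(tang, axis=1, keepdims=True)
        self.arclengths = s
        self._tree = cKDTree(self.points)

    def distance_and_tangent(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Distance to the curve and unit tangent at the nearest curve point."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        dist, idx = self._tree.query(pts)
        return dist, self.tangents[idx]

    def point_at_plane(self, axis: int, coord: float) -> np.ndarray | None:
        """First crossing point of the curve with the plane {x_axis = coord}."""
        vals = self.points[:, axis] - coord
        sign = np.sign(vals)
        crossings = np.nonzero(np.diff(sign) != 0)[0]
        exact = np.nonzero(vals == 0)[0]
        if exact.size:
            return self.points[exact[0]].copy()
        if not crossings.size:
            return None
        i = crossings[0]
        w = vals[i] / (vals[i] - vals[i + 1])
        return self.points[i] + w * (self.points[i + 1] - self.points[i])
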