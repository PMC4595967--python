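"""Track geometry: piecewise-linear paths and projection of tracked positions.

A track is modelled as an open polyline in room coordinates (cm).  Raw
camera positions are projected onto the nearest point of the polyline and
expressed as arclength from the first vertex, which is the coordinate all
downstream lap segmentation and binning operate on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TrackGeometry"]


class TrackGeometry:
    """An open piecewise-linear track path.

    Parameters
    ----------
    vertices : (n, 2) array_like
        Path vertices in room coordinates, cm, ordered from one food well
        to the other.  Must contain at least two distinct points.
    """

    def __init__(self, vertices) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n>=2, 2) array")
        seg = np.diff(v, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seg_len <= 0):
            raise ValueError("degenerate geometry: zero-length segment")
        self.vertices = v
        self._seg = seg
        self._seg_len = seg_len
        self._cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    @property
    def length_cm(self) -> float:
        """Total arclength of the path in cm."""
        return float(self._cum[-1])

    @classmethod
    def straight(cls, length_cm: float, origin=(0.0, 0.0), direction=(1.0, 0.0)) -> "TrackGeometry":
        """A straight track of the given length."""
        if length_cm <= 0:
            raise ValueError("length_cm must be positive")
        o = np.asarray(origin, float)
        d = np.asarray(direction, float)
        d = d / np.hypot(*d)
        return cls(np.stack([o, o + length_cm * d]))

    @classmethod
    def c_shape(cls, total_length_cm: float = 300.0) -> "TrackGeometry":
        """A C-shaped track with four corners, total arclength as given.

        Segment proportions are fixed (1:1:2:1:1 of the total); the exact
        shape only matters for projecting 2-D positions, not for any
        linearized analysis.
        """
        u = total_length_cm / 6.0
        verts = np.array(
            [
                [0.0, 0.0],
                [u, 0.0],
                [u, u],
                [u + 2 * u, u],
                [u + 2 * u, 0.0],
                [u + 3 * u, 0.0],
            ]
        )
        g = cls(verts)
        # rescale so arclength matches exactly
        scale = total_length_cm / g.length_cm
        return cls(verts * scale)

    def project(self, xy) -> np.ndarray:
        """Project points onto the path; return arclength positions (cm).

        Parameters
        ----------
        xy : (m, 2) array_like
            Points in room coordinates.

        Returns
        -------
        (m,) ndarray of arclength along the path, in ``[0, length_cm]``.
        """
        p = np.atleast_2d(np.asarray(xy, dtype=float))
        a = self.vertices[:-1]  # (k, 2)
        d = self._seg  # (k, 2)
        ll = self._seg_len**2  # (k,)
        # fractional position of the foot of the perpendicular on each segment
        diff = p[:, None, :] - a[None, :, :]  # (m, k, 2)
        tfrac = np.clip((diff * d[None, :, :]).sum(-1) / ll[None, :], 0.0, 1.0)
        foot = a[None, :, :] + tfrac[:, :, None] * d[None, :, :]
        dist2 = ((p[:, None, :] - foot) ** 2).sum(-1)
        best = np.argmin(dist2, axis=1)
        m = np.arange(p.shape[0])
        return self._cum[best] + tfrac[m, best] * self._seg_len[best]

    def point_at(self, s) -> np.ndarray:
        """Room coordinates of arclength position(s) ``s`` (cm)."""
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length_cm)
        idx = np.clip(np.searchsorted(self._cum, s, side="right") - 1, 0, len(self._seg_len) - 1)
        frac = (s - self._cum[idx]) / self._seg_len[idx]
        return self.vertices[idx] + frac[:, None] * self._seg[idx]
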