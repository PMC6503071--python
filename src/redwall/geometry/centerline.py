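"""Centerline polylines and transport frames used to sweep tube surfaces."""

from __future__ import annotations

import numpy as np


def polyline_arc_length(points: np.ndarray) -> float:
    """Total arc length of a polyline (µm)."""
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def cumulative_arc_length(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents by central differencing along the polyline."""
    t = np.gradient(points, axis=0)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation-minimizing (parallel-transported) frames along a polyline.

    Returns unit tangent ``t`` and two transverse unit vectors ``e1``, ``e2``
    forming a right-handed triad at each polyline node.  Parallel transport
    avoids the frame flips a Frenet frame exhibits at inflection points of a
    tortuous centerline.
    """
    t = tangents(points)
    e1 = np.empty_like(t)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, t[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - np.dot(ref, t[0]) * t[0]
    e1[0] = v / np.linalg.norm(v)
    for i in range(1, len(points)):
        v = e1[i - 1] - np.dot(e1[i - 1], t[i]) * t[i]
        n = np.linalg.norm(v)
        if n < 1e-12:  # pathological kink; restart frame
            v = ref - np.dot(ref, t[i]) * t[i]
            n = np.linalg.norm(v)
        e1[i] = v / n
    e2 = np.cross(t, e1)
    return t, e1, e2


def segment_distance(points: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Distance from query points to a polyline (vectorized over both)."""
    a = points[:-1]
    b = points[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0.0, 1.0, denom)
    q = query[:, None, :] - a[None, :, :]
    s = np.clip(np.einsum("qij,ij->qi", q, ab) / denom, 0.0, 1.0)
    closest = a[None] + s[..., None] * ab[None]
    d = np.linalg.norm(query[:, None, :] - closest, axis=2)
    return d.min(axis=1)


def sinusoidal_bend(amplitude: float, periods: float = 1.0,
                    length: float | None = None, axis: int = 1):
    """Curvature profile: lateral sinusoidal offset of given amplitude (µm).

    Returns a callable mapping axial position ``x`` (and the tube length) to a
    transverse (y, z) offset.  With whole ``periods`` the centerline is
    axially periodic, which the periodic-box flow fixtures rely on.
    """

    def profile(x: np.ndarray, L: float) -> np.ndarray:
        L = length if length is not None else L
        off = np.zeros((np.size(x), 2))
        off[:, axis - 1] = amplitude * np.sin(2.0 * np.pi * periods * np.asarray(x) / L)
        return off

    return profile
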