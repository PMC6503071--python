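"""Velocity/scalar samplers used by the wall-traction pipeline.

The pipeline only needs "velocity at a point"; it runs identically on a
solver grid, on an analytic field (fixtures with closed-form solutions), or
on a time-averaged field.
"""

from __future__ import annotations

from typing import Callable, Protocol

import numpy as np

from ..solver.grid import EulerianGrid, face_offsets


class VelocitySampler(Protocol):
    def velocity(self, points_um: np.ndarray) -> np.ndarray: ...


class CallableSampler:
    """Wraps an analytic velocity field u(points µm) -> (n, 3) m/s."""

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray]):
        self.fn = fn

    def velocity(self, points_um: np.ndarray) -> np.ndarray:
        return np.asarray(self.fn(np.atleast_2d(points_um)), float)


class GridSampler:
    """Trilinear interpolation of staggered face velocities (and optional
    cell-centered scalars) from a solver grid."""

    def __init__(self, grid: EulerianGrid, u: list[np.ndarray]):
        self.grid = grid
        self.u = u

    def velocity(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points_um)
        out = np.empty((len(pts), 3))
        for c in range(3):
            idx, w = self.grid._trilinear_stencil(c, pts)
            out[:, c] = (self.u[c][idx[..., 0], idx[..., 1], idx[..., 2]]
                         * w).sum(axis=1)
        return out


class CellFieldSampler:
    """Trilinear sampler for a cell-centered scalar (pressure, hematocrit)."""

    def __init__(self, grid: EulerianGrid, values: np.ndarray):
        self.grid = grid
        self.values = values

    def sample(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points_um)
        g = self.grid
        gc = (pts - g.origin) / g.h - 0.5
        nx, ny, nz = g.shape
        i0 = np.floor(gc).astype(int)
        f = gc - i0
        out = np.zeros(len(pts))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    ii = i0[:, 0] + dx
                    ii = ii % nx if g.periodic_x else np.clip(ii, 0, nx - 1)
                    jj = np.clip(i0[:, 1] + dy, 0, ny - 1)
                    kk = np.clip(i0[:, 2] + dz, 0, nz - 1)
                    w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                         * np.where(dy, f[:, 1], 1 - f[:, 1])
                         * np.where(dz, f[:, 2], 1 - f[:, 2]))
                    out += w * self.values[ii, jj, kk]
        return out


def time_average(series: list[list[np.ndarray]],
                 cadence: float | None = None,
                 times: list[float] | None = None) -> list[np.ndarray]:
    """Arithmetic mean of a uniformly sampled velocity-snapshot series.

    Each element is a per-component list of face arrays.  With ``times``
    given, uniform cadence is verified (and must match ``cadence`` if both
    are supplied).
    """
    if len(series) < 2:
        raise ValueError("time averaging needs at least 2 samples")
    shapes = [tuple(a.shape for a in s) for s in series]
    if any(s != shapes[0] for s in shapes):
        raise ValueError("mismatched grids in the snapshot series")
    if times is not None:
        dts = np.diff(times)
        if np.max(np.abs(dts - dts[0])) > 1e-9 + 1e-6 * abs(dts[0]):
            raise ValueError("snapshot series is not uniformly sampled")
        if cadence is not None and abs(dts[0] - cadence) > 1e-9:
            raise ValueError("snapshot cadence does not match the requested "
                             "cadence")
    n = len(series)
    return [sum(s[c] for s in series) / n for c in range(3)]
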