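"""Cross-sectional velocity and hematocrit profiles along a chord.

Used to quantify profile blunting (u_max/u_mean drops below the parabolic
value 2 when cells are present) and profile skewness downstream of
junctions or in bent vessels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampling import VelocitySampler


@dataclass
class ChordProfile:
    s: np.ndarray          # chord coordinate, µm (0 at chord midpoint)
    velocity: np.ndarray   # axial (plane-normal) velocity, m/s
    hematocrit: np.ndarray | None
    bluntness: float       # u_max / u_mean over the lumen chord
    skew_side: str         # "positive" | "negative" | "none"
    skew_moment: float     # signed first moment of u about the midpoint


def cross_section_profiles(sampler: VelocitySampler, distance_fn,
                           center: np.ndarray, normal: np.ndarray,
                           chord_dir: np.ndarray,
                           indicator_sampler=None, n: int = 81,
                           search_half_length: float = 30.0,
                           skew_rtol: float = 0.02) -> ChordProfile:
    """Sample profiles along the chord through ``center`` in direction
    ``chord_dir`` (both µm); ``normal`` is the vessel-axis direction used
    for the velocity component.  The chord must cross exactly one lumen
    interval (a plane through a junction is rejected)."""
    normal = np.asarray(normal, float)
    normal /= np.linalg.norm(normal)
    d = np.asarray(chord_dir, float)
    d = d - (d @ normal) * normal
    d /= np.linalg.norm(d)
    s_scan = np.linspace(-search_half_length, search_half_length, 4 * n + 1)
    pts_scan = center[None] + s_scan[:, None] * d[None]
    phi = distance_fn(pts_scan)
    inside = phi < 0
    if not inside.any():
        raise ValueError("chord does not intersect the lumen")
    runs = np.flatnonzero(np.diff(inside.astype(int)))
    segments = (len(runs) + (1 if inside[0] else 0) + (1 if inside[-1] else 0)) // 2
    if segments != 1:
        raise ValueError("chord crosses more than one lumen interval "
                         "(plane through a junction?)")
    idx = np.flatnonzero(inside)

    def refine(s_in: float, s_out: float) -> float:
        for _ in range(50):
            mid = 0.5 * (s_in + s_out)
            if distance_fn(center[None] + mid * d[None])[0] < 0:
                s_in = mid
            else:
                s_out = mid
        return s_in

    s_lo = refine(s_scan[idx[0]], s_scan[idx[0] - 1]) if idx[0] > 0 \
        else s_scan[0]
    s_hi = refine(s_scan[idx[-1]], s_scan[idx[-1] + 1]) \
        if idx[-1] < len(s_scan) - 1 else s_scan[-1]
    s = np.linspace(s_lo, s_hi, n)
    pts = center[None] + s[:, None] * d[None]
    u = sampler.velocity(pts) @ normal
    hem = indicator_sampler.sample(pts) if indicator_sampler is not None else None
    # bluntness compares the chord peak with the cross-sectional (area) mean
    # velocity, so a parabola scores 2 and a plug scores 1
    mid_pt = center + 0.5 * (s_lo + s_hi) * d
    radius = 0.5 * (s_hi - s_lo)
    u_area_mean = _disc_mean(sampler, distance_fn, mid_pt, normal, d, radius)
    bluntness = float(u.max() / u_area_mean) if u_area_mean != 0 else np.nan
    mid = 0.5 * (s_lo + s_hi)
    tot = np.abs(u).sum()
    moment = float(((s - mid) * u).sum() / (tot * (s_hi - s_lo) + 1e-300))
    if abs(moment) <= skew_rtol:
        side = "none"
    else:
        side = "positive" if moment > 0 else "negative"
    return ChordProfile(s=s - mid, velocity=u, hematocrit=hem,
                        bluntness=bluntness, skew_side=side,
                        skew_moment=moment)


def cell_free_layer_width(distance_fn, indicator_sampler, center: np.ndarray,
                          chord_dir: np.ndarray, threshold: float = 0.02,
                          n: int = 161, search_half_length: float = 30.0
                          ) -> float:
    """Width (µm) of the near-wall band where the time-averaged hematocrit
    stays below ``threshold`` x its chord maximum (minimum of the two wall
    sides)."""
    prof = cross_section_profiles(
        lambda_sampler_zero, distance_fn, center, np.array([1.0, 0, 0]),
        chord_dir, indicator_sampler=indicator_sampler, n=n,
        search_half_length=search_half_length)
    hem = prof.hematocrit
    ref = hem.max()
    if ref <= 0:
        return float(prof.s[-1] - prof.s[0])
    above = np.flatnonzero(hem > threshold * ref)
    if len(above) == 0:
        return float(prof.s[-1] - prof.s[0])
    left = prof.s[above[0]] - prof.s[0]
    right = prof.s[-1] - prof.s[above[-1]]
    return float(min(left, right))


def _disc_mean(sampler, distance_fn, center, normal, e1, radius,
               n_r: int = 10, n_t: int = 20) -> float:
    """Lumen-area mean of the plane-normal velocity over the disc."""
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    r_edges = radius * np.sqrt(np.linspace(0, 1, n_r + 1))
    r_mid = np.sqrt(0.5 * (r_edges[:-1] ** 2 + r_edges[1:] ** 2))
    t = 2 * np.pi * (np.arange(n_t) + 0.5) / n_t
    R, T = np.meshgrid(r_mid, t, indexing="ij")
    pts = (center[None]
           + (R * np.cos(T)).ravel()[:, None] * e1[None]
           + (R * np.sin(T)).ravel()[:, None] * e2[None])
    w = np.repeat(np.pi * np.diff(r_edges**2) / n_t, n_t)
    inside = distance_fn(pts) < 0
    if not inside.any():
        return 0.0
    u = sampler.velocity(pts) @ normal
    return float((u[inside] * w[inside]).sum() / w[inside].sum())


class _ZeroSampler:
    def velocity(self, pts):
        return np.zeros((len(np.atleast_2d(pts)), 3))


lambda_sampler_zero = _ZeroSampler()
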