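"""ROI statistics: area-weighted averages, per-vessel variability, temporal
RMS, and RBC-influence ratio maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..geometry.wallmesh import WallMesh
from .fields import WSSField, WSSGField


def _roi_mask(mesh: WallMesh, roi) -> np.ndarray:
    if isinstance(roi, str):
        mask = mesh.roi_labels == roi
    else:
        mask = np.asarray(roi, dtype=bool)
    return mask


def _values(f, component: str = "t_s") -> np.ndarray:
    if isinstance(f, WSSField):
        return getattr(f, component)
    if isinstance(f, WSSGField):
        return f.magnitude if component == "magnitude" else getattr(f, component)
    return np.asarray(f, float)


def _valid(f, n: int) -> np.ndarray:
    if isinstance(f, (WSSField, WSSGField)):
        return f.valid
    return np.ones(n, dtype=bool)


def roi_average(f, mesh: WallMesh, roi, component: str = "t_s") -> float:
    """Area-weighted ROI mean:  tau_bar = sum(tau dA) / A  over valid
    vertices of the ROI."""
    mask = _roi_mask(mesh, roi)
    vals = _values(f, component)
    mask = mask & _valid(f, len(vals))
    if not mask.any():
        name = roi if isinstance(roi, str) else "<mask>"
        raise ValueError(f"ROI {name!r} has no valid vertices")
    w = mesh.vertex_area[mask]
    return float((vals[mask] * w).sum() / w.sum())


def vessel_std(f, mesh: WallMesh, roi, component: str = "t_s") -> float:
    """Normalized per-vessel WSS standard deviation

        tau' = (1/tau_bar) sqrt( sum_i (tau_i - tau_bar)^2 / (N-1) )

    over the vessel's mesh vertices — a coefficient-of-variation-like
    measure of spatial WSS variability (dimensionless, scale invariant)."""
    mask = _roi_mask(mesh, roi)
    vals = _values(f, component)
    mask = mask & _valid(f, len(vals))
    x = vals[mask]
    if len(x) < 2:
        raise ValueError("vessel_std needs at least 2 vertices")
    mean = x.mean()
    if mean == 0:
        raise ValueError("vessel_std undefined: mean WSS is zero")
    return float(np.sqrt(((x - mean) ** 2).sum() / (len(x) - 1)) / mean)


@dataclass
class RMSResult:
    absolute: float   # vertex-averaged temporal RMS, field units
    relative: float | None  # scaled by |ROI time-averaged value|


def temporal_rms(series: list, mesh: WallMesh, roi,
                 component: str = "t_s") -> RMSResult:
    """Temporal fluctuation statistics of a WSS/WSSG signal over an ROI.

    Per-vertex RMS of (signal - its time mean); the ROI *absolute* RMS is
    the plain vertex average of those, the *relative* RMS divides each
    vertex's RMS by the magnitude of the ROI's time-averaged value before
    averaging (None when that average vanishes)."""
    if len(series) < 8:
        raise ValueError("temporal RMS needs at least 8 time samples")
    vals = np.stack([_values(f, component) for f in series])  # (T, n)
    valid = np.ones(vals.shape[1], dtype=bool)
    for f in series:
        valid &= _valid(f, vals.shape[1])
    mask = _roi_mask(mesh, roi) & valid
    if not mask.any():
        raise ValueError("ROI has no valid vertices")
    x = vals[:, mask]
    rms = np.sqrt(((x - x.mean(axis=0)) ** 2).mean(axis=0))
    absolute = float(rms.mean())
    w = mesh.vertex_area[mask]
    roi_time_mean = float((x.mean(axis=0) * w).sum() / w.sum())
    relative = None
    if roi_time_mean != 0.0:
        relative = float((rms / abs(roi_time_mean)).mean())
    return RMSResult(absolute=absolute, relative=relative)


def ratio_map(wss_rbc: WSSField, wss_pl: WSSField, mesh: WallMesh,
              rois: list | None = None, floor: float = 1e-12,
              enforce_flow_bc: bool = True):
    """RBC influence on WSS:  per-vertex and per-ROI tau_RBC / tau_pl.

    Comparing runs with different driving is meaningless for this ratio, so
    both fields must come from inlet-flow-rate runs (checked against the run
    metadata when present).  The per-ROI ratio is the ratio of ROI averages,
    not the average of pointwise ratios."""
    if len(wss_rbc.t_s) != len(wss_pl.t_s):
        raise ValueError("fields live on different meshes")
    if enforce_flow_bc:
        for f, name in ((wss_rbc, "RBC"), (wss_pl, "plasma")):
            if f.bc_kind is not None and f.bc_kind != "inlet_flow_rate":
                raise ValueError(
                    f"{name} run used the {f.bc_kind!r} boundary condition; "
                    "the RBC-influence ratio is defined for matched "
                    "inlet-flow-rate runs only")
    ok = wss_rbc.valid & wss_pl.valid & (np.abs(wss_pl.t_s) > floor)
    pointwise = np.full(len(wss_rbc.t_s), np.nan)
    pointwise[ok] = wss_rbc.t_s[ok] / wss_pl.t_s[ok]
    roi_ratios = {}
    for roi in (rois if rois is not None else mesh.roi_names()):
        roi_ratios[roi] = (roi_average(wss_rbc, mesh, roi)
                           / roi_average(wss_pl, mesh, roi))
    return pointwise, roi_ratios
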