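"""Network-level aggregation: branch flow/cell-flux partitioning at
junctions (phase separation) and per-vessel WSS tables.

At a bifurcation the flow ratio Q1* = Q_D1/Q_F and the RBC flux ratio
N1* = N_D1/N_F quantify how disproportionately cells partition relative to
plasma; N1* - Q1* > 0 in the favored branch is classical plasma skimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry.network import NetworkSpec
from .wss.sampling import VelocitySampler

UM = 1e-6


@dataclass
class GatePlane:
    """Flux-metering disc in a vessel: center/normal (µm), radius (µm).

    The normal is oriented along the nominal flow direction of the vessel.
    """

    vessel_id: int
    center: np.ndarray
    normal: np.ndarray
    radius: float

    def quadrature(self, n_r: int = 12, n_t: int = 24):
        """Polar quadrature nodes (µm) and weights (µm²) over the disc."""
        nrm = self.normal / np.linalg.norm(self.normal)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(nrm @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(nrm, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)
        # midpoint rule in r^2 (equal-area rings) and angle
        r_edges = self.radius * np.sqrt(np.linspace(0, 1, n_r + 1))
        r_mid = np.sqrt(0.5 * (r_edges[:-1] ** 2 + r_edges[1:] ** 2))
        t = 2 * np.pi * (np.arange(n_t) + 0.5) / n_t
        R, T = np.meshgrid(r_mid, t, indexing="ij")
        pts = (self.center[None]
               + (R * np.cos(T)).ravel()[:, None] * e1[None]
               + (R * np.sin(T)).ravel()[:, None] * e2[None])
        ring_area = np.pi * np.diff(r_edges**2) / n_t
        w = np.repeat(ring_area, n_t)
        return pts, w, nrm

    def flux(self, sampler: VelocitySampler) -> float:
        """Volumetric flow rate (µm³/s) of the sampled field through the
        gate."""
        pts, w, nrm = self.quadrature()
        u = sampler.velocity(pts) @ nrm  # m/s
        return float((u * w).sum() / UM)  # (m/s)·µm² -> µm³/s

    def count_crossings(self, centroid_series: np.ndarray,
                        times: np.ndarray) -> float:
        """Net signed centroid crossings per second through the gate disc.

        ``centroid_series`` has shape (T, n_cells, 3) in µm.
        """
        nrm = self.normal / np.linalg.norm(self.normal)
        s = (centroid_series - self.center[None, None]) @ nrm
        lateral = (centroid_series - self.center[None, None]) \
            - s[..., None] * nrm[None, None]
        r = np.linalg.norm(lateral, axis=2)
        sign = s > 0
        crossings = 0.0
        for k in range(1, len(times)):
            flipped = sign[k] != sign[k - 1]
            near = (r[k] < self.radius) | (r[k - 1] < self.radius)
            step = np.where(sign[k], 1.0, -1.0)
            crossings += (step * (flipped & near)).sum()
        window = times[-1] - times[0]
        return crossings / window if window > 0 else 0.0


def gate_for_vessel(spec: NetworkSpec, vessel_id: int,
                    downstream_of: np.ndarray | None = None,
                    distance_diameters: float = 1.0) -> GatePlane:
    """Gate one feeder-diameter downstream of the junction center (or at
    mid-vessel when no junction is given), normal along the centerline."""
    v = spec.vessel(vessel_id)
    cl = v.centerline
    seg = np.diff(cl, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0], np.cumsum(lens)])
    if downstream_of is None:
        s_target = 0.5 * arc[-1]
    else:
        d0 = np.linalg.norm(cl - downstream_of, axis=1)
        i0 = int(np.argmin(d0))
        s_target = arc[i0] + distance_diameters * v.diameter
        s_target = min(max(s_target, 0.15 * arc[-1]), 0.85 * arc[-1])
    i = int(np.searchsorted(arc, s_target).clip(1, len(arc) - 1))
    f = (s_target - arc[i - 1]) / max(lens[i - 1], 1e-12)
    center = cl[i - 1] + f * seg[i - 1]
    normal = seg[i - 1] / lens[i - 1]
    return GatePlane(vessel_id=vessel_id, center=center, normal=normal,
                     radius=0.5 * v.diameter)


@dataclass
class BifurcationFlux:
    """Time-averaged flow and RBC-flux partitioning at one junction."""

    junction_id: int
    kind: str
    feeder_diameter: float           # D_f (bifurcation) or D_m (convergence)
    Q_F: float                       # µm³/s
    Q_D: tuple[float, float]
    N_F: float | None = None         # cells/s (None for plasma-only runs)
    N_D: tuple[float, float] | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def Q_star(self) -> tuple[float, float]:
        return (self.Q_D[0] / self.Q_F, self.Q_D[1] / self.Q_F)

    @property
    def N_star(self) -> tuple[float, float] | None:
        if self.N_F is None or self.N_F == 0:
            return None
        return (self.N_D[0] / self.N_F, self.N_D[1] / self.N_F)

    def check_conservation(self, rtol: float = 0.02) -> None:
        q1, q2 = self.Q_star
        if abs(q1 + q2 - 1.0) > rtol:
            raise ValueError(
                f"junction {self.junction_id}: Q1*+Q2* = {q1 + q2:.3f} "
                "violates time-averaged mass conservation")

    def phase_separation(self) -> tuple[float, float] | None:
        """(N1*-Q1*, N2*-Q2*) with branch 1 the higher-Q* branch."""
        ns = self.N_star
        if ns is None:
            return None
        qs = self.Q_star
        order = (0, 1) if qs[0] >= qs[1] else (1, 0)
        return (ns[order[0]] - qs[order[0]], ns[order[1]] - qs[order[1]])


def branch_fluxes(sampler: VelocitySampler, spec: NetworkSpec,
                  centroid_series: np.ndarray | None = None,
                  times: np.ndarray | None = None,
                  transient_fraction: float = 0.2) -> list[BifurcationFlux]:
    """Flow and cell-flux partitioning at every bifurcation of a network.

    ``sampler`` samples the *time-averaged* velocity; cell fluxes come from
    centroid crossings of the gate discs over the (transient-trimmed)
    trajectory series.
    """
    out = []
    if centroid_series is not None:
        k0 = int(transient_fraction * len(centroid_series))
        centroid_series = centroid_series[k0:]
        times = np.asarray(times)[k0:]
    for j in spec.bifurcations():
        feeder = spec.vessel(j.feeders[0])
        gF = gate_for_vessel(spec, feeder.id, downstream_of=None)
        gates = [gate_for_vessel(spec, d, downstream_of=j.center)
                 for d in j.daughters]
        QF = gF.flux(sampler)
        QD = tuple(g.flux(sampler) for g in gates)
        NF = ND = None
        if centroid_series is not None and len(centroid_series) >= 2:
            NF = abs(gF.count_crossings(centroid_series, times))
            ND = tuple(abs(g.count_crossings(centroid_series, times))
                       for g in gates)
        out.append(BifurcationFlux(junction_id=j.id, kind=j.kind,
                                   feeder_diameter=feeder.diameter,
                                   Q_F=QF, Q_D=QD, N_F=NF, N_D=ND))
    return out


@dataclass
class PhaseSeparationFit:
    slope: float
    intercept: float
    r_value: float
    n_points: int
    degenerate: bool = False


def phase_separation_vs_wss(fluxes: list[BifurcationFlux],
                            wss_by_vessel: dict[int, float],
                            spec: NetworkSpec) -> PhaseSeparationFit:
    """OLS of the phase-separation degree (N1*-Q1*) against the daughter
    WSS discrepancy (tau_bar_D1 - tau_bar_D2), branch 1 = higher-Q* branch.
    """
    xs, ys = [], []
    for bf in fluxes:
        ps = bf.phase_separation()
        if ps is None:
            continue
        j = next(jj for jj in spec.junctions if jj.id == bf.junction_id)
        qs = bf.Q_star
        order = (0, 1) if qs[0] >= qs[1] else (1, 0)
        d1 = j.daughters[order[0]]
        d2 = j.daughters[order[1]]
        xs.append(wss_by_vessel[d1] - wss_by_vessel[d2])
        ys.append(ps[0])
    if len(xs) < 3:
        raise ValueError("phase-separation regression needs >= 3 bifurcations")
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if np.ptp(xs) < 1e-15:
        return PhaseSeparationFit(np.nan, float(ys.mean()), np.nan,
                                  len(xs), degenerate=True)
    fit = sps.linregress(xs, ys)
    return PhaseSeparationFit(float(fit.slope), float(fit.intercept),
                              float(fit.rvalue), len(xs))


def phase_separation_points(xs, ys) -> PhaseSeparationFit:
    """OLS on prepared (x, y) points (synthetic or external data)."""
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    if len(xs) < 2 or np.ptp(xs) < 1e-15:
        return PhaseSeparationFit(np.nan, float(np.mean(ys)), np.nan,
                                  len(xs), degenerate=True)
    fit = sps.linregress(xs, ys)
    return PhaseSeparationFit(float(fit.slope), float(fit.intercept),
                              float(fit.rvalue), len(xs))


def vessel_table(spec: NetworkSpec, mesh, wss_rbc=None, wss_pl=None,
                 wssg_rbc=None, extra: dict | None = None) -> pd.DataFrame:
    """One record per vessel: geometry plus paired RBC/plasma ROI summaries.

    Pairing requires both runs on the same geometry; the ratio columns are
    filled only when both fields are given.
    """
    from .wss.stats import roi_average, vessel_std

    rows = []
    for v in spec.vessels:
        roi = f"vessel:{v.id}"
        row = {"vessel_id": v.id, "diameter_um": v.diameter,
               "length_um": v.length, "order": v.order, "class": v.vclass}
        present = (mesh.roi_labels == roi).any()
        for name, f in (("tau_rbc", wss_rbc), ("tau_pl", wss_pl)):
            row[name] = (roi_average(f, mesh, roi)
                         if (f is not None and present) else np.nan)
            if f is not None and present:
                try:
                    row[name.replace("tau", "tau_std")] = vessel_std(f, mesh, roi)
                except ValueError:
                    row[name.replace("tau", "tau_std")] = np.nan
        if wssg_rbc is not None and present:
            row["wssg_mag_rbc"] = roi_average(wssg_rbc, mesh, roi,
                                              component="magnitude")
        row["tau_ratio"] = (row.get("tau_rbc", np.nan)
                            / row.get("tau_pl", np.nan))
        row["paired"] = bool(np.isfinite(row["tau_ratio"]))
        if extra and v.id in extra:
            row.update(extra[v.id])
        rows.append(row)
    return pd.DataFrame(rows)
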