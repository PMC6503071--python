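"""Reproducible run configuration (TOML) and the paired-run workflow.

A run config gathers geometry, boundary condition, seeding, solver and
pipeline options.  Every output embeds the fully resolved config and its
hash; one RNG seed per run drives all randomness (sub-seeds are derived
deterministically per module).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class GeometryConfig:
    kind: str = "tube"          # tube | curved_tube | junction | network
    diameter: float = 10.0      # µm (tube kinds)
    length: float = 24.0        # µm
    bend_amplitude: float = 0.0  # µm (curved tube)
    bend_periods: float = 1.0
    mesh_size: float = 0.5      # µm
    # junction parameters
    junction_kind: str = "bifurcation"
    feeder_diameter: float = 14.0
    branch_diameters: tuple[float, float] = (10.0, 8.0)
    angles: tuple[float, float] = (35.0, 35.0)
    # network parameters
    n_orders: int = 2
    horton_ratio: float = 1.6
    tortuosity: float = 0.3


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    bc_kind: str = "inlet_flow_rate"
    bc_value: float = 2e-13       # m³/s (or Pa/µm for pressure_drop)
    hematocrit: float = 0.2
    seed: int = 0
    h: float = 0.5                # µm
    dt: float | None = None       # s
    t_end: float = 0.02           # s
    sample_dt: float = 5e-4       # s (0.5 ms cadence)
    stencil_span: float = 0.3     # µm
    n_refine: int = 3
    output_dir: str = "runs"

    def resolved(self) -> dict:
        d = asdict(self)
        d["config_hash"] = self.config_hash()
        return d

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def subseed(self, module: str) -> int:
        """Deterministic per-module sub-seed below 2^31."""
        hsh = hashlib.sha256(f"{self.seed}:{module}".encode()).digest()
        return int.from_bytes(hsh[:4], "little") % (2**31 - 1)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        geo = GeometryConfig(**raw.pop("geometry", {}))
        bc = raw.pop("bc", {})
        solver = raw.pop("solver", {})
        cells = raw.pop("cells", {})
        pipeline = raw.pop("pipeline", {})
        output = raw.pop("output", {})
        kw = {}
        kw.update({"bc_kind": bc.get("kind", "inlet_flow_rate"),
                   "bc_value": bc.get("value", 2e-13)})
        for k in ("h", "dt", "t_end", "sample_dt"):
            if k in solver:
                kw[k] = solver[k]
        if "hematocrit" in cells:
            kw["hematocrit"] = cells["hematocrit"]
        if "seed" in cells:
            kw["seed"] = cells["seed"]
        if "n_refine" in cells:
            kw["n_refine"] = cells["n_refine"]
        if "stencil_span" in pipeline:
            kw["stencil_span"] = pipeline["stencil_span"]
        if "dir" in output:
            kw["output_dir"] = output["dir"]
        kw.update(raw)
        return cls(geometry=geo, **kw)


def build_geometry(cfg: GeometryConfig):
    """Instantiate the configured geometry -> (mesh, spec)."""
    from .geometry import (make_junction, make_network, make_tube,
                           sinusoidal_bend)

    if cfg.kind == "tube":
        return make_tube(cfg.diameter, cfg.length, None, cfg.mesh_size)
    if cfg.kind == "curved_tube":
        prof = sinusoidal_bend(cfg.bend_amplitude, cfg.bend_periods)
        return make_tube(cfg.diameter, cfg.length, prof, cfg.mesh_size)
    if cfg.kind == "junction":
        return make_junction(cfg.junction_kind, cfg.feeder_diameter,
                             tuple(cfg.branch_diameters), tuple(cfg.angles))
    if cfg.kind == "network":
        return make_network(cfg.n_orders, cfg.horton_ratio, cfg.tortuosity,
                            seed=cfg.seed if hasattr(cfg, "seed") else 0)
    raise ValueError(f"unknown geometry kind {cfg.kind!r}")


def periodic_box_for_tube(cfg: GeometryConfig, margin: float = 1.0):
    """Box bounds (µm) for a periodic tube run."""
    half = cfg.diameter / 2.0 + cfg.bend_amplitude + margin
    lo = np.array([0.0, -half, -half])
    hi = np.array([cfg.length, half, half])
    return lo, hi


def run_from_config(cfg: RunConfig, plasma_only: bool = False):
    """Execute one run end to end; returns the RunResult (geometry attached).

    Tube geometries run in the periodic axial box; junctions and networks in
    a capped box with the inlet on the low-x face.
    """
    from .geometry import signed_distance
    from .membrane import make_biconcave, seed_cells
    from .solver import classify_grid
    from .solver.simulation import SimulationConfig, run_simulation

    mesh, spec = build_geometry(cfg.geometry)
    periodic = cfg.geometry.kind in ("tube", "curved_tube")
    df = signed_distance(mesh, min(cfg.h, 0.5),
                         min_diameter=min(v.diameter for v in spec.vessels))
    if periodic:
        lo, hi = periodic_box_for_tube(cfg.geometry)
    else:
        lo = mesh.vertices.min(axis=0) - 1.0
        hi = mesh.vertices.max(axis=0) + 1.0
    grid = classify_grid(df, cfg.h, lo=lo, hi=hi, periodic_x=periodic)
    placements = []
    template = None
    ht = 0.0 if plasma_only else cfg.hematocrit
    if ht > 0:
        template = make_biconcave(n_refine=cfg.n_refine)
        placements = seed_cells(df, ht, seed=cfg.subseed("seeding"),
                                cell=template, bounds=(lo, hi))
    sim = SimulationConfig(h=cfg.h, dt=cfg.dt, t_end=cfg.t_end,
                           sample_dt=cfg.sample_dt, bc_kind=cfg.bc_kind,
                           bc_value=cfg.bc_value, hematocrit=ht,
                           seed=cfg.seed, n_refine=cfg.n_refine,
                           periodic_x=periodic)
    res = run_simulation(grid, sim, placements=placements, template=template)
    res.mesh = mesh          # type: ignore[attr-defined]
    res.network_spec = spec  # type: ignore[attr-defined]
    res.run_config = cfg     # type: ignore[attr-defined]
    return res


def run_pair(cfg: RunConfig):
    """Paired RBC + plasma-only runs on identical geometry and BC, with the
    joined RBC-influence ratio report (flow-rate BC pairs only)."""
    from .wss import (GridSampler, local_frames, ratio_map, wall_shear_stress)

    if cfg.bc_kind != "inlet_flow_rate":
        raise ValueError(
            "ratio-bearing pairs require the inlet_flow_rate boundary "
            "condition; pressure pairs carry no meaningful WSS ratio")
    res_rbc = run_from_config(cfg, plasma_only=False)
    res_pl = run_from_config(cfg, plasma_only=True)
    mesh = res_rbc.mesh
    out = {}
    for name, res in (("rbc", res_rbc), ("plasma", res_pl)):
        sampler = GridSampler(res.grid, res.mean_u)
        frames = local_frames(mesh, sampler, probe_depth=cfg.stencil_span)
        out[name] = wall_shear_stress(
            sampler, mesh, frames, stencil_span=cfg.stencil_span,
            kind="time-averaged", bc_kind=cfg.bc_kind)
    pointwise, roi_ratios = ratio_map(out["rbc"], out["plasma"], mesh)
    return res_rbc, res_pl, {"wss_rbc": out["rbc"], "wss_plasma": out["plasma"],
                             "pointwise_ratio": pointwise,
                             "roi_ratios": roi_ratios}
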