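"""Vessel-graph specification and synthesis of small in-vivo-like networks.

The generator emulates the morphometry of microvascular networks: three
Strahler orders spanning the arterial and venous sides, diameters linked
across orders by Horton's law (a constant diameter ratio between consecutive
orders), diameters within 6–24 µm, segment lengths within 25–165 µm, tortuous
centerlines, and an equal number of bifurcations and convergences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .centerline import polyline_arc_length

DIAMETER_BOUNDS = (6.0, 24.0)
LENGTH_BOUNDS = (25.0, 165.0)


@dataclass
class Vessel:
    id: int
    centerline: np.ndarray  # (k, 3) polyline, µm
    diameter: float  # µm
    order: int  # Strahler order in {1, 2, 3}
    vclass: str  # arteriole | capillary | venule

    @property
    def length(self) -> float:
        return polyline_arc_length(self.centerline)

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter


@dataclass
class Junction:
    id: int
    kind: str  # bifurcation | convergence
    feeders: list[int]
    daughters: list[int]
    center: np.ndarray  # (3,) µm


@dataclass
class NetworkSpec:
    vessels: list[Vessel]
    junctions: list[Junction] = field(default_factory=list)
    inlets: list[int] = field(default_factory=list)
    outlets: list[int] = field(default_factory=list)
    horton_ratio: float = 1.6

    def vessel(self, vid: int) -> Vessel:
        for v in self.vessels:
            if v.id == vid:
                return v
        raise KeyError(f"no vessel with id {vid}")

    def bifurcations(self) -> list[Junction]:
        return [j for j in self.junctions if j.kind == "bifurcation"]

    def convergences(self) -> list[Junction]:
        return [j for j in self.junctions if j.kind == "convergence"]

    def validate(self, check_bounds: bool = True) -> None:
        """Raise ``ValueError`` on violated morphometric invariants."""
        for v in self.vessels:
            if check_bounds and not (DIAMETER_BOUNDS[0] <= v.diameter <= DIAMETER_BOUNDS[1]):
                raise ValueError(
                    f"vessel {v.id}: diameter {v.diameter:.2f} µm outside "
                    f"{DIAMETER_BOUNDS} µm")
            if check_bounds and not (LENGTH_BOUNDS[0] <= v.length <= LENGTH_BOUNDS[1]):
                raise ValueError(
                    f"vessel {v.id}: length {v.length:.2f} µm outside "
                    f"{LENGTH_BOUNDS} µm")
        for j in self.junctions:
            if j.kind == "bifurcation" and (len(j.feeders), len(j.daughters)) != (1, 2):
                raise ValueError(f"bifurcation {j.id} must have 1 feeder and 2 daughters")
            if j.kind == "convergence" and (len(j.feeders), len(j.daughters)) != (2, 1):
                raise ValueError(f"convergence {j.id} must have 2 feeders and 1 collector")
        self._check_connected()

    def _check_connected(self) -> None:
        adj: dict[int, set[int]] = {v.id: set() for v in self.vessels}
        for j in self.junctions:
            members = j.feeders + j.daughters
            for a in members:
                for b in members:
                    if a != b:
                        adj[a].add(b)
        if not self.inlets:
            return
        seen = set(self.inlets)
        stack = list(self.inlets)
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        missing = [o for o in self.outlets if o not in seen]
        if missing:
            raise ValueError(f"outlets {missing} unreachable from the inlet(s)")

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        payload = {
            "vessels": [asdict(v) for v in self.vessels],
            "junctions": [asdict(j) for j in self.junctions],
            "inlets": self.inlets,
            "outlets": self.outlets,
            "horton_ratio": self.horton_ratio,
        }
        text = json.dumps(payload, default=enc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "NetworkSpec":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        vessels = [Vessel(v["id"], np.asarray(v["centerline"]), v["diameter"],
                          v["order"], v["vclass"]) for v in payload["vessels"]]
        junctions = [Junction(j["id"], j["kind"], list(j["feeders"]),
                              list(j["daughters"]), np.asarray(j["center"]))
                     for j in payload["junctions"]]
        return cls(vessels, junctions, payload["inlets"], payload["outlets"],
                   payload["horton_ratio"])


def _polyline(rng: np.random.Generator, start: np.ndarray, end: np.ndarray,
              bow: np.ndarray | None, tort_amp: float, n: int = 21) -> np.ndarray:
    """Polyline from start to end: optional quadratic-Bezier bow plus a
    sinusoidal tortuosity perturbation pinned at both endpoints."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    t = np.linspace(0.0, 1.0, n)
    pts = start[None] + t[:, None] * (end - start)[None]
    if bow is not None:
        pts = pts + (2.0 * t * (1.0 - t))[:, None] * np.asarray(bow, float)[None]
    if tort_amp > 0:
        chord = end - start
        chord = chord / np.linalg.norm(chord)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(chord @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(chord, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(chord, e1)
        ang = rng.uniform(0, 2 * np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        lateral = np.cos(ang) * e1 + np.sin(ang) * e2
        pts = pts + (tort_amp * np.sin(2 * np.pi * t + phase)
                     * np.sin(np.pi * t))[:, None] * lateral[None]
    return pts


def build_network(n_orders: int = 3, horton_ratio: float = 1.6,
                  tortuosity: float = 0.3, seed: int = 0,
                  capillary_diameter: float = 7.0,
                  venous_widening: float = 1.15) -> NetworkSpec:
    """Synthesize a flow-through network specification.

    An arterial tree of ``n_orders`` Strahler orders descends from a single
    feeding vessel to the capillary bed; each terminal arterial bifurcation
    feeds a capillary loop (two tortuous capillaries that re-converge), and a
    mirrored venous tree ascends to a single draining venule.  Diameters
    follow Horton's law ``D(order) = capillary_diameter * horton_ratio**(order-1)``
    with venous vessels ``venous_widening`` wider than arterial ones of the
    same order; tortuosity amplitude is ``tortuosity * diameter``.
    Fully deterministic for a fixed ``seed``.
    """
    if n_orders not in (2, 3):
        raise ValueError("n_orders must be 2 or 3")
    rng = np.random.default_rng(seed)

    def diameter(order: int, side: str) -> float:
        d = capillary_diameter * horton_ratio ** (order - 1)
        if side == "ven":
            d *= venous_widening
        lo, hi = DIAMETER_BOUNDS
        if not (lo <= d <= hi):
            raise ValueError(
                f"order-{order} {side} diameter {d:.2f} µm violates the "
                f"{lo}-{hi} µm diameter bound; adjust horton_ratio or "
                "capillary_diameter")
        return d

    def jitter(x: float) -> float:
        return x * rng.uniform(0.97, 1.06)

    vessels: list[Vessel] = []
    junctions: list[Junction] = []
    _vid = iter(range(10_000))
    _jid = iter(range(10_000))

    def add_vessel(start, end, d, order, vclass, bow=None) -> Vessel:
        amp = tortuosity * d
        v = Vessel(next(_vid), _polyline(rng, start, end, bow, amp), d, order, vclass)
        vessels.append(v)
        return v

    y3, y2 = 18.0, 9.0  # lateral half-spreads of the two bifurcation tiers
    x_hat = np.array([1.0, 0.0, 0.0])

    # --- arterial side ---------------------------------------------------
    if n_orders == 3:
        a3 = add_vessel(np.zeros(3), np.array([jitter(40.0), 0, 0]),
                        diameter(3, "art"), 3, "arteriole")
        p0 = a3.centerline[-1]
        ends2 = []
        a2s = []
        for sgn in (-1.0, 1.0):
            dx = jitter(33.0)
            end = p0 + np.array([dx, sgn * y3, rng.uniform(-2, 2)])
            a2 = add_vessel(p0, end, diameter(2, "art"), 2, "arteriole")
            a2s.append(a2)
            ends2.append(end)
        junctions.append(Junction(next(_jid), "bifurcation", [a3.id],
                                  [a2s[0].id, a2s[1].id], p0))
        feed2 = a2s
    else:
        a2 = add_vessel(np.zeros(3), np.array([jitter(40.0), 0, 0]),
                        diameter(2, "art"), 2, "arteriole")
        feed2 = [a2]
        ends2 = [a2.centerline[-1]]

    # --- capillary loops + order-2 venules --------------------------------
    d1a = diameter(1, "art")
    v2_ids, v2_ends = [], []
    for a2, p in zip(feed2, ends2):
        loop_end = p + np.array([jitter(30.0), 0.0, rng.uniform(-2, 2)])
        caps = []
        for sgn in (-1.0, 1.0):
            bow = np.array([0.0, sgn * y2, rng.uniform(-1.5, 1.5)])
            c = add_vessel(p, loop_end, d1a, 1, "capillary", bow=bow)
            caps.append(c)
        junctions.append(Junction(next(_jid), "bifurcation", [a2.id],
                                  [caps[0].id, caps[1].id], p))
        d2v = diameter(2, "ven")
        if n_orders == 3:
            # head back toward the midline for the final convergence
            sgn_mid = -np.sign(p[1]) if p[1] != 0 else 1.0
            v2_end = loop_end + np.array([jitter(33.0), sgn_mid * y3, 0.0])
        else:
            v2_end = loop_end + np.array([jitter(40.0), 0.0, 0.0])
        v2 = add_vessel(loop_end, v2_end, d2v, 2, "venule")
        junctions.append(Junction(next(_jid), "convergence",
                                  [caps[0].id, caps[1].id], [v2.id], loop_end))
        v2_ids.append(v2.id)
        v2_ends.append(v2_end)

    # --- venous root ------------------------------------------------------
    if n_orders == 3:
        center = 0.5 * (v2_ends[0] + v2_ends[1])
        # snap both order-2 venule ends onto the common convergence center
        for vid_, endp in zip(v2_ids, v2_ends):
            vv = next(v for v in vessels if v.id == vid_)
            vv.centerline = vv.centerline + (center - endp) * np.linspace(
                0, 1, len(vv.centerline))[:, None]
        v3 = add_vessel(center, center + x_hat * jitter(40.0),
                        diameter(3, "ven"), 3, "venule")
        junctions.append(Junction(next(_jid), "convergence", v2_ids,
                                  [v3.id], center))
        outlet = v3.id
    else:
        outlet = v2_ids[0]

    spec = NetworkSpec(vessels, junctions, inlets=[vessels[0].id],
                       outlets=[outlet], horton_ratio=horton_ratio)
    spec.validate(check_bounds=True)
    return spec
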