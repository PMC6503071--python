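"""Local cylindrical frames on the wall surface.

Vessel geometry in a network is irregular, so wall tractions are expressed
in a frame local to each wall-mesh vertex: radial = inward wall normal,
axial = direction of the *local* near-wall flow (velocity probed one
stencil-spacing inside the wall, projected tangentially), circumferential
completing the right-handed triad.
"""

from __future__ import annotations

import numpy as np

from ..geometry.network import NetworkSpec
from ..geometry.wallmesh import WallMesh
from .fields import LocalFrame
from .sampling import VelocitySampler

STAGNATION_FRACTION = 1e-6


def local_frames(mesh: WallMesh, sampler: VelocitySampler,
                 probe_depth: float = 0.3,
                 spec: NetworkSpec | None = None) -> LocalFrame:
    """Build the per-vertex (e_r, e_s, e_theta) triad from the flow.

    ``probe_depth`` (µm) is how far inside the wall the velocity is probed
    to define the local flow direction (one traction-stencil span).  At
    stagnation vertices (near-zero tangential probe speed) the streamwise
    direction falls back to the owning vessel's centerline tangent when a
    network specification is supplied, otherwise to the area-mean flow
    direction; such vertices are flagged.
    """
    e_r = -mesh.normals  # inward
    probes = mesh.vertices + probe_depth * e_r
    v = sampler.velocity(probes)
    v_t = v - np.einsum("ij,ij->i", v, e_r)[:, None] * e_r
    speed = np.linalg.norm(v_t, axis=1)
    floor = STAGNATION_FRACTION * (speed.max() if speed.size else 0.0)
    stagnant = speed <= floor

    e_s = np.zeros_like(v_t)
    ok = ~stagnant
    e_s[ok] = v_t[ok] / speed[ok, None]

    if stagnant.any():
        fallback = _fallback_directions(mesh, v, stagnant, spec)
        ft = fallback - np.einsum("ij,ij->i", fallback, e_r)[:, None] * e_r
        n = np.linalg.norm(ft, axis=1)
        # a fallback parallel to the normal is hopeless; pick any tangent
        degenerate = n < 1e-12
        if degenerate.any():
            alt = np.cross(e_r[stagnant][degenerate],
                           np.array([0.0, 0.0, 1.0]))
            bad = np.linalg.norm(alt, axis=1) < 1e-6
            alt[bad] = np.cross(e_r[stagnant][degenerate][bad],
                                np.array([0.0, 1.0, 0.0]))
            ft[degenerate] = alt
            n[degenerate] = np.linalg.norm(alt, axis=1)
        e_s[stagnant] = ft / n[:, None]

    e_theta = np.cross(e_r, e_s)
    return LocalFrame(e_r=e_r, e_s=e_s, e_theta=e_theta, stagnant=stagnant)


def _fallback_directions(mesh: WallMesh, v: np.ndarray, stagnant: np.ndarray,
                         spec: NetworkSpec | None) -> np.ndarray:
    out = np.zeros((int(stagnant.sum()), 3))
    idx = np.flatnonzero(stagnant)
    if spec is not None:
        from ..geometry.centerline import tangents as cl_tangents

        labels = mesh.roi_labels[idx]
        for k, (i, lab) in enumerate(zip(idx, labels)):
            vid = _owner_vessel(str(lab), spec)
            vessel = spec.vessel(vid)
            t = cl_tangents(vessel.centerline)
            d = np.linalg.norm(vessel.centerline - mesh.vertices[i], axis=1)
            out[k] = t[np.argmin(d)]
        return out
    mean_v = v[~stagnant].mean(axis=0) if (~stagnant).any() else np.array(
        [1.0, 0.0, 0.0])
    out[:] = mean_v
    return out


def _owner_vessel(label: str, spec: NetworkSpec) -> int:
    if label.startswith("vessel:"):
        return int(label.split(":")[1])
    if ":" in label:  # junction region: use the widest feeder
        jid = int(label.split(":")[1])
        for j in spec.junctions:
            if j.id == jid:
                return max(j.feeders, key=lambda f: spec.vessel(f).diameter)
    return spec.vessels[0].id
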