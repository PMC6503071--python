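"""Wall traction components from one-sided near-wall velocity gradients.

At each wall vertex the velocity is interpolated at two probe points along
the inward normal (at span/2 and span from the wall, with the no-slip zero
at the wall itself) and differentiated with the one-sided second-order
stencil.  The stencil spans at most 0.3 µm so it sits inside the cell-free
layer, and the *plasma* viscosity is therefore used regardless of cell
proximity:

    t_s = mu du_s/dr,   t_r(viscous) = 2 mu du_r/dr,   t_theta = mu du_th/dr

reported in dyne/cm² (1 Pa = 10 dyne/cm²).  Only t_s — the WSS, tau — is
dynamically significant; t_theta and viscous t_r are orders of magnitude
smaller and carried for the hierarchy diagnostics.
"""

from __future__ import annotations

import numpy as np

from ..geometry.wallmesh import WallMesh
from .fields import PA_TO_DYNE_CM2, LocalFrame, WSSField
from .sampling import VelocitySampler

UM = 1e-6
MAX_STENCIL_SPAN = 0.3  # µm; must stay within the cell-free layer


def wall_shear_stress(sampler: VelocitySampler, mesh: WallMesh,
                      frames: LocalFrame, stencil_span: float = MAX_STENCIL_SPAN,
                      viscosity: float = 0.001,
                      pressure_sampler=None,
                      distance_fn=None,
                      kind: str = "instantaneous",
                      bc_kind: str | None = None) -> WSSField:
    """Traction components at every wall vertex (dyne/cm²).

    ``viscosity`` is the plasma viscosity in Pa s.  If ``distance_fn`` is
    given (or the mesh carries one), probe points that leave the lumen get a
    halved span, and vertices whose probes cannot be placed are flagged
    invalid.
    """
    if stencil_span > MAX_STENCIL_SPAN + 1e-12:
        raise ValueError(
            f"stencil span {stencil_span} µm exceeds the {MAX_STENCIL_SPAN} "
            "µm cell-free-layer bound")
    dist = distance_fn if distance_fn is not None else mesh.distance_fn
    n = mesh.n_vertices
    span = np.full(n, float(stencil_span))
    valid = np.ones(n, dtype=bool)
    if dist is not None:
        for _ in range(3):
            probes = mesh.vertices + span[:, None] * frames.e_r
            outside = dist(probes) > 0
            if not outside.any():
                break
            span[outside] *= 0.5
        bad = span < stencil_span / 4.0
        valid[bad] = False

    delta = span / 2.0
    p1 = mesh.vertices + delta[:, None] * frames.e_r
    p2 = mesh.vertices + span[:, None] * frames.e_r
    u0 = sampler.velocity(mesh.vertices)  # ~0 by no-slip for flow fields
    u1 = sampler.velocity(p1)
    u2 = sampler.velocity(p2)

    def ddr(direction: np.ndarray) -> np.ndarray:
        f0 = np.einsum("ij,ij->i", u0, direction)
        f1 = np.einsum("ij,ij->i", u1, direction)
        f2 = np.einsum("ij,ij->i", u2, direction)
        return (-3.0 * f0 + 4.0 * f1 - f2) / (2.0 * delta * UM)

    t_s = viscosity * ddr(frames.e_s) * PA_TO_DYNE_CM2
    t_th = viscosity * ddr(frames.e_theta) * PA_TO_DYNE_CM2
    t_r = 2.0 * viscosity * ddr(frames.e_r) * PA_TO_DYNE_CM2
    p_wall = None
    if pressure_sampler is not None:
        p_wall = pressure_sampler.sample(p1) * PA_TO_DYNE_CM2
    return WSSField(t_s=t_s, t_theta=t_th, t_r_visc=t_r, p_wall=p_wall,
                    valid=valid, kind=kind, bc_kind=bc_kind)
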