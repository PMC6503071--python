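"""Per-wall-vertex field containers for tractions and their gradients."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PA_TO_DYNE_CM2 = 10.0


@dataclass
class LocalFrame:
    """Orthonormal local cylindrical triad at each wall vertex.

    e_r: inward wall normal (local radial direction, pointing into the
    lumen); e_s: local streamwise tangent (along the near-wall flow);
    e_theta = e_r x e_s (circumferential).  ``stagnant`` flags vertices where
    the near-wall tangential velocity vanished and a geometric fallback
    direction was used.
    """

    e_r: np.ndarray
    e_s: np.ndarray
    e_theta: np.ndarray
    stagnant: np.ndarray

    def check_orthonormal(self, tol: float = 1e-10) -> None:
        for a in (self.e_r, self.e_s, self.e_theta):
            if np.max(np.abs(np.linalg.norm(a, axis=1) - 1.0)) > tol:
                raise ValueError("frame vectors are not unit length")
        for a, b in ((self.e_r, self.e_s), (self.e_r, self.e_theta),
                     (self.e_s, self.e_theta)):
            if np.max(np.abs(np.einsum("ij,ij->i", a, b))) > tol:
                raise ValueError("frame vectors are not orthogonal")


@dataclass
class WSSField:
    """Wall-traction components per vertex, in dyne/cm².

    ``t_s`` is the streamwise (axial) component — the WSS proper, denoted
    tau; ``t_theta`` the circumferential component; ``t_r_visc`` the viscous
    part of the radial component (the full radial traction also carries
    -p, stored separately in ``p_wall`` when available).
    """

    t_s: np.ndarray
    t_theta: np.ndarray
    t_r_visc: np.ndarray
    p_wall: np.ndarray | None = None
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    kind: str = "instantaneous"   # or "time-averaged"
    bc_kind: str | None = None    # run metadata for ratio guards

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.t_s), dtype=bool)

    @property
    def tau(self) -> np.ndarray:
        return self.t_s


@dataclass
class WSSGField:
    """Surface gradient of the WSS per vertex, in dyne/cm²/µm."""

    grad_s: np.ndarray
    grad_theta: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.grad_s), dtype=bool)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.grad_s, self.grad_theta)
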