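"""Immersed-boundary unsteady-Stokes flow solver on a staggered grid."""

from .grid import EulerianGrid, classify_grid
from .ibm import interpolate_velocity, peskin4, spread_forces
from .stepper import BoundaryCondition, FlowState, StokesSolver
from .viscosity import MU_INTERIOR, MU_PLASMA, cell_indicator, viscosity_field

__all__ = [
    "BoundaryCondition", "EulerianGrid", "FlowState", "MU_INTERIOR",
    "MU_PLASMA", "StokesSolver", "cell_indicator", "classify_grid",
    "interpolate_velocity", "peskin4", "run_simulation", "spread_forces",
    "viscosity_field",
]


def __getattr__(name):
    if name in ("run_simulation", "SimulationConfig", "RunResult"):
        from . import simulation

        return getattr(simulation, name)
    raise AttributeError(name)
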