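"""Random non-overlapping cell seeding into a vessel lumen at a target
feed hematocrit (tube hematocrit = cell volume fraction of the lumen)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ..geometry.sdf import DistanceField
from .cell import CellMembrane

WALL_CLEARANCE = 0.3    # µm kept between any membrane vertex and the wall
PAIR_CLEARANCE = 0.3    # µm kept between membranes of different cells


@dataclass
class Placement:
    """Rigid placement of the template cell: x = rotation @ x_ref + position."""

    position: np.ndarray  # (3,), µm
    rotation: np.ndarray  # (3, 3)

    def apply(self, cell: CellMembrane) -> np.ndarray:
        ref = cell.vertices - cell.vertices.mean(axis=0)
        return ref @ self.rotation.T + self.position


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def lumen_volume(distance: DistanceField,
                 bounds: tuple[np.ndarray, np.ndarray] | None = None) -> float:
    """Lumen volume (µm³) by voxel counting on the sampled field,
    optionally restricted to a bounding box (the simulation box)."""
    mask = distance.values < 0
    if bounds is not None:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
        for ax in range(3):
            coords = distance.origin[ax] + distance.h * np.arange(
                distance.shape[ax])
            sel = (coords >= lo[ax]) & (coords <= hi[ax])
            mask = mask & np.expand_dims(
                sel, tuple(a for a in range(3) if a != ax))
    return float(mask.sum()) * distance.h**3


def seed_cells(distance: DistanceField, hematocrit: float, seed: int,
               cell: CellMembrane | None = None,
               max_attempts_per_cell: int = 1000,
               bounds: tuple[np.ndarray, np.ndarray] | None = None
               ) -> list[Placement]:
    """Place cells with random position/orientation, rejecting overlaps.

    The requested count is ``round(hematocrit * lumen_volume / V_cell)``.
    Every membrane vertex keeps a clearance from the wall and from every
    other cell.  If the count cannot be reached after bounded retries the
    achieved (smaller) placement list is returned; the achieved hematocrit is
    ``len(placements) * V_cell / lumen_volume``.
    """
    if not (0.0 <= hematocrit <= 0.45):
        raise ValueError("hematocrit must lie in [0, 0.45]")
    if cell is None:
        from .cell import make_biconcave

        cell = make_biconcave(n_refine=3)
    rng = np.random.default_rng(seed)
    V = lumen_volume(distance, bounds=bounds)
    n_target = int(round(hematocrit * V / cell.reference_volume))
    if n_target == 0:
        return []

    lo = distance.origin.copy()
    hi = distance.origin + distance.h * (np.asarray(distance.shape) - 1)
    if bounds is not None:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    ref = cell.vertices - cell.vertices.mean(axis=0)

    best: list[Placement] = []
    for _restart in range(20):
        placements: list[Placement] = []
        trees: list[cKDTree] = []
        for _ in range(n_target):
            placed = False
            for _attempt in range(max_attempts_per_cell):
                pos = rng.uniform(lo, hi)
                if distance.sample(pos[None])[0] > -1.0:
                    continue
                rot = _random_rotation(rng)
                verts = ref @ rot.T + pos
                if np.max(distance.sample(verts)) > -WALL_CLEARANCE:
                    continue
                ok = True
                for tree in trees:
                    d, _ = tree.query(verts, k=1)
                    if d.min() <= PAIR_CLEARANCE:
                        ok = False
                        break
                if not ok:
                    continue
                placements.append(Placement(position=pos, rotation=rot))
                trees.append(cKDTree(verts))
                placed = True
                break
            if not placed:
                break
        if len(placements) > len(best):
            best = placements
        if len(best) == n_target:
            break
    return best
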