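"""Circular 2-D occupancy lattice and division-space search.

A culture well is discretized into square voxels of one cell diameter; the
in-well region is a circular mask on an integer lattice.  Daughter-cell
placement scans the parent's neighbourhood (Von Neumann or Moore) outwards
up to third-order neighbours and picks uniformly among the empty voxels of
the nearest non-empty order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "EMPTY",
    "OUTSIDE",
    "MAX_ORDER",
    "NeighbourhoodSpec",
    "Grid",
    "grid_diameter_voxels",
    "ring_offsets",
    "free_spaces",
    "place_daughter",
]

EMPTY = -1       # in-well voxel with no cell
OUTSIDE = -2     # voxel outside the circular well mask
MAX_ORDER = 3    # division-space search range ("up to third-order neighbours")

VON_NEUMANN = "von_neumann"
MOORE = "moore"


@dataclass(frozen=True)
class NeighbourhoodSpec:
    """Neighbourhood kind and search order.

    ``von_neumann`` order k covers Manhattan distance exactly k;
    ``moore`` order k covers Chebyshev distance exactly k (ring k).
    """

    kind: str
    order: int = MAX_ORDER

    def __post_init__(self) -> None:
        if self.kind not in (VON_NEUMANN, MOORE):
            raise ValueError(f"kind must be 'von_neumann' or 'moore', got {self.kind!r}")
        if self.order not in (1, 2, 3):
            raise ValueError(f"order must be 1, 2 or 3, got {self.order}")


@lru_cache(maxsize=None)
def ring_offsets(kind: str, order: int) -> tuple[tuple[int, int], ...]:
    """Lattice offsets at exactly the given neighbourhood order."""
    if kind == MOORE:
        ring = [
            (dr, dc)
            for dr in range(-order, order + 1)
            for dc in range(-order, order + 1)
            if max(abs(dr), abs(dc)) == order
        ]
    elif kind == VON_NEUMANN:
        ring = [
            (dr, dc)
            for dr in range(-order, order + 1)
            for dc in range(-order, order + 1)
            if abs(dr) + abs(dc) == order
        ]
    else:
        raise ValueError(f"unknown neighbourhood kind {kind!r}")
    return tuple(ring)


def grid_diameter_voxels(well_diameter_mm: float, voxel_edge_um: float) -> int:
    """Well diameter expressed in voxels (rounded to nearest integer).

    A 15.6 mm well at 9.6 um voxels gives 1625; a 34.8 mm well at 12 um
    voxels gives 2900.
    """
    if well_diameter_mm <= 0.0 or voxel_edge_um <= 0.0:
        raise ValueError("well diameter and voxel edge must be positive")
    return int(round(well_diameter_mm * 1000.0 / voxel_edge_um))


class Grid:
    """Circular occupancy lattice.

    The well of diameter D voxels is embedded in a D x D array; a voxel
    belongs to the well if its centre lies within the well radius D/2 of the
    array centre (centre convention, so voxel counts are reproducible).
    ``occupancy`` holds the owning cell slot index, ``EMPTY`` or ``OUTSIDE``.
    """

    def __init__(self, diameter_voxels: int):
        if diameter_voxels < 1:
            raise ValueError("grid diameter must be at least 1 voxel")
        self.diameter = int(diameter_voxels)
        d = self.diameter
        centre = (d - 1) / 2.0
        radius = d / 2.0
        ii, jj = np.ogrid[0:d, 0:d]
        self.mask = (ii - centre) ** 2 + (jj - centre) ** 2 <= radius**2
        self.occupancy = np.where(self.mask, EMPTY, OUTSIDE).astype(np.int64)
        self.n_sites = int(self.mask.sum())
        # flat coordinates of in-well voxels, for uniform seeding
        rows, cols = np.nonzero(self.mask)
        self._site_rows = rows.astype(np.int32)
        self._site_cols = cols.astype(np.int32)

    @classmethod
    def from_well(cls, well_diameter_mm: float, voxel_edge_um: float) -> "Grid":
        return cls(grid_diameter_voxels(well_diameter_mm, voxel_edge_um))

    def in_mask(self, r: int, c: int) -> bool:
        return 0 <= r < self.diameter and 0 <= c < self.diameter and bool(self.mask[r, c])

    def is_empty(self, r: int, c: int) -> bool:
        return (
            0 <= r < self.diameter
            and 0 <= c < self.diameter
            and self.occupancy[r, c] == EMPTY
        )

    def n_occupied(self) -> int:
        return int((self.occupancy >= 0).sum())

    def random_free_sites(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n distinct uniformly random empty in-well positions, shape (n, 2)."""
        free = self.occupancy[self._site_rows, self._site_cols] == EMPTY
        rows = self._site_rows[free]
        cols = self._site_cols[free]
        if n > rows.size:
            raise ValueError(f"requested {n} sites but only {rows.size} free")
        pick = rng.choice(rows.size, size=n, replace=False)
        return np.stack([rows[pick], cols[pick]], axis=1)


def free_spaces(
    pos: tuple[int, int], grid: Grid, spec: NeighbourhoodSpec
) -> list[list[tuple[int, int]]]:
    """Empty in-well positions around ``pos``, grouped by neighbourhood order.

    Returns one list per order 1..spec.order, nearest first; within a group
    the order follows the fixed offset enumeration (deterministic).
    """
    r, c = pos
    if not grid.in_mask(r, c):
        raise ValueError(f"position {pos} is outside the well mask")
    occ = grid.occupancy
    d = grid.diameter
    groups: list[list[tuple[int, int]]] = []
    for order in range(1, spec.order + 1):
        ring = []
        for dr, dc in ring_offsets(spec.kind, order):
            rr, cc = r + dr, c + dc
            if 0 <= rr < d and 0 <= cc < d and occ[rr, cc] == EMPTY:
                ring.append((rr, cc))
        groups.append(ring)
    return groups


def place_daughter(
    parent_pos: tuple[int, int],
    grid: Grid,
    spec: NeighbourhoodSpec,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Choose a voxel for a daughter cell, or None if no space within range.

    Positions closest to the parent are occupied first: the choice is
    uniform among the empty voxels of the lowest non-empty order.
    """
    for group in free_spaces(parent_pos, grid, spec):
        if group:
            return group[int(rng.integers(len(group)))]
    return None
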