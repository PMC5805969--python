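"""Cell-cycle engine: per-cell timers, phases, lag, division and quiescence.

Each virtual cell occupies one voxel and carries an individual cycle clock
and cycle duration (drawn from a normal distribution, SD 5 % of the mean,
truncated at +-3 SD).  The clock maps onto the four cycling phases G1, S,
G2, M by cumulative phase fractions of the cycle; when the clock reaches
the cycle duration the cell attempts to divide into a free neighbouring
voxel, alternating Moore and Von Neumann neighbourhoods between attempts so
that colonies grow circularly.  A cell with no free voxel within
third-order neighbours enters the reversible quiescent state G0 (clock
frozen) and resumes cycling when a neighbouring voxel is vacated.  A lag
phase (default 2 h) freezes all clocks at the start of a run, emulating
attachment after seeding; treatment can still kill cells during the lag.

The population is stored as flat numpy arrays (struct-of-arrays) indexed by
cell slot, with the lattice occupancy grid holding slot indices, so that
per-step bookkeeping is vectorized and only division events run in a Python
loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .lattice import EMPTY, MAX_ORDER, MOORE, VON_NEUMANN, Grid, ring_offsets
from .survival import PHASES

__all__ = [
    "VIABLE",
    "DOOMED",
    "SENESCENT",
    "GIANT",
    "CycleConfig",
    "CellPopulation",
    "assign_phase",
    "seed_population",
    "step",
]

# fate codes
VIABLE = 0
DOOMED = 1      # scheduled to die at death_time; keeps proliferating until then
SENESCENT = 2   # permanently viable, never divides, never dies in-simulation
GIANT = 3       # product of mitotic catastrophe; no daughters; dies at death_time

_FATE_NAMES = {VIABLE: "viable", DOOMED: "doomed", SENESCENT: "senescent", GIANT: "giant"}


@dataclass(frozen=True)
class CycleConfig:
    """Cell-cycle timing parameters.

    Defaults are the calibrated HCT116 values: 19.5 h mean doubling time
    with 5 % SD, 2 h lag, and a cycle split of 40 % G1, 35 % S, 20 % G2,
    5 % M (the G2/M split of the flow-cytometry doublet peak).
    """

    mean_doubling_time: float = 19.5
    rate_sd_fraction: float = 0.05
    phase_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"G1": 0.40, "S": 0.35, "G2": 0.20, "M": 0.05}
    )
    lag_hours: float = 2.0

    def __post_init__(self) -> None:
        if self.mean_doubling_time <= 0.0:
            raise ValueError("mean_doubling_time must be positive")
        if self.rate_sd_fraction < 0.0:
            raise ValueError("rate_sd_fraction must be >= 0")
        if self.lag_hours < 0.0:
            raise ValueError("lag_hours must be >= 0")
        missing = [p for p in PHASES if p not in self.phase_fractions]
        if missing:
            raise ValueError(f"phase_fractions missing {missing}")
        total = sum(self.phase_fractions[p] for p in PHASES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phase fractions must sum to 1, got {total}")
        if any(self.phase_fractions[p] < 0.0 for p in PHASES):
            raise ValueError("phase fractions must be non-negative")
        fr = [self.phase_fractions[p] for p in PHASES]
        object.__setattr__(
            self, "_boundaries", np.cumsum(fr)[:-1]  # G1|S, S|G2, G2|M cuts
        )

    @property
    def boundaries(self) -> np.ndarray:
        """Phase boundaries as fractions of the cycle (cuts G1|S, S|G2, G2|M)."""
        return self._boundaries

    @property
    def duration_sd(self) -> float:
        return self.rate_sd_fraction * self.mean_doubling_time


def assign_phase(cycle_clock: float, cycle_duration: float, config: CycleConfig) -> str:
    """Cycling phase for a clock position, half-open intervals [start, end).

    A clock at exactly the cycle duration (a pending division) reads as M.
    """
    if not (0.0 <= cycle_clock <= cycle_duration):
        raise ValueError(
            f"cycle_clock {cycle_clock} outside [0, {cycle_duration}]"
        )
    x = cycle_clock / cycle_duration
    idx = int(np.searchsorted(config.boundaries, x, side="right"))
    return PHASES[idx]


class CellPopulation:
    """Array-backed population of lattice cells.

    Parameters
    ----------
    grid : Grid
        Occupancy lattice; the population registers cell slots in it.
    config : CycleConfig
        Cycle timing parameters shared by all cells.
    rng : numpy.random.Generator
        Source of all randomness (division-site choice, durations, update
        order, mitotic-fate draws).
    dynamics : object, optional
        Delayed-death parameters (attributes ``p_mitotic_cat`` and
        ``p_senescence``) consulted when a doomed cell completes M-phase.
        With ``None`` doomed cells always divide normally.
    """

    _INITIAL_CAPACITY = 1024

    def __init__(self, grid: Grid, config: CycleConfig, rng: np.random.Generator,
                 dynamics=None):
        self.grid = grid
        self.config = config
        self.rng = rng
        self.dynamics = dynamics
        self.time = 0.0
        self.created = 0
        self.removed = 0
        cap = self._INITIAL_CAPACITY
        self._n = 0
        self.row = np.zeros(cap, dtype=np.int32)
        self.col = np.zeros(cap, dtype=np.int32)
        self.clock = np.zeros(cap, dtype=np.float64)
        self.duration = np.ones(cap, dtype=np.float64)
        self.fate = np.zeros(cap, dtype=np.int8)
        self.death_time = np.full(cap, np.inf, dtype=np.float64)
        self.in_g0 = np.zeros(cap, dtype=bool)
        self.use_moore = np.zeros(cap, dtype=bool)
        self.giant_size = np.zeros(cap, dtype=np.int32)
        self.alive = np.zeros(cap, dtype=bool)

    # ---------------------------------------------------------------- admin

    def _grow(self, need: int) -> None:
        cap = len(self.row)
        new_cap = cap
        while new_cap < need:
            new_cap *= 2
        for name in ("row", "col", "clock", "duration", "fate", "death_time",
                     "in_g0", "use_moore", "giant_size", "alive"):
            old = getattr(self, name)
            fresh = np.zeros(new_cap, dtype=old.dtype)
            if name == "death_time":
                fresh[:] = np.inf
            elif name == "duration":
                fresh[:] = 1.0
            fresh[:cap] = old
            setattr(self, name, fresh)

    def draw_durations(self, n: int) -> np.ndarray:
        """Cycle durations ~ Normal(mean, sd) truncated at +-3 sd (and > 0)."""
        mean = self.config.mean_doubling_time
        sd = self.config.duration_sd
        if sd == 0.0:
            return np.full(n, mean)
        out = self.rng.normal(mean, sd, size=n)
        bad = (np.abs(out - mean) > 3.0 * sd) | (out <= 0.0)
        while bad.any():
            out[bad] = self.rng.normal(mean, sd, size=int(bad.sum()))
            bad = (np.abs(out - mean) > 3.0 * sd) | (out <= 0.0)
        return out

    def _draw_duration(self) -> float:
        mean = self.config.mean_doubling_time
        sd = self.config.duration_sd
        if sd == 0.0:
            return mean
        normal = self.rng.normal
        while True:
            x = normal(mean, sd)
            if abs(x - mean) <= 3.0 * sd and x > 0.0:
                return float(x)

    # ---------------------------------------------------------------- seeding

    def seed(self, n: int, positions=None) -> None:
        """Place n cells at distinct uniformly random in-well positions
        (or at explicit ``positions``, an (n, 2) array of row/col).

        Clocks are drawn uniformly within each cell's cycle so that the
        initial phase occupancies match the configured phase fractions.
        """
        if n == 0:
            return
        if n > self.grid.n_sites:
            raise ValueError(
                f"cannot seed {n} cells on a grid of {self.grid.n_sites} voxels"
            )
        if positions is None:
            pos = self.grid.random_free_sites(n, self.rng)
        else:
            pos = np.asarray(positions, dtype=np.int32)
            if pos.shape != (n, 2):
                raise ValueError("positions must have shape (n, 2)")
            for r, c in pos:
                if not self.grid.is_empty(int(r), int(c)):
                    raise ValueError(f"position ({r}, {c}) not free in-well")
        if self._n + n > len(self.row):
            self._grow(self._n + n)
        lo, hi = self._n, self._n + n
        slots = np.arange(lo, hi)
        self.row[lo:hi] = pos[:, 0]
        self.col[lo:hi] = pos[:, 1]
        dur = self.draw_durations(n)
        self.duration[lo:hi] = dur
        self.clock[lo:hi] = self.rng.uniform(0.0, dur)
        self.fate[lo:hi] = VIABLE
        self.death_time[lo:hi] = np.inf
        self.in_g0[lo:hi] = False
        self.use_moore[lo:hi] = False
        self.giant_size[lo:hi] = 0
        self.alive[lo:hi] = True
        self.grid.occupancy[pos[:, 0], pos[:, 1]] = slots
        self._n = hi
        self.created += n

    # ---------------------------------------------------------------- removal

    def remove_cells(self, slots: np.ndarray) -> None:
        """Remove cells from the lattice and wake nearby quiescent cells.

        Vacancies are the only way space frees up, so waking quiescent cells
        within Chebyshev radius 3 of each vacated voxel is equivalent to
        re-checking every G0 cell each step.
        """
        slots = np.asarray(slots)
        if slots.size == 0:
            return
        occ = self.grid.occupancy
        d = self.grid.diameter
        rows = self.row[slots]
        cols = self.col[slots]
        occ[rows, cols] = EMPTY
        self.alive[slots] = False
        self.removed += int(slots.size)
        in_g0 = self.in_g0
        for r, c in zip(rows.tolist(), cols.tolist()):
            window = occ[max(r - MAX_ORDER, 0): r + MAX_ORDER + 1,
                         max(c - MAX_ORDER, 0): c + MAX_ORDER + 1]
            ids = window[window >= 0]
            if ids.size:
                in_g0[ids] = False

    # ---------------------------------------------------------------- stepping

    def step(self, dt: float) -> None:
        """Advance the population by dt hours."""
        if dt <= 0.0:
            raise ValueError("dt must be positive")
        prev = self.time
        now = prev + dt
        self.time = now
        n = self._n
        alive = self.alive[:n]

        # scheduled (delayed) deaths
        due = alive & (self.death_time[:n] <= now)
        if due.any():
            self.remove_cells(np.flatnonzero(due))
            alive = self.alive[:n]

        # clock advance; the seeding lag freezes clocks at the start of a run
        eff = min(dt, max(0.0, now - self.config.lag_hours))
        if eff > 0.0:
            advancing = alive & ~self.in_g0[:n] & (self.fate[:n] != SENESCENT)
            self.clock[:n][advancing] += eff

        ripe = alive & ~self.in_g0[:n] & (self.clock[:n] >= self.duration[:n] - 1e-12)

        # giant cells: attempted division only grows their size counter
        giants = ripe & (self.fate[:n] == GIANT)
        if giants.any():
            self.giant_size[:n][giants] += 1
            self.clock[:n][giants] = 0.0

        dividers = np.flatnonzero(ripe & ((self.fate[:n] == VIABLE) | (self.fate[:n] == DOOMED)))
        if dividers.size == 0:
            return
        # seeded random processing order avoids spatial bias in space contests
        order = self.rng.permutation(dividers)
        attempt = self._attempt_division
        for i in order.tolist():
            attempt(i)

    def _attempt_division(self, i: int) -> None:
        rng = self.rng
        fate = self.fate
        if fate[i] == DOOMED and self.dynamics is not None:
            dyn = self.dynamics
            if rng.random() < dyn.p_mitotic_cat:
                # mitotic catastrophe at the end of M-phase
                if rng.random() < dyn.p_senescence:
                    fate[i] = SENESCENT
                    self.death_time[i] = np.inf
                    self.in_g0[i] = False
                else:
                    fate[i] = GIANT
                    self.giant_size[i] = 1
                    self.clock[i] = 0.0
                return
        # alternate neighbourhood kind at every division attempt
        self.use_moore[i] = not self.use_moore[i]
        moore = bool(self.use_moore[i])
        occ = self.grid.occupancy
        d = self.grid.diameter
        r = int(self.row[i])
        c = int(self.col[i])
        site = None
        kind = MOORE if moore else VON_NEUMANN
        for order in range(1, MAX_ORDER + 1):
            ring = []
            for dr, dc in ring_offsets(kind, order):
                rr, cc = r + dr, c + dc
                if 0 <= rr < d and 0 <= cc < d and occ[rr, cc] == EMPTY:
                    ring.append((rr, cc))
            if ring:
                site = ring[int(rng.integers(len(ring)))]
                break
        if site is None:
            # no space with this neighbourhood; clamp the clock at division
            self.clock[i] = self.duration[i]
            if moore:
                self.in_g0[i] = True
            else:
                # a Von Neumann failure may still have Moore-reachable space;
                # stay pending (re-attempt next step with the toggled kind)
                # and only go quiescent if no space exists at all
                if not self._any_moore_space(r, c):
                    self.in_g0[i] = True
            return
        # divide: parent and daughter both restart in G1 with clock 0
        j = self._n
        if j >= len(self.row):
            self._grow(j + 1)
            fate = self.fate  # arrays were reallocated
        rr, cc = site
        self.row[j] = rr
        self.col[j] = cc
        self.clock[j] = 0.0
        self.duration[j] = self._draw_duration()
        if fate[i] == DOOMED:
            # descendants of a doomed cell die with their ancestor
            fate[j] = DOOMED
            self.death_time[j] = self.death_time[i]
        else:
            fate[j] = VIABLE
            self.death_time[j] = np.inf
        self.in_g0[j] = False
        self.use_moore[j] = self.use_moore[i]
        self.giant_size[j] = 0
        self.alive[j] = True
        occ[rr, cc] = j
        self._n = j + 1
        self.created += 1
        self.clock[i] = 0.0

    def _any_moore_space(self, r: int, c: int) -> bool:
        occ = self.grid.occupancy
        d = self.grid.diameter
        window = occ[max(r - MAX_ORDER, 0): r + MAX_ORDER + 1,
                     max(c - MAX_ORDER, 0): c + MAX_ORDER + 1]
        return bool((window == EMPTY).any())

    # ---------------------------------------------------------------- queries

    @property
    def n_alive(self) -> int:
        return int(self.alive[: self._n].sum())

    def phase_indices(self, slots: np.ndarray) -> np.ndarray:
        """Phase index (0..3 for G1,S,G2,M) of the given cell slots."""
        x = self.clock[slots] / self.duration[slots]
        return np.searchsorted(self.config.boundaries, x, side="right")

    def counts(self) -> dict[str, int]:
        """Compartment census: cycling viable by phase, G0, doomed, senescent,
        giant, and the total number of cells present."""
        n = self._n
        alive = self.alive[:n]
        fate = self.fate[:n]
        viable = alive & (fate == VIABLE)
        quiescent = viable & self.in_g0[:n]
        cycling = np.flatnonzero(viable & ~self.in_g0[:n])
        phase_counts = np.bincount(self.phase_indices(cycling), minlength=4)
        out = {p: int(phase_counts[k]) for k, p in enumerate(PHASES)}
        out["G0"] = int(quiescent.sum())
        out["doomed"] = int((alive & (fate == DOOMED)).sum())
        out["senescent"] = int((alive & (fate == SENESCENT)).sum())
        out["giant"] = int((alive & (fate == GIANT)).sum())
        out["total"] = int(alive.sum())
        return out

    def check_invariants(self) -> None:
        """Assert conservation and the occupancy bijection (used by tests)."""
        n = self._n
        alive = np.flatnonzero(self.alive[:n])
        assert self.created == alive.size + self.removed, "cell conservation violated"
        occ = self.grid.occupancy
        occupied = int((occ >= 0).sum())
        assert occupied == alive.size, "occupancy count != alive count"
        back = occ[self.row[alive], self.col[alive]]
        assert np.array_equal(np.sort(back), alive), "occupancy bijection violated"


def seed_population(
    n: int,
    grid: Grid,
    config: CycleConfig,
    rng: np.random.Generator,
    dynamics=None,
) -> CellPopulation:
    """Create and seed a population of n cells on the grid."""
    pop = CellPopulation(grid, config, rng, dynamics=dynamics)
    pop.seed(n)
    return pop


def step(population: CellPopulation, dt: float) -> CellPopulation:
    """Advance a population by dt hours (thin wrapper over the method)."""
    population.step(dt)
    return population
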