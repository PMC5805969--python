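"""Treatment delivery: the per-cell live/die decision tree and scheduling.

A treatment fraction carries a radiation dose, an optional heating profile,
or both.  Radiation is delivered homogeneously: every non-senescent cell
draws one uniform random number N and is compared against the relevant
surviving fractions,

* heat only:      N > S_HT            -> removed instantly,
* radiation only: N > S_RT(phase)     -> doomed, dies after a random delay,
* combined:       N > S_HT            -> removed instantly,
                  S_HT >= N > S_RTHT  -> doomed, dies after a random delay.

Death delays are exponential with rate ``k_delay`` (clonogenic survival
measures the long-run endpoint; the delay reproduces the observed slow
decline of irradiated cultures).  Until its death time a doomed cell keeps
cycling; every daughter inherits the ancestor's absolute death time.  At
the end of M-phase a doomed cell may instead undergo mitotic catastrophe
(probability ``p_mitoticCat``): it becomes a giant cell, or with
probability ``p_senescence`` a permanently viable senescent non-divider.

Phase-dependent radiosensitivity weights the radiation survival term by the
cell's current phase exponent; heat kill is phase-independent.  An
"instantaneous" delivery mode removes cells that fail the draw immediately
(no delay), provided for comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .population import DOOMED, GIANT, SENESCENT, VIABLE, CellPopulation
from .survival import (
    AlphaRParams,
    PhaseSensitivity,
    ThermalProfile,
    alphar_survival,
    ht_survival,
)

__all__ = [
    "DeathDynamics",
    "Fraction",
    "TreatmentSchedule",
    "sample_death_delay",
    "sample_mitotic_fate",
    "mitotic_fate",
    "apply_fraction",
    "instantaneous_mode",
]


@dataclass(frozen=True)
class DeathDynamics:
    """Delayed-death parameters.

    Defaults are the HCT116 calibration: k_delay = 0.009 h^-1 (mean delay
    ~111 h), p_mitoticCat = 0.2, p_senescence = 0.05.
    """

    k_delay: float = 0.009
    p_mitotic_cat: float = 0.2
    p_senescence: float = 0.05

    def __post_init__(self) -> None:
        if self.k_delay <= 0.0:
            raise ValueError("k_delay must be positive")
        for name in ("p_mitotic_cat", "p_senescence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class Fraction:
    """One treatment fraction.

    ``rt_survival``/``combined_survival`` optionally pin the computed
    surviving fractions to explicit values (used e.g. to re-run a growth
    curve at the confidence bounds of a measured surviving fraction).
    """

    time_h: float
    dose_gy: float = 0.0
    thermal: ThermalProfile | None = None
    rt_survival: float | None = None
    ht_survival: float | None = None

    def __post_init__(self) -> None:
        if self.dose_gy < 0.0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered list of fractions with non-decreasing times."""

    fractions: tuple[Fraction, ...] = ()

    def __init__(self, fractions: Sequence[Fraction] = ()):
        fr = tuple(fractions)
        times = [f.time_h for f in fr]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("fraction times must be non-decreasing")
        object.__setattr__(self, "fractions", fr)

    def __len__(self) -> int:
        return len(self.fractions)

    def __iter__(self):
        return iter(self.fractions)

    @property
    def end_time(self) -> float:
        return self.fractions[-1].time_h if self.fractions else 0.0

    @classmethod
    def daily(
        cls,
        n_fractions: int,
        dose_gy: float,
        start_h: float = 0.0,
        interval_h: float = 24.0,
        thermal: ThermalProfile | None = None,
    ) -> "TreatmentSchedule":
        """n equal fractions every ``interval_h`` hours (default every 24 h)."""
        return cls(
            [
                Fraction(start_h + k * interval_h, dose_gy, thermal)
                for k in range(n_fractions)
            ]
        )

    @classmethod
    def weekday(
        cls, n_fractions: int, dose_gy: float, start_h: float = 0.0
    ) -> "TreatmentSchedule":
        """n daily fractions delivered 5 days a week, Monday to Friday.

        The first fraction falls on a Monday; weekends (2-day gaps) are
        skipped, so 30 fractions span 6 calendar weeks.
        """
        fr = []
        day = 0
        for _ in range(n_fractions):
            fr.append(Fraction(start_h + day * 24.0, dose_gy))
            day += 1
            if day % 7 == 5:  # after Friday, jump to next Monday
                day += 2
        return cls(fr)

    def with_thermal_at(
        self, day: float, thermal: ThermalProfile
    ) -> "TreatmentSchedule":
        """Attach a heating profile to the fraction closest to ``day`` days."""
        if not self.fractions:
            raise ValueError("empty schedule")
        target = day * 24.0
        idx = min(
            range(len(self.fractions)),
            key=lambda k: abs(self.fractions[k].time_h - target),
        )
        fr = list(self.fractions)
        fr[idx] = replace(fr[idx], thermal=thermal)
        return TreatmentSchedule(fr)


def sample_death_delay(dynamics: DeathDynamics, rng: np.random.Generator, size=None):
    """Delay between irradiation and death: Exponential with rate k_delay."""
    return rng.exponential(1.0 / dynamics.k_delay, size=size)


def sample_mitotic_fate(dynamics: DeathDynamics, rng: np.random.Generator) -> str:
    """Outcome of a doomed cell completing M-phase.

    Returns ``"divide"`` (probability 1 - p_mitoticCat), ``"senescent"``
    (p_mitoticCat * p_senescence) or ``"giant"`` (the remainder).
    """
    if rng.random() < dynamics.p_mitotic_cat:
        if rng.random() < dynamics.p_senescence:
            return "senescent"
        return "giant"
    return "divide"


def mitotic_fate(
    population: CellPopulation, slot: int, dynamics: DeathDynamics,
    rng: np.random.Generator,
) -> str:
    """Draw and apply the M-phase exit fate of a doomed cell.

    Raises ``ValueError`` if the cell is not doomed.
    """
    if population.fate[slot] != DOOMED:
        raise ValueError(f"cell {slot} is not doomed (fate={population.fate[slot]})")
    outcome = sample_mitotic_fate(dynamics, rng)
    if outcome == "senescent":
        population.fate[slot] = SENESCENT
        population.death_time[slot] = np.inf
        population.in_g0[slot] = False
    elif outcome == "giant":
        population.fate[slot] = GIANT
        population.giant_size[slot] = 1
        population.clock[slot] = 0.0
    return outcome


def _fraction_survivals(
    fraction: Fraction, cell_line, phase_fractions,
) -> tuple[float, float, np.ndarray | None]:
    """(S_HT, S_lower-scalar-part, gamma array) for a fraction.

    S_HT is the instant-kill threshold (1.0 without heat).  The delayed-kill
    threshold of a cell in phase p is ``S_HT * s_rt_component ** gamma_p``
    where ``s_rt_component`` is the radiation factor (sensitized under
    combined treatment).  Returns ``gamma`` as the (G1, S, G2, M, G0)
    exponent array, or None when no radiation is delivered.
    """
    t43 = fraction.thermal.cem43() if fraction.thermal is not None else 0.0
    if fraction.ht_survival is not None:
        s_ht = float(fraction.ht_survival)
    elif t43 > 0.0:
        s_ht = ht_survival(t43, cell_line.ht)
    else:
        s_ht = 1.0
    if fraction.dose_gy <= 0.0:
        return s_ht, 1.0, None
    if fraction.rt_survival is not None:
        # explicit override of the radiation factor; under combined
        # treatment any sensitization is folded into the supplied value
        s_rt_component = float(fraction.rt_survival)
    elif t43 > 0.0:
        alpha_eff = cell_line.rt.alpha + cell_line.sensitization_slope * t43
        d = fraction.dose_gy
        s_rt_component = float(np.exp(-alpha_eff * d - cell_line.rt.beta * d * d))
    else:
        s_rt_component = alphar_survival(fraction.dose_gy, cell_line.rt)
    if cell_line.gamma_override is not None:
        sens = cell_line.gamma_override
    else:
        sens = PhaseSensitivity.from_survival_ratio(
            s_rt_component, phase_fractions, ratio=cell_line.survival_ratio
        )
    return s_ht, s_rt_component, sens.as_array()


def apply_fraction(
    population: CellPopulation,
    fraction: Fraction,
    cell_line,
    dynamics: DeathDynamics,
    rng: np.random.Generator,
    now: float,
    mode: str = "delayed",
) -> CellPopulation:
    """Deliver one treatment fraction to every cell.

    ``mode="delayed"`` (default) schedules radiation deaths after an
    exponential delay; ``mode="instantaneous"`` removes them at delivery,
    for the comparison experiments.  Heat kill is always instantaneous.
    Senescent cells are unaffected.  A doomed cell failing a later draw is
    rescheduled only if the new death time is earlier (earliest-death wins).
    """
    if mode not in ("delayed", "instantaneous"):
        raise ValueError(f"unknown delivery mode {mode!r}")
    n = population._n
    alive = population.alive[:n]
    fate = population.fate[:n]
    targets = np.flatnonzero(alive & (fate != SENESCENT))
    if targets.size == 0:
        return population
    s_ht, s_rt_component, gamma = _fraction_survivals(
        fraction, cell_line, population.config.phase_fractions
    )
    draws = rng.random(targets.size)
    if gamma is not None:
        pidx = population.phase_indices(targets)
        pidx = np.where(population.in_g0[targets], 4, pidx)  # G0 exponent slot
        s_cell = s_ht * np.power(s_rt_component, gamma[pidx])
    else:
        s_cell = np.full(targets.size, s_ht)
    instant = draws > s_ht
    delayed = ~instant & (draws > s_cell)
    if mode == "instantaneous":
        instant = instant | delayed
        delayed[:] = False
    if delayed.any():
        hit = targets[delayed]
        deaths = now + sample_death_delay(dynamics, rng, size=hit.size)
        # earliest-death wins for cells already scheduled to die
        new_time = np.minimum(population.death_time[hit], deaths)
        population.death_time[hit] = new_time
        newly = population.fate[hit] == VIABLE
        population.fate[hit[newly]] = DOOMED
    if instant.any():
        population.remove_cells(targets[instant])
    population.dynamics = dynamics
    return population


def instantaneous_mode(
    population: CellPopulation,
    fraction: Fraction,
    cell_line,
    dynamics: DeathDynamics,
    rng: np.random.Generator,
    now: float,
) -> CellPopulation:
    """Deliver a fraction with instantaneous rather than delayed cell kill."""
    return apply_fraction(
        population, fraction, cell_line, dynamics, rng, now, mode="instantaneous"
    )
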