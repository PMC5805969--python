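"""Closed-form dose–response models for radiation, heat and combined treatment.

The central survival model is the "AlphaR" parametrization of clonogenic
survival.  It combines a damage rate ``alpha0`` (per unit dose), a repair
rate ``alpha_r`` and a dose-dependent loss of repair capacity ``beta``:
below a threshold dose ``D_T`` survival follows a linear-quadratic (LQ)
exponential,

    S(d) = exp(-(alpha0 - alpha_r) * d - beta * d**2),        d <= D_T,

while above ``D_T`` no repair is possible and the curve continues as a
single exponential with slope ``alpha0``.  With the natural threshold
``D_T = alpha_r / beta`` the two branches meet continuously and the
post-threshold branch reduces to ``exp(-alpha0 * d)``.  The same functional
form describes heat-induced cell kill once the physical heating profile has
been reduced to a thermal dose (cumulative equivalent minutes at 43 °C,
CEM43); with ``alpha0 == alpha_r`` the LQ branch degenerates to the strong
shoulder ``exp(-beta * t43**2)`` typical of hyperthermia survival curves.

Combined radio-thermal survival multiplies the heat-only survival by a
radiation term whose linear coefficient is radio-sensitized in proportion to
the thermal dose:

    S_RTHT(d, t43) = S_HT(t43) * exp(-(alpha_RT + a * t43) * d - beta_RT * d**2).

Cycle-phase radiosensitivity is expressed by exponent weights ``gamma`` so
that the survival of a cell in phase ``p`` is ``S ** gamma_p``; the weights
are solved so that phase survivals keep a fixed ratio (S > G1 > G2 > M,
consecutive ratio 1.5) while the phase-fraction-weighted mean survival
equals the unweighted model prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PHASES",
    "ALL_PHASES",
    "AlphaRParams",
    "CombinationParams",
    "ThermalProfile",
    "PhaseSensitivity",
    "alphar_survival",
    "cem43",
    "ht_survival",
    "rtht_survival",
    "phase_weighted_survival",
]

#: Cycling phases in cycle order.  G0 (quiescence) is tracked separately.
PHASES: tuple[str, ...] = ("G1", "S", "G2", "M")
ALL_PHASES: tuple[str, ...] = PHASES + ("G0",)

#: Sensitivity rank of each phase: number of ratio steps below the most
#: radio-resistant phase (S).  S_S = r * S_G1 = r**2 * S_G2 = r**3 * S_M.
_SENSITIVITY_RANK: Mapping[str, int] = {"S": 0, "G1": 1, "G2": 2, "M": 3}


@dataclass(frozen=True)
class AlphaRParams:
    """AlphaR survival parameters for one treatment modality.

    Parameters
    ----------
    alpha0 : float
        Damage rate per unit dose (Gy⁻¹ for radiation, CEM43⁻¹ for heat).
    alpha_r : float
        Damage-repair rate per unit dose, ``0 <= alpha_r <= alpha0``.
    beta : float
        Quadratic (repair-loss) rate per unit dose squared.
    d_t : float, optional
        Explicit threshold dose above which no repair occurs.  If omitted it
        defaults to ``alpha_r / beta`` when both are positive (the value at
        which the repair term vanishes and the branches join smoothly), and
        to infinity otherwise (pure-LQ behaviour).
    """

    alpha0: float
    alpha_r: float
    beta: float
    d_t: float | None = None

    def __post_init__(self) -> None:
        if not (self.alpha0 >= self.alpha_r >= 0.0):
            raise ValueError(
                f"require alpha0 >= alpha_r >= 0, got alpha0={self.alpha0}, "
                f"alpha_r={self.alpha_r}"
            )
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.d_t is not None and self.d_t < 0.0:
            raise ValueError(f"d_t must be >= 0, got {self.d_t}")

    @property
    def alpha(self) -> float:
        """Net linear coefficient ``alpha0 - alpha_r`` of the LQ branch."""
        return self.alpha0 - self.alpha_r

    @property
    def threshold(self) -> float:
        """Effective threshold dose D_T."""
        if self.d_t is not None:
            return self.d_t
        if self.alpha_r > 0.0 and self.beta > 0.0:
            return self.alpha_r / self.beta
        return math.inf

    @classmethod
    def lq(cls, alpha: float, beta: float) -> "AlphaRParams":
        """Pure linear-quadratic parameters (no threshold; D_T infinite).

        Used when only the LQ branch of the model is calibrated, e.g. the
        HCT116 radiation response with alpha = 0.5 Gy⁻¹, beta = 0.042 Gy⁻².
        """
        return cls(alpha0=alpha, alpha_r=0.0, beta=beta, d_t=math.inf)


def alphar_survival(dose, params: AlphaRParams):
    """Surviving fraction after a dose under the AlphaR model.

    Accepts a scalar or array dose (Gy for radiation, CEM43 for heat).
    Continuous at the threshold dose, monotonically non-increasing, and
    equal to 1 at zero dose.

    Raises
    ------
    ValueError
        If any dose is negative.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("dose must be non-negative")
    t = params.threshold
    dl = np.minimum(d, t)
    log_s = -params.alpha * dl - params.beta * dl * dl
    # Single-exponential continuation beyond the threshold; with the natural
    # threshold alpha_r/beta this equals exp(-alpha0 * d) exactly.
    excess = d - dl
    log_s = log_s - params.alpha0 * excess
    s = np.exp(log_s)
    if np.isscalar(dose) or d.ndim == 0:
        return float(s)
    return s


@dataclass(frozen=True)
class ThermalProfile:
    """A heating exposure as an ordered list of (duration_min, temperature_C)."""

    steps: tuple[tuple[float, float], ...]

    def __init__(self, steps: Iterable[Sequence[float]]):
        norm = tuple((float(t), float(temp)) for t, temp in steps)
        for minutes, temp in norm:
            if minutes < 0.0:
                raise ValueError(f"step duration must be >= 0, got {minutes}")
            if not (0.0 <= temp <= 100.0):
                raise ValueError(f"temperature out of range [0, 100] C: {temp}")
        object.__setattr__(self, "steps", norm)

    def __add__(self, other: "ThermalProfile") -> "ThermalProfile":
        return ThermalProfile(self.steps + other.steps)

    def cem43(self) -> float:
        return cem43(self)

    @classmethod
    def constant(cls, minutes: float, celsius: float) -> "ThermalProfile":
        return cls([(minutes, celsius)])


def cem43(profile: ThermalProfile) -> float:
    """Thermal dose of a heating profile in cumulative equivalent minutes at 43 °C.

    Each step of duration t_i at temperature T_i contributes
    ``t_i * R ** (43 - T_i)`` with R = 0.5 above (or at) 43 °C and R = 0.25
    between 40 and 43 °C; steps at or below 40 °C are biologically inert and
    contribute nothing.  Additive over concatenated profiles.
    """
    total = 0.0
    for minutes, temp in profile.steps:
        if temp <= 40.0:
            continue
        r = 0.5 if temp >= 43.0 else 0.25
        total += minutes * r ** (43.0 - temp)
    return total


def ht_survival(t43, params: AlphaRParams):
    """Surviving fraction after heating, as a function of thermal dose (CEM43).

    The AlphaR model evaluated with heat parameters; typically
    ``alpha0 == alpha_r`` so the sub-threshold branch is the pure shoulder
    ``exp(-beta * t43**2)``.
    """
    return alphar_survival(t43, params)


@dataclass(frozen=True)
class CombinationParams:
    """Parameters for combined radio-thermal survival.

    ``slope_a`` is the radio-sensitization slope: the linear radiation
    coefficient grows as ``alpha_RT + slope_a * t43`` with thermal dose,
    while the quadratic coefficient stays at its radiation-only value.
    """

    alpha_rt: float
    beta_rt: float
    slope_a: float
    ht_params: AlphaRParams

    def __post_init__(self) -> None:
        if self.slope_a < 0.0:
            raise ValueError(f"slope_a must be >= 0, got {self.slope_a}")
        if self.beta_rt < 0.0:
            raise ValueError(f"beta_rt must be >= 0, got {self.beta_rt}")

    def alpha_rtht(self, t43: float) -> float:
        """Sensitized linear coefficient at thermal dose ``t43``."""
        return self.alpha_rt + self.slope_a * t43


def rtht_survival(dose, t43: float, params: CombinationParams):
    """Surviving fraction after simultaneous radiation and heat.

    ``S_HT(t43) * exp(-(alpha_RT + a*t43)*d - beta_RT*d**2)``; reduces to the
    radiation-only LQ survival at zero thermal dose and to the heat-only
    survival at zero radiation dose, and never exceeds either.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("dose must be non-negative")
    if t43 < 0.0:
        raise ValueError("thermal dose must be non-negative")
    s_ht = ht_survival(t43, params.ht_params)
    s = s_ht * np.exp(-params.alpha_rtht(t43) * d - params.beta_rt * d * d)
    if np.isscalar(dose) or d.ndim == 0:
        return float(s)
    return s


@dataclass(frozen=True)
class PhaseSensitivity:
    """Cycle-phase radiosensitivity exponents.

    Maps each phase (including G0) to a positive exponent ``gamma`` such
    that a cell in phase p survives with probability ``S ** gamma_p`` when
    the population-average surviving fraction is S.
    """

    gamma: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [p for p in ALL_PHASES if p not in self.gamma]
        if missing:
            raise ValueError(f"gamma map missing phases: {missing}")
        bad = {p: g for p, g in self.gamma.items() if g <= 0.0}
        if bad:
            raise ValueError(f"gamma exponents must be positive: {bad}")

    def as_array(self) -> np.ndarray:
        """Exponents ordered as (G1, S, G2, M, G0) for vectorized lookups."""
        return np.array([self.gamma[p] for p in ALL_PHASES], dtype=float)

    @classmethod
    def identity(cls) -> "PhaseSensitivity":
        return cls({p: 1.0 for p in ALL_PHASES})

    @classmethod
    def from_survival_ratio(
        cls,
        base_survival: float,
        phase_fractions: Mapping[str, float],
        ratio: float = 1.5,
        g0_like: str = "G1",
    ) -> "PhaseSensitivity":
        """Solve the gamma map at a reference survival level.

        Phase survivals are constrained to consecutive ratios
        ``S_S = r*S_G1 = r**2*S_G2 = r**3*S_M`` (S-phase most resistant,
        M-phase most sensitive) and normalized so that the
        phase-fraction-weighted mean of phase survivals equals
        ``base_survival``.  This has the closed-form solution

            S_S = S / sum_p f_p * r**(-k_p),   gamma_p = ln(S_p) / ln(S),

        with ``k_p`` the sensitivity rank of phase p.  Quiescent (G0) cells
        take the exponent of ``g0_like`` (default G1).

        For survival levels too close to 1 the normalization would require a
        phase survival above 1; the map then degenerates to identity
        (uniform sensitivity), which is the correct zero-kill limit.
        """
        s = float(base_survival)
        if not (0.0 < s <= 1.0):
            raise ValueError(f"base_survival must be in (0, 1], got {s}")
        if ratio <= 0.0:
            raise ValueError(f"ratio must be positive, got {ratio}")
        weight = sum(
            phase_fractions[p] * ratio ** (-_SENSITIVITY_RANK[p]) for p in PHASES
        )
        s_s = s / weight
        if s >= 1.0 or s_s >= 1.0:
            return cls.identity()
        log_s = math.log(s)
        gamma = {
            p: math.log(s_s * ratio ** (-_SENSITIVITY_RANK[p])) / log_s
            for p in PHASES
        }
        gamma["G0"] = gamma[g0_like]
        return cls(gamma)


def phase_weighted_survival(
    base_survival: float, phase: str, sensitivity: PhaseSensitivity
) -> float:
    """Surviving fraction of a cell in a given cycle phase.

    ``base_survival ** gamma_phase``.  A base survival of exactly 0 maps to
    0 for every phase (documented edge case: the exponentiation is taken in
    the limit from above).
    """
    if phase not in sensitivity.gamma:
        raise ValueError(f"unknown phase {phase!r}")
    if not (0.0 <= base_survival <= 1.0):
        raise ValueError(f"base_survival must be in [0, 1], got {base_survival}")
    if base_survival == 0.0:
        return 0.0
    return float(base_survival ** sensitivity.gamma[phase])
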