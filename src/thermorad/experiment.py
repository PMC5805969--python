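"""Run controller: well-plate presets, replicate ensembles, growth curves.

An experiment seeds N0 cells on a circular well grid, steps the population
forward at a fixed time step, delivers scheduled treatment fractions, and
records a compartment census at a fixed sampling interval.  Ensembles run
independent seeded replicates and report per-time-point mean and SD.
Everything is reproducible bit-for-bit from (config, master seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .lattice import Grid, grid_diameter_voxels
from .population import CellPopulation, CycleConfig
from .survival import AlphaRParams, PhaseSensitivity
from .treatment import DeathDynamics, Fraction, TreatmentSchedule, apply_fraction

__all__ = [
    "PLATE_PRESETS",
    "CellLine",
    "HCT116",
    "ExperimentConfig",
    "GrowthCurve",
    "run_experiment",
    "run_ensemble",
    "envelope_runs",
    "heat_timing_sweep",
    "write_manifest",
]

COMPARTMENTS = ("G1", "S", "G2", "M", "G0", "doomed", "senescent", "giant", "total")

#: Well-plate presets as (well diameter mm, voxel edge um); these reproduce
#: grid diameters of 1625 voxels (24-well) and 2900 voxels (6-well).
PLATE_PRESETS: Mapping[str, tuple[float, float]] = {
    "24-well": (15.6, 9.6),
    "6-well": (34.8, 12.0),
}


def _default_ht_params() -> AlphaRParams:
    # Synthetic placeholder heat-survival parameters (no measured values are
    # bundled): a pure shoulder with D_T = 40 CEM43 and S_HT(40) = e^-2.
    # Real analyses should supply cell-line-specific values.
    return AlphaRParams(alpha0=0.05, alpha_r=0.05, beta=0.00125)


@dataclass(frozen=True)
class CellLine:
    """Complete per-cell-line parameter set.

    ``rt`` holds radiation AlphaR parameters (LQ-reduced for HCT116),
    ``ht`` thermal-dose AlphaR parameters, ``sensitization_slope`` the
    linear growth rate of the radiation alpha with thermal dose (Gy^-1 per
    CEM43), ``dynamics`` the delayed-death parameters, and
    ``survival_ratio`` the constant ratio between consecutive phase
    survivals (S > G1 > G2 > M).  ``gamma_override`` pins explicit phase
    exponents instead of solving them per fraction.
    """

    name: str = "HCT116"
    cycle: CycleConfig = field(default_factory=CycleConfig)
    rt: AlphaRParams = field(default_factory=lambda: AlphaRParams.lq(0.5, 0.042))
    ht: AlphaRParams = field(default_factory=_default_ht_params)
    sensitization_slope: float = 0.01
    dynamics: DeathDynamics = field(default_factory=DeathDynamics)
    survival_ratio: float = 1.5
    gamma_override: PhaseSensitivity | None = None


#: Default HCT116 parametrization (radiation arm fully calibrated; heat arm
#: carries documented synthetic placeholders).
HCT116 = CellLine()


@dataclass(frozen=True)
class ExperimentConfig:
    """One in silico growth-curve experiment.

    ``plate`` selects a preset; alternatively give ``well_diameter_mm`` and
    ``voxel_edge_um`` directly (they override the preset when both set).
    """

    cell_line: CellLine = field(default_factory=lambda: HCT116)
    plate: str = "24-well"
    well_diameter_mm: float | None = None
    voxel_edge_um: float | None = None
    n_initial: int = 23_000
    duration_h: float = 200.0
    dt_h: float = 0.5
    sample_interval_h: float = 1.0
    schedule: TreatmentSchedule = field(default_factory=TreatmentSchedule)
    kill_mode: str = "delayed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kill_mode not in ("delayed", "instantaneous"):
            raise ValueError(f"unknown kill_mode {self.kill_mode!r}")
        if self.n_initial < 0:
            raise ValueError("n_initial must be >= 0")
        if self.dt_h <= 0.0 or self.duration_h < 0.0:
            raise ValueError("dt_h must be > 0 and duration_h >= 0")
        ratio = self.sample_interval_h / self.dt_h
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("sample_interval_h must be a multiple of dt_h")
        if (self.well_diameter_mm is None) != (self.voxel_edge_um is None):
            raise ValueError("set both well_diameter_mm and voxel_edge_um, or neither")
        if self.well_diameter_mm is None and self.plate not in PLATE_PRESETS:
            raise ValueError(f"unknown plate preset {self.plate!r}")

    def geometry(self) -> tuple[float, float]:
        if self.well_diameter_mm is not None:
            return self.well_diameter_mm, self.voxel_edge_um
        return PLATE_PRESETS[self.plate]

    def grid_diameter(self) -> int:
        well, voxel = self.geometry()
        return grid_diameter_voxels(well, voxel)

    def make_grid(self) -> Grid:
        return Grid(self.grid_diameter())


class GrowthCurve:
    """Compartment counts over time, optionally with replicate statistics.

    ``data`` holds the (mean) counts with columns ``time_h`` plus one per
    compartment; ``sd`` mirrors it with standard deviations for ensembles.
    """

    def __init__(self, data: pd.DataFrame, sd: pd.DataFrame | None = None,
                 n_replicates: int = 1):
        self.data = data.reset_index(drop=True)
        self.sd = sd.reset_index(drop=True) if sd is not None else None
        self.n_replicates = n_replicates

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy()

    @property
    def total(self) -> np.ndarray:
        return self.data["total"].to_numpy(dtype=float)

    def doubling_time(self, window: tuple[float, float] = (24.0, 96.0)) -> float:
        """Doubling time from a log-linear fit of total count over a window."""
        t0, t1 = window
        sel = (self.data["time_h"] >= t0) & (self.data["time_h"] <= t1)
        t = self.data.loc[sel, "time_h"].to_numpy(dtype=float)
        y = self.data.loc[sel, "total"].to_numpy(dtype=float)
        if t.size < 3 or np.any(y <= 0):
            raise ValueError("need >= 3 positive counts in the fit window")
        slope = np.polyfit(t, np.log2(y), 1)[0]
        return 1.0 / slope

    def to_csv(self, path) -> None:
        """Write tidy long-format CSV (time_h, compartment, mean, sd)."""
        long = self.data.melt(id_vars="time_h", var_name="compartment",
                              value_name="mean")
        if self.sd is not None:
            sd_long = self.sd.melt(id_vars="time_h", var_name="compartment",
                                   value_name="sd")
            long = long.merge(sd_long, on=["time_h", "compartment"])
        else:
            long["sd"] = 0.0
        long.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GrowthCurve":
        long = pd.read_csv(path)
        data = long.pivot(index="time_h", columns="compartment", values="mean")
        sd = long.pivot(index="time_h", columns="compartment", values="sd")
        cols = [c for c in COMPARTMENTS if c in data.columns]
        data = data[cols].reset_index()
        sd = sd[cols].reset_index()
        return cls(data, sd)


def _single_run(config: ExperimentConfig, seed) -> GrowthCurve:
    rng = np.random.default_rng(seed)
    grid = config.make_grid()
    if config.n_initial > grid.n_sites:
        raise ValueError(
            f"N0={config.n_initial} exceeds the {grid.n_sites}-voxel well"
        )
    pop = CellPopulation(grid, config.cell_line.cycle, rng,
                         dynamics=config.cell_line.dynamics)
    pop.seed(config.n_initial)
    fractions = sorted(config.schedule.fractions, key=lambda f: f.time_h)
    fi = 0
    # fractions at t <= 0 are delivered right after seeding
    while fi < len(fractions) and fractions[fi].time_h <= 1e-9:
        apply_fraction(pop, fractions[fi], config.cell_line,
                       config.cell_line.dynamics, rng, now=0.0,
                       mode=config.kill_mode)
        fi += 1
    records = [(0.0, pop.counts())]
    n_steps = int(round(config.duration_h / config.dt_h))
    stride = int(round(config.sample_interval_h / config.dt_h))
    for k in range(1, n_steps + 1):
        pop.step(config.dt_h)
        now = pop.time
        while fi < len(fractions) and fractions[fi].time_h <= now + 1e-9:
            apply_fraction(pop, fractions[fi], config.cell_line,
                           config.cell_line.dynamics, rng, now=now,
                           mode=config.kill_mode)
            fi += 1
        if k % stride == 0:
            records.append((now, pop.counts()))
    rows = []
    for t, c in records:
        row = {"time_h": t}
        row.update({k: c[k] for k in COMPARTMENTS})
        rows.append(row)
    return GrowthCurve(pd.DataFrame(rows))


def run_experiment(config: ExperimentConfig, seed: int | None = None) -> GrowthCurve:
    """Run a single replicate; deterministic given the master seed."""
    return _single_run(config, config.seed if seed is None else seed)


def run_ensemble(
    config: ExperimentConfig, n_replicates: int, seed: int | None = None
) -> GrowthCurve:
    """Mean and SD growth curve over independent seeded replicates."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    master = config.seed if seed is None else seed
    if not isinstance(master, np.random.SeedSequence):
        master = np.random.SeedSequence(master)
    children = master.spawn(n_replicates)
    curves = [_single_run(config, child) for child in children]
    times = curves[0].data["time_h"]
    stack = np.stack([c.data[list(COMPARTMENTS)].to_numpy(dtype=float)
                      for c in curves])
    mean = pd.DataFrame(stack.mean(axis=0), columns=COMPARTMENTS)
    sd = pd.DataFrame(stack.std(axis=0, ddof=0), columns=COMPARTMENTS)
    mean.insert(0, "time_h", times)
    sd.insert(0, "time_h", times)
    return GrowthCurve(mean, sd, n_replicates=n_replicates)


def _with_rt_override(config: ExperimentConfig, survival: float) -> ExperimentConfig:
    fr = [dataclasses.replace(f, rt_survival=survival if f.dose_gy > 0 else None)
          for f in config.schedule.fractions]
    return dataclasses.replace(config, schedule=TreatmentSchedule(fr))


def envelope_runs(
    config: ExperimentConfig,
    survival_ci: tuple[float, float],
    n_replicates: int = 5,
    seed: int | None = None,
) -> dict[str, GrowthCurve]:
    """Growth-curve envelope for the confidence bounds of a surviving fraction.

    Re-runs the experiment with the radiation surviving fraction pinned at
    each CI bound; returns ``{"low", "central", "high"}`` ensemble curves.
    The bound curves bracket the central one during the death-dominated
    interval (in expectation).
    """
    low, high = survival_ci
    if low > high:
        raise ValueError("require low <= high")
    return {
        "low": run_ensemble(_with_rt_override(config, low), n_replicates, seed),
        "central": run_ensemble(config, n_replicates, seed),
        "high": run_ensemble(_with_rt_override(config, high), n_replicates, seed),
    }


def heat_timing_sweep(
    config: ExperimentConfig,
    candidate_days: Sequence[float],
    thermal,
    n_replicates: int = 5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[float, GrowthCurve]]:
    """Sweep the day on which a single heat fraction joins an RT schedule.

    For each candidate day the heating profile is attached to the nearest
    scheduled fraction and an ensemble is run.  The summary statistic per
    day is the regrowth onset: the first time after the end of treatment at
    which the mean total count exceeds its value at treatment end (NaN if
    the population never regrows within the simulated horizon).
    """
    if not config.schedule.fractions:
        raise ValueError("sweep needs a base treatment schedule")
    end = config.schedule.end_time
    rows = []
    curves: dict[float, GrowthCurve] = {}
    for day in candidate_days:
        sched = config.schedule.with_thermal_at(day, thermal)
        cfg = dataclasses.replace(config, schedule=sched)
        curve = run_ensemble(cfg, n_replicates, seed)
        curves[day] = curve
        t = curve.times
        total = curve.total
        at_end = total[np.searchsorted(t, end)]
        after = (t > end) & (total > at_end)
        onset = float(t[after][0]) if after.any() else float("nan")
        rows.append({"day": day, "regrowth_onset_h": onset,
                     "count_at_end": at_end, "final_count": total[-1]})
    return pd.DataFrame(rows), curves


def _config_dict(config: ExperimentConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)


def write_manifest(path, config: ExperimentConfig, seed: int | None = None) -> dict:
    """Write a JSON run manifest (config, config hash, seed, version)."""
    payload = {
        "package": "thermorad",
        "version": _pkg_version,
        "seed": config.seed if seed is None else seed,
        "config": _config_dict(config),
    }
    blob = json.dumps(payload["config"], sort_keys=True).encode()
    payload["config_sha256"] = hashlib.sha256(blob).hexdigest()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload
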