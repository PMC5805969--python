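"""YAML configuration loading for cell lines, schedules and experiments."""

from __future__ import annotations

from pathlib import Path

import yaml

from .experiment import CellLine, ExperimentConfig
from .population import CycleConfig
from .survival import AlphaRParams, PhaseSensitivity, ThermalProfile
from .treatment import DeathDynamics, Fraction, TreatmentSchedule

__all__ = [
    "load_cell_line",
    "load_schedule",
    "load_experiment",
    "load_config",
]


def _cycle_from_dict(d: dict) -> CycleConfig:
    kw = {}
    if "doubling_time_h" in d:
        kw["mean_doubling_time"] = float(d["doubling_time_h"])
    if "rate_sd_fraction" in d:
        kw["rate_sd_fraction"] = float(d["rate_sd_fraction"])
    if "lag_h" in d:
        kw["lag_hours"] = float(d["lag_h"])
    if "phase_fractions" in d:
        kw["phase_fractions"] = {k: float(v) for k, v in d["phase_fractions"].items()}
    return CycleConfig(**kw)


def _alphar_from_dict(d: dict) -> AlphaRParams:
    if "alpha" in d and "alpha0" not in d:
        # LQ-reduced form: alpha = alpha0 - alpha_r, threshold infinite
        return AlphaRParams.lq(float(d["alpha"]), float(d["beta"]))
    return AlphaRParams(
        alpha0=float(d["alpha0"]),
        alpha_r=float(d.get("alpha_r", 0.0)),
        beta=float(d["beta"]),
        d_t=float(d["d_t"]) if "d_t" in d else None,
    )


def load_cell_line(d: dict) -> CellLine:
    kw: dict = {}
    if "name" in d:
        kw["name"] = d["name"]
    kw["cycle"] = _cycle_from_dict(d)
    if "rt" in d:
        kw["rt"] = _alphar_from_dict(d["rt"])
    if "ht" in d:
        kw["ht"] = _alphar_from_dict(d["ht"])
    if "sensitization_slope" in d:
        kw["sensitization_slope"] = float(d["sensitization_slope"])
    if "dynamics" in d:
        dd = d["dynamics"]
        kw["dynamics"] = DeathDynamics(
            k_delay=float(dd.get("k_delay", 0.009)),
            p_mitotic_cat=float(dd.get("p_mitotic_cat", 0.2)),
            p_senescence=float(dd.get("p_senescence", 0.05)),
        )
    if d.get("gamma"):
        kw["gamma_override"] = PhaseSensitivity(
            {k: float(v) for k, v in d["gamma"].items()}
        )
    if "survival_ratio" in d:
        kw["survival_ratio"] = float(d["survival_ratio"])
    return CellLine(**kw)


def _thermal_from_entry(entry) -> ThermalProfile | None:
    if entry is None:
        return None
    return ThermalProfile([(float(m), float(t)) for m, t in entry])


def load_schedule(entries: list) -> TreatmentSchedule:
    """Schedule from a list of fraction dicts, or a pattern dict.

    Pattern forms: ``{pattern: daily, n: 5, dose_gy: 2}`` and
    ``{pattern: weekday, n: 30, dose_gy: 2}``.
    """
    if isinstance(entries, dict):
        pattern = entries.get("pattern", "daily")
        n = int(entries["n"])
        dose = float(entries["dose_gy"])
        start = float(entries.get("start_h", 0.0))
        if pattern == "daily":
            return TreatmentSchedule.daily(
                n, dose, start_h=start,
                interval_h=float(entries.get("interval_h", 24.0)),
                thermal=_thermal_from_entry(entries.get("thermal")),
            )
        if pattern == "weekday":
            return TreatmentSchedule.weekday(n, dose, start_h=start)
        raise ValueError(f"unknown schedule pattern {pattern!r}")
    fractions = [
        Fraction(
            time_h=float(e["time_h"]),
            dose_gy=float(e.get("dose_gy", 0.0)),
            thermal=_thermal_from_entry(e.get("thermal")),
            rt_survival=(float(e["rt_survival"]) if "rt_survival" in e else None),
            ht_survival=(float(e["ht_survival"]) if "ht_survival" in e else None),
        )
        for e in entries or []
    ]
    return TreatmentSchedule(fractions)


def load_experiment(d: dict, cell_line: CellLine,
                    schedule: TreatmentSchedule) -> ExperimentConfig:
    kw: dict = {"cell_line": cell_line, "schedule": schedule}
    for src, dst, cast in [
        ("plate", "plate", str),
        ("well_diameter_mm", "well_diameter_mm", float),
        ("voxel_edge_um", "voxel_edge_um", float),
        ("n_initial", "n_initial", int),
        ("duration_h", "duration_h", float),
        ("dt_h", "dt_h", float),
        ("sample_interval_h", "sample_interval_h", float),
        ("kill_mode", "kill_mode", str),
        ("seed", "seed", int),
    ]:
        if src in d:
            kw[dst] = cast(d[src])
    return ExperimentConfig(**kw)


def load_config(path) -> ExperimentConfig:
    """Load a full experiment configuration from a YAML file."""
    with open(Path(path)) as fh:
        doc = yaml.safe_load(fh) or {}
    cell_line = load_cell_line(doc.get("cell_line", {}))
    schedule = load_schedule(doc.get("schedule", []))
    return load_experiment(doc.get("experiment", {}), cell_line, schedule)
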