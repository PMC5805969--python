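"""Treatment decision tree: instant heat kill, delayed radiation death,
mitotic catastrophe, and fraction scheduling."""

import numpy as np
import pytest

from thermorad import (
    CellLine,
    DeathDynamics,
    ExperimentConfig,
    Fraction,
    Grid,
    PhaseSensitivity,
    ThermalProfile,
    TreatmentSchedule,
    apply_fraction,
    run_experiment,
    sample_death_delay,
    seed_population,
)
from thermorad.population import DOOMED, GIANT, SENESCENT, VIABLE
from thermorad.treatment import mitotic_fate, sample_mitotic_fate

CAL = DeathDynamics()  # calibrated: k_delay=0.009, p_mitoticCat=0.2, p_sen=0.05


class TestDeathDelay:
    def test_mean_delay_is_inverse_rate(self, rng):
        draws = sample_death_delay(CAL, rng, size=100_000)
        assert draws.mean() == pytest.approx(1.0 / 0.009, abs=1.5)

    def test_large_rate_gives_vanishing_delays(self, rng):
        fast = DeathDynamics(k_delay=1e9)
        assert sample_death_delay(fast, rng, size=100).max() < 1e-6

    def test_reproducible_under_fixed_seed(self):
        a = sample_death_delay(CAL, np.random.default_rng(5), size=10)
        b = sample_death_delay(CAL, np.random.default_rng(5), size=10)
        assert np.array_equal(a, b)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            DeathDynamics(k_delay=0.0)


class TestMitoticFate:
    def test_zero_catastrophe_probability_always_divides(self, rng):
        dyn = DeathDynamics(p_mitotic_cat=0.0)
        assert all(sample_mitotic_fate(dyn, rng) == "divide" for _ in range(200))

    def test_certain_catastrophe_and_senescence(self, rng):
        dyn = DeathDynamics(p_mitotic_cat=1.0, p_senescence=1.0)
        assert all(sample_mitotic_fate(dyn, rng) == "senescent" for _ in range(200))

    def test_calibrated_fate_frequencies(self, rng):
        """With (0.2, 0.05): divide/giant/senescent converge to
        0.80 / 0.19 / 0.01."""
        n = 100_000
        counts = {"divide": 0, "giant": 0, "senescent": 0}
        for _ in range(n):
            counts[sample_mitotic_fate(CAL, rng)] += 1
        # 4-sigma binomial tolerances
        assert counts["divide"] / n == pytest.approx(0.80, abs=4 * np.sqrt(0.8 * 0.2 / n))
        assert counts["giant"] / n == pytest.approx(0.19, abs=4 * np.sqrt(0.19 * 0.81 / n))
        assert counts["senescent"] / n == pytest.approx(0.01, abs=4 * np.sqrt(0.01 * 0.99 / n))

    def test_rejects_non_doomed_cell(self, cycle, rng):
        pop = seed_population(3, Grid(21), cycle, rng)
        with pytest.raises(ValueError):
            mitotic_fate(pop, 0, CAL, rng)

    def test_applies_fate_to_doomed_cell(self, cycle, rng):
        pop = seed_population(3, Grid(21), cycle, rng)
        pop.fate[0] = DOOMED
        pop.death_time[0] = 500.0
        out = mitotic_fate(pop, 0, DeathDynamics(p_mitotic_cat=1.0, p_senescence=0.0), rng)
        assert out == "giant"
        assert pop.fate[0] == GIANT and pop.giant_size[0] == 1


def _uniform_line():
    return CellLine(gamma_override=PhaseSensitivity.identity())


class TestApplyFraction:
    def test_zero_dose_fraction_changes_nothing(self, cycle, rng):
        pop = seed_population(500, Grid(101), cycle, rng)
        apply_fraction(pop, Fraction(0.0, dose_gy=0.0), _uniform_line(), CAL, rng, now=0.0)
        assert pop.n_alive == 500
        assert int((pop.fate[:500] == VIABLE).sum()) == 500

    def test_heat_kill_is_binomial_and_instantaneous(self, cycle):
        """Pure heat at S_HT = 0.5 on 10^5 cells leaves 50000 +- 3*sqrt(25000)
        survivors, removed at the moment of treatment."""
        rng = np.random.default_rng(11)
        g = Grid(401)
        pop = seed_population(100_000, g, cycle, rng)
        apply_fraction(pop, Fraction(0.0, ht_survival=0.5), _uniform_line(), CAL,
                       rng, now=0.0)
        assert pop.n_alive == pytest.approx(50_000, abs=3 * np.sqrt(25_000))
        assert pop.counts()["doomed"] == 0  # heat never schedules delayed death

    def test_radiation_marks_doomed_without_removing(self, cycle):
        rng = np.random.default_rng(12)
        pop = seed_population(10_000, Grid(151), cycle, rng)
        apply_fraction(pop, Fraction(0.0, dose_gy=5.0, rt_survival=0.03),
                       _uniform_line(), CAL, rng, now=0.0)
        c = pop.counts()
        assert c["total"] == 10_000  # delayed kill: nothing removed yet
        assert c["doomed"] == pytest.approx(9_700, abs=3 * np.sqrt(10_000 * 0.03 * 0.97))
        doomed = pop.fate[:10_000] == DOOMED
        assert np.all(np.isfinite(pop.death_time[:10_000][doomed]))

    def test_combined_branch_frequencies(self, cycle):
        """Combined treatment splits cells into instant-killed, doomed and
        surviving fractions (1 - S_HT, S_HT - S_RTHT, S_RTHT)."""
        rng = np.random.default_rng(13)
        pop = seed_population(100_000, Grid(401), cycle, rng)
        # S_HT = 0.6 pinned; radiation factor pinned at 0.5 -> S_RTHT = 0.3
        apply_fraction(pop, Fraction(0.0, dose_gy=2.0, rt_survival=0.5, ht_survival=0.6),
                       _uniform_line(), CAL, rng, now=0.0)
        c = pop.counts()
        n = 100_000
        tol = 4 * np.sqrt(n * 0.25) / n
        assert 1 - c["total"] / n == pytest.approx(0.4, abs=tol)
        assert c["doomed"] / n == pytest.approx(0.3, abs=tol)
        assert (c["total"] - c["doomed"]) / n == pytest.approx(0.3, abs=tol)

    def test_phase_weighting_spares_s_phase(self, cycle):
        """With phase-dependent sensitivity, S-phase cells are doomed less
        often than M-phase cells at the same dose."""
        rng = np.random.default_rng(14)
        line = CellLine()  # ratio-1.5 phase weighting solved per fraction
        pop = seed_population(40_000, Grid(301), cycle, rng)
        slots = np.arange(40_000)
        phase_before = pop.phase_indices(slots)
        apply_fraction(pop, Fraction(0.0, dose_gy=5.0), line, CAL, rng, now=0.0)
        doomed = pop.fate[:40_000] == DOOMED
        rate_s = doomed[phase_before == 1].mean()
        rate_m = doomed[phase_before == 3].mean()
        assert rate_s < rate_m

    def test_senescent_cells_are_immune(self, cycle, rng):
        pop = seed_population(100, Grid(31), cycle, rng)
        pop.fate[:100] = SENESCENT
        apply_fraction(pop, Fraction(0.0, ht_survival=0.0), _uniform_line(), CAL,
                       rng, now=0.0)
        assert pop.n_alive == 100

    def test_earliest_death_wins_on_reirradiation(self, cycle):
        rng = np.random.default_rng(15)
        pop = seed_population(5_000, Grid(101), cycle, rng)
        apply_fraction(pop, Fraction(0.0, dose_gy=5.0, rt_survival=0.03),
                       _uniform_line(), CAL, rng, now=0.0)
        before = pop.death_time[:5_000].copy()
        apply_fraction(pop, Fraction(24.0, dose_gy=5.0, rt_survival=0.03),
                       _uniform_line(), CAL, rng, now=24.0)
        after = pop.death_time[: 5_000]
        assert np.all(after <= before + 1e-12)

    def test_unknown_mode_rejected(self, cycle, rng):
        pop = seed_population(10, Grid(21), cycle, rng)
        with pytest.raises(ValueError):
            apply_fraction(pop, Fraction(0.0), _uniform_line(), CAL, rng, 0.0,
                           mode="sometime")


class TestDelayedVersusInstantaneous:
    def _config(self, mode):
        return ExperimentConfig(
            cell_line=_uniform_line(),
            well_diameter_mm=0.301, voxel_edge_um=1.0,
            n_initial=2_000, duration_h=150.0, sample_interval_h=5.0,
            schedule=TreatmentSchedule([Fraction(0.0, dose_gy=5.0, rt_survival=0.03)]),
            kill_mode=mode,
        )

    def test_instantaneous_drop_matches_survival(self):
        curve = run_experiment(self._config("instantaneous"), seed=21)
        n0 = 2_000
        assert curve.total[0] == pytest.approx(n0 * 0.03, abs=3 * np.sqrt(n0 * 0.03))

    def test_delayed_kill_dominates_instantaneous_pointwise(self):
        """Delayed-kill growth curves lie above instantaneous-kill curves at
        every recorded time while scheduled deaths are still pending."""
        delayed = run_experiment(self._config("delayed"), seed=21)
        instant = run_experiment(self._config("instantaneous"), seed=21)
        assert np.all(delayed.total >= instant.total)
        # and early on the gap is large: most cells are dying, not dead
        mid = np.searchsorted(delayed.times, 48.0)
        assert delayed.total[mid] > 5 * instant.total[mid]

    def test_delayed_curve_exceeds_scaled_survivor_growth_early(self):
        """Shortly after 5 Gy the population is far larger than surviving
        clones alone could be: doomed cells keep proliferating."""
        delayed = run_experiment(self._config("delayed"), seed=22)
        t = 48.0
        idx = np.searchsorted(delayed.times, t)
        survivor_only = 0.03 * 2_000 * 2 ** (t / 19.5)
        assert delayed.total[idx] > 3 * survivor_only


class TestSchedules:
    def test_daily_pattern(self):
        s = TreatmentSchedule.daily(5, 2.0)
        assert [f.time_h for f in s] == [0.0, 24.0, 48.0, 72.0, 96.0]
        assert all(f.dose_gy == 2.0 for f in s)

    def test_weekday_pattern_skips_weekends(self):
        s = TreatmentSchedule.weekday(10, 2.0)
        days = [f.time_h / 24.0 for f in s]
        assert days == [0, 1, 2, 3, 4, 7, 8, 9, 10, 11]

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError):
            TreatmentSchedule([Fraction(24.0), Fraction(0.0)])

    def test_with_thermal_at_attaches_to_nearest_fraction(self):
        s = TreatmentSchedule.daily(5, 2.0)
        heated = s.with_thermal_at(2.0, ThermalProfile.constant(5, 46))
        assert heated.fractions[2].thermal is not None
        assert sum(f.thermal is not None for f in heated) == 1

    def test_doomed_daughters_inherit_parent_death_time(self, cycle):
        rng = np.random.default_rng(30)
        g = Grid(31)
        pop = seed_population(1, g, cycle, rng)
        pop.fate[0] = DOOMED
        pop.death_time[0] = 1000.0
        pop.dynamics = DeathDynamics(p_mitotic_cat=0.0)
        for _ in range(100):  # ~2 cycles
            pop.step(0.5)
        alive = np.flatnonzero(pop.alive[: pop._n])
        assert alive.size > 1
        assert np.all(pop.fate[alive] == DOOMED)
        assert np.all(pop.death_time[alive] == 1000.0)
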