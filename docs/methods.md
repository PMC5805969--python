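# Methods

This note documents the model implemented by `thermorad`, the defaults it
ships with, the numerical choices made where the design was genuinely open,
and what the test suite does and does not establish.

## Growth engine

Cells are lattice agents on a circular 2-D grid; voxel edge length equals
one cell diameter, so the grid diameter in voxels is
`round(well_diameter / voxel_edge)` (15.6 mm / 9.6 µm → 1625;
34.8 mm / 12 µm → 2900). A voxel belongs to the well if its centre lies
within the well radius of the array centre; this centre convention makes the
in-well voxel count (the carrying capacity) exactly reproducible — 2 073 929
voxels for the 24-well preset.

Each cell carries an individual cycle duration drawn once from
N(T_d, (f·T_d)²) truncated at ±3 SD (defaults T_d = 19.5 h, f = 0.05) and a
cycle clock advanced by the global time step. Phases are assigned by
cumulative phase fractions of the cycle with half-open boundaries
(defaults G1 40 %, S 35 %, G2 20 %, M 5 %; the G2/M split of the
flow-cytometry doublet peak is fixed at 20 %/5 %, while the G1/S split is an
ordinary config knob since it is the least certain of the four). Seeded
cells start with clocks uniform in their cycle, which makes the initial
phase census match the configured fractions; a 2 h lag freezes all clocks
after seeding (treatment delivered during the lag still kills).

On completing its cycle a cell divides: its neighbourhood is scanned
outwards (orders 1–3) and a uniformly random empty voxel of the nearest
non-empty ring receives the daughter. Moore (Chebyshev) and Von Neumann
(Manhattan) neighbourhoods alternate per cell, toggled at every division
attempt, which keeps single-founder colonies circular (property-tested:
width/height within 10 % of 1 at 10⁴ cells). Parent and daughter both
restart in G1 with clock 0; the daughter draws a fresh duration. With no
free voxel the cell enters reversible quiescence (G0, clock frozen).

Two engine-level choices deserve note:

* **Quiescence wake-up.** Instead of re-scanning every G0 cell each step,
  quiescent cells are woken when a voxel within Chebyshev radius 3 of them
  is vacated. Vacancies arise only through cell removal, so this is
  behaviourally identical and costs O(removals), not O(G0 population). A
  cell whose Von Neumann scan failed while diagonal (Moore) space remains
  is kept "pending" rather than quiescent and re-attempts next step with
  the toggled neighbourhood.
* **Update order.** Cells due to divide in a step are processed in a fresh
  seeded random permutation, so space contests carry no spatial bias.

The time step defaults to dt = 0.5 h, resolving the ~1 h M-phase; the
realized doubling time is stable to halving dt (tested). Because clocks
reset to 0 at division, the mean realized cycle exceeds the drawn duration
by about dt/2 (~0.25 h), well inside the ±1 h band on the doubling time.

## Survival models

The AlphaR model is evaluated as
`S(d) = exp(−(α₀−α_R)·min(d,D_T) − β·min(d,D_T)²) · exp(−α₀·max(d−D_T,0))`,
which is continuous at any threshold; with the natural threshold
D_T = α_R/β the repair term vanishes there and the expression reduces to
exp(−α₀ d) above threshold. D_T may also be supplied explicitly, in which
case the post-threshold branch is S(D_T)·exp(−α₀(d−D_T)). For the HCT116
radiation arm only the LQ branch is calibrated (α = α₀−α_R = 0.5 Gy⁻¹,
β = 0.042 Gy⁻², D_T infinite); it gives S = 0.311, 0.153, 0.029 at 2, 3,
5 Gy.

Thermal dose uses the standard two-case conversion
t₄₃ = Σ tᵢ·R^(43−Tᵢ), R = 0.5 for T ≥ 43 °C and 0.25 for 40 < T < 43 °C,
with steps at or below 40 °C ignored; 5 min at 46 °C converts to 40 CEM43.
Heat survival feeds t₄₃ through the AlphaR form with heat parameters
(α₀ = α_R, so the sub-threshold branch is the shoulder exp(−β t₄₃²)).
No measured heat parameters are bundled: the shipped defaults
(α₀ = α_R = 0.05 CEM43⁻¹, β = 0.00125 CEM43⁻², sensitization slope
a = 0.01 Gy⁻¹ CEM43⁻¹) are synthetic placeholders giving a moderate
S_HT(40 CEM43) = e⁻² ≈ 0.135, and analyses should supply cell-line values.

Combined survival is
S_RTHT(d, t₄₃) = S_HT(t₄₃)·exp(−(α_RT + a t₄₃) d − β_RT d²) with β
independent of thermal dose. RT and HT within one fraction are treated as
simultaneous; no decay of radiosensitization with RT–HT interval is
modelled (schedules here separate fractions by ≥ 24 h).

### Phase sensitivity

Phase-dependent radiosensitivity uses exponents γ_p (survival S^γ_p),
solved at the delivered dose from two constraints: consecutive phase
survivals in the order S, G1, G2, M keep a fixed ratio r = 1.5, and the
phase-fraction-weighted mean of phase survivals equals the unweighted
survival. This has a closed form, S_S = S / Σ_p f_p r^(−k_p) with k_p the
sensitivity rank, and γ_p = ln S_p / ln S; the normalization residual is
machine precision. Two edge cases: for survival close to 1 (roughly
S ≳ 0.72 with default phase fractions) the arithmetic-mean constraint would
demand a phase survival above 1, and the map degenerates to γ ≡ 1 — the
correct zero-kill limit; and quiescent (G0) cells take γ_G1 by default
(configurable), since no separate quiescent sensitivity is established.
Explicit γ maps may be supplied instead of the solved ones. Heat kill is
phase-independent; under combined treatment the weighting applies to the
radiation factor only.

## Treatment dynamics

Each fraction draws one uniform N per non-senescent cell. Heat kill
(N > S_HT) removes the cell at delivery. Radiation kill (N above the
phase-weighted survival, within the band S_HT ≥ N > S_RTHT for combined
fractions) marks the cell doomed with absolute death time
now + Exponential(k_delay). Doomed cells keep cycling; all descendants
inherit the ancestor's death time, so a doomed lineage grows and then dies
as a unit. At M-phase exit a doomed cell undergoes mitotic catastrophe with
probability p_mitoticCat, becoming senescent with conditional probability
p_senescence (fate cleared to permanently viable non-divider) and otherwise
a giant cell — a single-voxel agent that stops producing daughters and
counts its further attempted divisions as a size field (the lattice
bookkeeping stays a strict one-cell-per-voxel bijection; multi-voxel giants
are not modelled). Senescent cells are never removed and are immune to
later fractions. A doomed or giant cell hit by a later fraction is
rescheduled only if the new draw implies an earlier death
(earliest-death-wins; configurable at the call site by pinning survivals).
An instantaneous-kill mode removes radiation-killed cells at delivery and
exists for the comparison experiments; delayed-kill populations dominate
instantaneous ones pointwise while deaths are pending (tested on paired
seeded runs).

Calibrated HCT116 dynamics: k_delay = 0.009 h⁻¹ (mean delay ≈ 111 h),
p_mitoticCat = 0.2, p_senescence = 0.05 (held fixed during fitting).

## Experiments, ensembles and calibration

`run_experiment` is bit-reproducible from (config, master seed); fractions
are delivered at the first step boundary at or after their scheduled time,
and a full compartment census (G1/S/G2/M/G0/doomed/senescent/giant/total)
is recorded at the sampling interval (default 1 h). `run_ensemble` spawns
independent child seeds and reports per-time mean and SD. Envelope runs pin
the radiation surviving fraction at the confidence bounds of a measured
value and re-run the ensemble. The heat-timing sweep attaches one heating
profile to different days of a fractionated course and summarizes each day
by the regrowth onset (first time after treatment end at which the mean
count exceeds its end-of-treatment value).

Calibration of (k_delay, p_mitoticCat) maximizes R² between the
ensemble-mean total and a reference curve (simulation linearly interpolated
at the reference times) over an exhaustive grid — deterministic, and the
full R² surface is returned for inspection. All grid points reuse the same
replicate seeds (common random numbers), so R² differences reflect the
parameters and an inert parameter pair yields an exactly flat surface,
which is flagged as unidentifiable. The synthetic reference generator
samples an ensemble mean at experiment-like times (default every 24 h) and
applies multiplicative Gaussian noise with a triplicate-style SD; it
emulates haemocytometer counts' sampling noise but not their systematic
errors (attachment losses, counting bias, medium-renewal effects), so
parameter-recovery results bound what calibration can do on clean data, not
on real assays.

## Problem sizes and replicate counts

Published-scale ensembles (hundreds of runs, 10⁶–10⁷ cells) are not needed
for the package's own verification. The defaults used by the test suite and
the acceptance script are desk-scale choices: 10 replicates for the
doubling-time estimate at full 24-well geometry (2.3 × 10⁴ founders,
96 h), toy wells of 100–400 voxel diameter for dynamics properties, 5×4
calibration grids with 2 replicates per point, and 10 seeded trials for
parameter recovery. Stochastic tolerances are stated per test (binomial
4 σ bounds, ±1 h on the doubling time).

## Known limitations

* Strict monolayer: no stacking, no 3-D/spheroid growth, no
  nutrient/oxygen transport; the plateau is purely geometric (carrying
  capacity = in-well voxel count), so the voxel size must be calibrated per
  plate type to reproduce measured plateau densities.
* No sub-lethal damage repair between fractions, no dose-rate effects, and
  no decay of thermal radiosensitization with RT–HT interval.
* Heat-arm parameters ship as synthetic placeholders (above).
* The solved γ range depends on the normalization convention; the constant
  ratio 1.5 is enforced exactly, but alternative normalizations (e.g.
  geometric-mean) would shift the exponent endpoints.
* Giant-cell geometry is a size counter, not physical multi-voxel
  occupancy, so confluent cultures rich in giant cells underestimate the
  area those cells cover.
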