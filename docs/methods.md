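# Methods

This note documents the models, conventions and design choices behind
`winotherm`, in the package's own words.

## Heat-balance theory

The theory module answers one question: *how fast could microbial
metabolism warm sediment in the best case?* It uses a zero-loss lumped
balance: a population of N cells per kg releasing q W each delivers a power
density p = q·N (W kg⁻¹) into sediment of specific heat c_s, so
dT/dt = p/c_s. Defaults: q = 0.8 pW (aerobic) and 0.2 pW (anaerobic) per
cell — literature calorimetry values for a well-characterized model
enterobacterium — and N = 5.725×10¹² cells kg⁻¹, chosen so that the aerobic
power density is exactly 4.58 W kg⁻¹ (the reference coefficient this
module is built to reproduce); both are configurable.

Two heat-capacity quantities coexist deliberately:

* `DEFAULT_CS_RANGE = (2880, 4180)` J kg⁻¹ °C⁻¹ — an externally supplied
  estimate for the wet sediment (62% water by mass), used for all rate
  ranges;
* `mixture_heat_capacity` — a mass-weighted water/solid mixture
  calculator for sensitivity analysis. It does **not** reproduce the
  default range from w = 0.62 and dry-solid capacities of 910–2400
  (it gives ≈2940–3510), so the two are kept separate rather than forcing
  an agreement the arithmetic does not support.

`prediction_report` compares its computed rate bounds, rounded to print
precision (1 decimal), against configurable reference bounds
(3.9–5.6 aerobic, 0.9–1.3 anaerobic °C h⁻¹) and lists each disagreement:
with the defaults the three bounds other than the aerobic minimum disagree
at the last printed digit (computed 5.7, 1.0, 1.4). The report flags this
rather than silently adopting either side.

Gravimetric water content uses oven-drying to constant mass: the sample is
dry at the first reading whose change is ≤ `convergence_delta`
(default 0.01 g — a precision-balance least count; the stopping rule is
otherwise qualitative). The estimator is invariant under tare shifts.

## Log dialect and validation

The native dialect is semicolon-separated text with one header row and
ISO-8601 naive local timestamps (the incubator's wall clock; the analysis
is phase-of-day based, so no timezone or DST arithmetic is attempted).
Header names map to canonical channel ids through an alias table
("Living Top", "T_LT", "living top" → `living_top`). Readings outside a
plausibility window (−10…60 °C, configurable; the incubator operates at
22–30 °C) are dropped and counted; rows with unparseable timestamps are
skipped and counted. Merging concatenates, sorts, deduplicates exact
timestamp collisions (first wins) and recomputes the gap report: a gap is
any index spacing exceeding 3× the nominal sampling period (60 s default).
Gaps are never interpolated — affected days simply contribute fewer samples.

A calendar day is a **valid measurement day** for a phase when the fraction
of expected samples present in that phase's window is ≥ `min_coverage`
(default 0.9: tolerates brief dropouts, excludes real interruptions; the
choice is a convention, the original rule being stated only qualitatively).

## Diel phases

The light program (ramp 07:00→08:00 up, constant to 00:00, dim to 1.9%
"moonlight" by 01:00) partitions the day into D1 08:00–15:30,
D2 15:30–24:00, N1 01:00–04:00, N2 04:00–07:00, with transitions
T1 00:00–01:00 and T2 07:00–08:00 excluded from analysis. Intervals are
half-open [start, end): a sample at exactly 15:30 is D2, at 08:00 is D1.
An end of "00:00" means 24:00 of the same day, so D2 belongs wholly to its
start date and every phase occurrence lies within one calendar day.
Durations: 450/510/180/180/60/60 minutes. Standard deviations use the n−1
denominator, reported as 0 for single-sample groups.

## Difference statistics

Aggregation is hierarchical everywhere: raw samples → per-day phase means →
phase boxplot statistics or month-level means over valid days. Pooling raw
samples would weight months with uneven coverage inconsistently. Quartiles
use linear interpolation between order statistics. Channel pairing snaps
timestamps to the nominal grid (round to nearest period) before
subtracting; unmatched samples are dropped and tallied. Useful identities,
enforced by tests: differences are invariant under common channel offsets,
and ΔT_Top − ΔT_Bott = ΔT_TB(living) − ΔT_TB(control) pointwise.

## Retention metrics

For an insulation event and each phase: the **baseline** is the mean of the
per-day phase means over the last `baseline_days` (default 3) valid days
whose phase window lies entirely before the wrap; **during** days are those
whose window overlaps the wrap, partially overlapped days contributing only
the overlapped portion's mean (subject to the same coverage fraction);
**post** days are the first `post_days` (default 3) valid days entirely
after it. Then ΔΔT = max(during means) − baseline and
ΔΔT_Steady = post mean − baseline. Windows are counted in *valid
phase-days*, skipping interrupted days rather than shrinking — all
statistics here are phase-resolved, so "three days" means three valid
occurrences of the phase. The daily-mean maximum (not a raw-sample maximum)
keeps ΔΔT from being noise-dominated. Both statistics are offset-invariant
and scale-equivariant. `precision_flag` classifies |value| against the
sensor quantization step (0.0625 °C), with exact equality reported as
`at-threshold`.

## Binned-frequency test

Temperature-difference samples are counted into 200 left-closed 0.01 °C
bins on [−1, +1) °C and normalized by the **total** sample count including
out-of-range values (which are tallied separately) — the normalization
follows the procedure's stated wording. The two 200-element frequency
vectors are then compared with a two-sided Mann–Whitney U test (exact when
both sides have ≤ 20 tie-free observations — never the case for full
vectors — otherwise the tie-corrected normal approximation; the method used
is recorded).

This procedure is statistically unconventional and the package documents
its actual behavior rather than an assumed one: because the test compares
the *multiset of frequency values*, a pure location shift — identical
histogram translated along the temperature axis — leaves the vector values
unchanged and is **invisible** to the binned test, while spread/shape
differences change the frequency values and are detected strongly. The
companion `mwu_raw` (standard rank test on the raw samples) sees location
shifts immediately but inherits the autocorrelation problem that motivated
binning in the first place. Both results should always be reported
together; a binned/raw disagreement usually means "location difference,
same shape".

## Simulator

Two nodes per column (matching the two embedded probes; finer spatial
discretization would not be observable), explicit-Euler integration at a
fixed step (default 30 s) with an automatic stability guard
(dt ≤ 0.1 × min C/K). Cumulative per-node energy input is accumulated with
the same discrete fluxes, so C·ΔT equals the integrated flux identically —
the energy-closure test checks bookkeeping, not a numerical coincidence.

Default physical parameters, chosen as plausible for the apparatus and
fixed once: node mass ≈ 0.13 kg (half of ~200 mL wet sediment at
~1.3 kg L⁻¹) at c_s = 3200 J kg⁻¹ °C⁻¹ → C = 416 J °C⁻¹ per node;
conductances K_ext,top = 0.15, K_ext,bottom = 0.10, K_int = 0.05,
K_base = 0.10 W °C⁻¹, giving node time constants of ~20–35 min — the same
order as the observed thermal lag of columns behind incubator transitions.
Insulation events multiply both K_ext by their `conduct_scale` while
leaving K_base intact, so night-time heat loss through the uninsulated
column base remains in effect.

The incubator trace follows the light program through a first-order
response (τ = 20 min) plus white process noise scaled to a stationary SD of
`noise_sd`, clipped to the 22–30 °C band. Sensor channels add per-channel
offsets (bounded by the ±0.5 °C accuracy spec) and Gaussian read noise
(default 0.05 °C), then quantize to 0.0625 °C (12-bit step); the ambient
reference uses a finer 0.01 °C step. Logging gaps can be scripted intervals
or a Poisson rate of fixed-length dropouts.

A consequence of the two different node time constants (the bottom node has
the extra base-loss path) is that rapid forcing transitions induce a
transient apparent top-bottom gradient in *both* columns — e.g. ≈+0.24 °C
in N1 after the sundown cooling step with the default parameters. This
reproduces the thermal-inertia caveat of real columns and is why the
detection statistic is the living-minus-control gradient difference, in
which the shared transient cancels, rather than the living gradient alone.

`scenario_default` calibrates the living column's light-modulated
top-node source in closed form so the steady D2 internal-gradient excess
over the control equals a target (default 0.25 °C, a deliberately
scaled-down stand-in for the measured sub-degree daytime contrast), plus a
small constant 4 mW bottom source. Defaults set all sensor offsets to zero
and noise to 0.05 °C: the noise dithers the quantizer (σ ≈ 0.8× the step,
making the daily-mean quantization bias negligible) and keeps the
zero-source null comparison centered — per-channel offsets are a supported
feature for offset-sensitivity studies, not part of the default detection
scenario.

### What the generator does and does not emulate

Emulated: diurnal forcing with thermal lag, localized light-coupled heat
injection, per-sensor offsets, read noise, quantization, logging gaps,
insulation-induced retention, external-reference disturbance spikes.
Not emulated: microbial population dynamics (sources are fixed profiles,
not growth curves), spatially continuous gradients, evaporation and
sediment shrinkage, slow community drift between columns. Passing tests on
synthetic data therefore demonstrate that the *pipeline* recovers known
injected effects under realistic noise — not that any particular measured
record contains such effects.

## Problem sizes

Tests and the acceptance script use 1–10-day simulations at 60 s sampling
(≈1.4k samples/day/channel) and a 20-day run spanning a month boundary for
the monthly-aggregate workflow; these sizes put the detection signal
(~0.24 °C daily-mean excess vs ~0.005 °C daily-mean noise) far from the
decision boundary, so longer runs add nothing but runtime.

## Known limitations

* The lumped two-node model cannot represent radial gradients or the
  water column above the sediment; K values are effective, not physical
  material constants.
* The binned-test normalization (denominator includes out-of-range
  samples) makes frequency vectors from datasets with different
  out-of-range fractions subtly incomparable; `n_outside` is always
  reported so this is visible.
* Valid-day accounting is per phase; a day can be valid for N1 and invalid
  for D1, which is intended but can surprise when comparing counts across
  phases.
* Exact Mann–Whitney p-values require tie-free data; quantized temperature
  differences are full of ties, so realistic comparisons always use the
  tie-corrected normal approximation.
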