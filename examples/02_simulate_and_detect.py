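"""Simulate a week of logging and detect the living column's heat source.

Runs the default two-column scenario (light-modulated top-node source in
the living column, source-free control), then compares the per-day D2
internal top-to-bottom gradients of the two columns.
"""

from winotherm.diffstats import difference_series, per_day_phase_means
from winotherm.simulate import scenario_default, simulate

result = simulate(scenario_default(duration_days=7.0, seed=1))
print(f"simulated {len(result.dataset)} records on channels {result.dataset.channels}")

living = per_day_phase_means(
    difference_series(result.dataset, "dT_TB_int_living"), min_coverage=0.9
)
control = per_day_phase_means(
    difference_series(result.dataset, "dT_TB_int_control"), min_coverage=0.9
)
l = living[living["phase"] == "D2"].set_index("day")
c = control[control["phase"] == "D2"].set_index("day")

print("day          living dT_TB  control dT_TB  excess")
for day in l.index:
    excess = l.loc[day, "mean"] - c.loc[day, "mean"]
    print(f"{day}   {l.loc[day, 'mean']:+.4f}      {c.loc[day, 'mean']:+.4f}       {excess:+.4f}")

# The living column's internal gradient exceeds the control's by ~0.24 degC
# on every day: the light-modulated source warms the upper sediment node.
# The per-sample noise (0.05 degC) averages out over the 510 D2 samples/day.
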