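"""Insulation experiment: temperature retention statistics.

Simulates ten days with a 24-h foil wrap (external conductances scaled to
25%), then computes the phase-resolved retention metrics on the top-region
living-minus-control difference and flags them against sensor precision.
"""

from datetime import datetime

from winotherm.apparatus import DS18B20
from winotherm.diffstats import difference_series
from winotherm.retention import InsulationEvent, flag_result, retention_stats
from winotherm.simulate import scenario_default, simulate

event = InsulationEvent(
    start=datetime(2022, 4, 5, 9, 0), end=datetime(2022, 4, 6, 9, 0),
    wrap="foil", conduct_scale=0.25,
)
result = simulate(scenario_default(duration_days=10.0, seed=2, insulation=[event]))

series = difference_series(result.dataset, "dT_top")
print("phase  ddT (degC)  ddT_steady (degC)  flags")
for phase, r in retention_stats(series, event).items():
    flags = flag_result(r, DS18B20)
    print(
        f"{phase:5s}  {r.delta_delta:+.4f}     {r.delta_delta_steady:+.4f}          "
        f"{flags['delta_delta']}/{flags['delta_delta_steady']}"
    )

# ddT rises well above the 0.0625 degC precision line during the lit phases:
# wrapping the columns suppresses external losses, so the living column's
# source-driven temperature excess grows.  Once the wrap is removed the
# difference relaxes back, so ddT_steady stays below precision.
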