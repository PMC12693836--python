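"""Binned-frequency vs raw-sample Mann-Whitney comparison.

Bins the living and control internal-gradient samples of a simulated week
into 0.01 degC intervals on [-1, +1) and compares the two 200-element
relative-frequency vectors with a two-sided Mann-Whitney U test, alongside
the standard rank test on the raw samples.
"""

from winotherm.diffstats import difference_series
from winotherm.disttest import bin_differences, mwu_binned, mwu_raw
from winotherm.simulate import scenario_default, simulate

result = simulate(scenario_default(duration_days=7.0, seed=1))
a = difference_series(result.dataset, "dT_TB_int_living").samples.to_numpy()
b = difference_series(result.dataset, "dT_TB_int_control").samples.to_numpy()

ba, bb = bin_differences(a), bin_differences(b)
print(f"living:  {ba.n_total} samples, {ba.n_outside} outside [-1, 1)")
print(f"control: {bb.n_total} samples, {bb.n_outside} outside [-1, 1)")

binned = mwu_binned(ba, bb)
raw = mwu_raw(a, b)
print(f"binned frequencies: U={binned.U:.0f}, p={binned.p_value:.3g} ({binned.method})")
print(f"raw samples:        U={raw.U:.0f}, p={raw.p_value:.3g} ({raw.method})")

# The two procedures answer different questions.  The raw rank test sees
# the ~0.24 degC location shift immediately (p ~ 0).  The binned test
# compares the *values* of the two frequency vectors and is blind to a pure
# translation of the histogram, so its p-value stays large here; it reacts
# to shape (spread) differences instead.  Report both.
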