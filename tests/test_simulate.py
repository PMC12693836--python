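import io
from datetime import datetime, timedelta

import numpy as np
import pytest

from winotherm.apparatus import IlluminationSpec
from winotherm.errors import ConfigurationError, StabilityError
from winotherm.logio import write_log
from winotherm.retention import InsulationEvent
from winotherm.simulate import (
    ColumnSimConfig,
    ColumnThermalModel,
    HeatSource,
    IncubatorForcing,
    SensorModel,
    scenario_default,
    simulate,
    source_power_for_gradient_excess,
)

CONSTANT_LIGHT = IlluminationSpec(schedule=((0.0, 1.0), (24.0, 1.0)))
CONSTANT_FORCING = IncubatorForcing(
    base_temp=25.0, amplitude=0.0, schedule=CONSTANT_LIGHT, noise_sd=0.0
)
QUIET_SENSORS = SensorModel(noise_sd=0.0)


def single_node_model(k_ext=0.05, power=0.0, capacity=416.0):
    """Top node coupled only to the incubator; bottom node inert."""
    return ColumnThermalModel(
        heat_capacity={"top": capacity, "bottom": capacity},
        conduct_ext={"top": k_ext, "bottom": 0.1},
        conduct_int=0.0,
        base_loss=0.0,
        sources={"top": HeatSource(power), "bottom": HeatSource()},
    )


class TestPhysics:
    def test_equilibrium_without_sources(self):
        cfg = ColumnSimConfig(duration_days=1.0, forcing=CONSTANT_FORCING,
                              sensors=QUIET_SENSORS, seed=0)
        res = simulate(cfg)
        for ch in res.dataset.frame.columns:
            assert np.all(np.abs(res.dataset.frame[ch] - 25.0) <= 0.0625), ch

    def test_steady_state_offset_is_power_over_conductance(self):
        cfg = ColumnSimConfig(
            duration_days=2.0, forcing=CONSTANT_FORCING,
            living=single_node_model(k_ext=0.05, power=0.01),
            sensors=QUIET_SENSORS, seed=0,
        )
        res = simulate(cfg)
        offset = res.truth["living_top"].iloc[-1] - res.truth["incubator"].iloc[-1]
        assert offset == pytest.approx(0.01 / 0.05, rel=5e-3)

    def test_decoupled_node_heats_at_theoretical_rate(self):
        """With K = 0, dT/dt = P/C reproduces the loss-free heating-rate law."""
        model = ColumnThermalModel(
            heat_capacity={"top": 3200.0, "bottom": 3200.0},  # 1 kg at c_s = 3200
            conduct_ext={"top": 0.0, "bottom": 0.0}, conduct_int=0.0, base_loss=0.0,
            sources={"top": HeatSource(4.58), "bottom": HeatSource()},
        )
        cfg = ColumnSimConfig(duration_days=1.0 / 24.0, forcing=CONSTANT_FORCING,
                              living=model, sensors=QUIET_SENSORS, seed=0)
        res = simulate(cfg)
        rise = res.truth["living_top"].iloc[-1] - res.truth["living_top"].iloc[0]
        assert rise == pytest.approx(4.58 / 3200.0 * 3600.0, rel=1e-3)

    def test_energy_bookkeeping_closes(self, default_sim):
        tr = default_sim.truth
        C = default_sim.config.living.heat_capacity["top"]
        lhs = C * (tr["living_top"].iloc[-1] - tr["living_top"].iloc[0])
        assert lhs == pytest.approx(tr["E_living_top"].iloc[-1], rel=1e-3, abs=1e-6)

    def test_exponential_relaxation_matches_analytic_solution(self):
        k, c = 0.05, 416.0
        model = single_node_model(k_ext=k, capacity=c)
        model = ColumnThermalModel(
            heat_capacity=model.heat_capacity, conduct_ext=model.conduct_ext,
            conduct_int=0.0, base_loss=0.0, sources=model.sources,
            initial_temps={"top": 20.0, "bottom": 25.0},
        )
        cfg = ColumnSimConfig(duration_days=0.5, forcing=CONSTANT_FORCING,
                              living=model, sensors=QUIET_SENSORS, seed=0, dt=30.0)
        res = simulate(cfg)
        t = np.arange(len(res.truth)) * 60.0
        analytic = 25.0 - 5.0 * np.exp(-k * t / c)
        err = np.abs(res.truth["living_top"].to_numpy() - analytic)
        assert err.max() < 0.005 * 5.0  # < 0.5% of the step size

    def test_thermal_lag_behind_incubator_forcing(self, default_sim):
        """Columns respond to the diurnal forcing with a strictly positive lag."""
        tr = default_sim.truth
        inc = tr["incubator"].to_numpy() - tr["incubator"].mean()
        top = tr["living_bottom"].to_numpy() - tr["living_bottom"].mean()
        max_lag = 240  # samples of 60 s = 4 h
        corrs = [
            np.corrcoef(inc[: len(inc) - lag], top[lag:])[0, 1]
            for lag in range(max_lag)
        ]
        assert int(np.argmax(corrs)) > 0

    def test_insulation_event_raises_source_driven_difference(self):
        ev = InsulationEvent(start=datetime(2022, 4, 4), end=datetime(2022, 4, 5),
                             conduct_scale=0.25)
        cfg = scenario_default(duration_days=7.0, seed=4, insulation=[ev])
        res = simulate(cfg)
        tr = res.truth
        d_top = tr["living_top"] - tr["control_top"]
        during = d_top[(tr.index >= ev.start) & (tr.index < ev.end)].mean()
        before = d_top[tr.index < ev.start].mean()
        assert during > before


class TestObservationModel:
    def test_quantization_to_exact_multiples(self, default_sim):
        res = default_sim.dataset.frame
        for ch in ("living_top", "living_bottom", "control_top", "control_bottom"):
            vals = res[ch].to_numpy()
            assert np.allclose(np.round(vals / 0.0625) * 0.0625, vals, atol=1e-12)

    def test_identical_seed_gives_bit_identical_logs(self):
        buffers = []
        for _ in range(2):
            res = simulate(scenario_default(duration_days=1.0, seed=7))
            buf = io.StringIO()
            write_log(res.dataset, buf)
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]

    def test_different_seeds_differ(self):
        a = simulate(scenario_default(duration_days=1.0, seed=1))
        b = simulate(scenario_default(duration_days=1.0, seed=2))
        assert not a.dataset.frame.equals(b.dataset.frame)

    def test_sensor_offsets_shift_readings(self):
        sensors = SensorModel(noise_sd=0.0, offsets={"living_top": 0.25})
        cfg = ColumnSimConfig(duration_days=0.5, forcing=CONSTANT_FORCING,
                              sensors=sensors, seed=0)
        res = simulate(cfg)
        assert res.dataset.frame["living_top"].mean() == pytest.approx(25.25, abs=0.04)
        assert res.dataset.frame["control_top"].mean() == pytest.approx(25.0, abs=0.04)

    def test_scripted_dropout_creates_gap(self):
        g0 = datetime(2022, 4, 1, 6, 0)
        g1 = datetime(2022, 4, 1, 9, 0)
        sensors = SensorModel(noise_sd=0.0, dropout=((g0, g1),))
        cfg = ColumnSimConfig(duration_days=1.0, forcing=CONSTANT_FORCING,
                              sensors=sensors, seed=0)
        res = simulate(cfg)
        gaps = res.dataset.gap_report
        assert len(gaps) == 1
        assert gaps[0][0] < g0 + timedelta(minutes=1)
        assert gaps[0][1] == g1


class TestConfigValidation:
    def test_unstable_step_rejected_with_suggestion(self):
        model = single_node_model(k_ext=5.0, capacity=100.0)  # tau = 20 s
        with pytest.raises(StabilityError, match="dt <="):
            simulate(ColumnSimConfig(duration_days=0.1, forcing=CONSTANT_FORCING,
                                     living=model, sensors=QUIET_SENSORS, seed=0, dt=30.0))

    def test_control_sources_forbidden(self):
        hot_control = single_node_model(power=0.01)
        with pytest.raises(ConfigurationError, match="control"):
            ColumnSimConfig(duration_days=1.0, control=hot_control)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ConfigurationError):
            ColumnThermalModel(conduct_ext={"top": -0.1, "bottom": 0.1})


class TestDefaultScenario:
    def test_calibration_formula_hits_target_steady_gradient(self):
        model = ColumnThermalModel()
        p = source_power_for_gradient_excess(model, 0.25)
        cfg = ColumnSimConfig(
            duration_days=2.0, forcing=CONSTANT_FORCING,
            living=ColumnThermalModel(sources={"top": HeatSource(p), "bottom": HeatSource()}),
            sensors=QUIET_SENSORS, seed=0,
        )
        res = simulate(cfg)
        grad = (res.truth["living_top"] - res.truth["living_bottom"]).iloc[-1]
        assert grad == pytest.approx(0.25, rel=1e-3)

    def test_default_scenario_stays_inside_incubator_band(self, default_sim):
        inc = default_sim.truth["incubator"]
        assert inc.min() >= 22.0 and inc.max() <= 30.0
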