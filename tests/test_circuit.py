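import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, strategies as st

from pvloopva import (
    ModelState,
    default_config,
    initial_state,
    run_to_steady_state,
    simulate,
    state_derivative,
    total_blood_volume,
    valve_flow,
)
from pvloopva.config import CHAMBER_NAMES, COMPARTMENT_NAMES


class TestValveFlow:
    def test_open_valve_is_ohmic(self):
        assert valve_flow(100.0, 80.0, 0.01) == pytest.approx(2000.0)

    def test_reverse_gradient_closes(self):
        assert valve_flow(80.0, 100.0, 0.01) == 0.0

    def test_zero_gradient_zero_flow(self):
        assert valve_flow(90.0, 90.0, 0.005) == 0.0

    def test_invalid_resistance_rejected(self):
        with pytest.raises(ValueError):
            valve_flow(100.0, 80.0, 0.0)

    @given(st.floats(-200, 300), st.floats(-200, 300),
           st.floats(1e-4, 10.0))
    def test_never_retrograde(self, pu, pd, r):
        assert valve_flow(pu, pd, r) >= 0.0


def _state_at_pressure(config, p: float) -> ModelState:
    """All compartments and chambers at the same (diastolic) pressure."""
    comp = {c.name: c.unstressed_volume + c.compliance * p
            for c in config.compartments}
    cham = {n: config.chambers[n].V0_chamber + p / config.chambers[n].E_min
            for n in CHAMBER_NAMES}
    return ModelState(chamber_volumes=cham, compartment_volumes=comp)


class TestStateDerivative:
    def test_equal_pressures_in_diastole_give_zero_rates(self):
        # at 60 bpm both ventricular and atrial activation are zero at 0.82 T
        config = default_config(60.0)
        state = _state_at_pressure(config, 6.0)
        dy = state_derivative(state, 0.82, config)
        np.testing.assert_allclose(dy, 0.0, atol=1e-9)

    def test_single_pressure_gradient_gives_ohmic_transfer(self):
        config = default_config(60.0)
        state = _state_at_pressure(config, 6.0)
        tvn = config.compartment("thoracic_vein")
        dp = 10.0
        vols = dict(state.compartment_volumes)
        vols["thoracic_vein"] += tvn.compliance * dp
        state = ModelState(state.chamber_volumes, vols)
        dy = state_derivative(state, 0.82, config)
        i_ra = list(CHAMBER_NAMES).index("right_atrium")
        # thoracic vein drains into the right atrium and back up the vein
        assert dy[i_ra] == pytest.approx(dp / tvn.resistance_out, rel=1e-9)

    def test_rates_sum_to_zero_for_random_states(self):
        config = default_config(80.0)
        rng = np.random.default_rng(42)
        base = initial_state(config).to_vector()
        for t in rng.uniform(0, 10, size=20):
            y = base * rng.uniform(0.5, 1.5, size=base.size)
            dy = state_derivative(ModelState.from_vector(y), float(t), config)
            assert abs(dy.sum()) < 1e-9 * np.abs(dy).sum() + 1e-12

    def test_non_finite_state_raises_diagnostic(self):
        config = default_config(80.0)
        y = initial_state(config).to_vector()
        y[5] = np.nan
        with pytest.raises(FloatingPointError, match="systemic_artery"):
            state_derivative(ModelState.from_vector(y), 0.0, config)


class TestTotalBloodVolume:
    def test_sums_chambers_and_compartments(self):
        config = default_config(80.0)
        st_ = initial_state(config)
        assert total_blood_volume(st_) == pytest.approx(config.total_blood_volume)

    def test_simple_sum(self):
        s = ModelState(
            chamber_volumes=dict.fromkeys(CHAMBER_NAMES, 10.0),
            compartment_volumes=dict.fromkeys(COMPARTMENT_NAMES, 20.0))
        assert total_blood_volume(s) == 4 * 10 + 11 * 20


class TestSimulate:
    def test_volume_conserved_and_pressures_finite(self):
        config = default_config(80.0)
        ts = simulate(config, 15.0)
        v0 = config.total_blood_volume
        drift = abs(total_blood_volume(ts.final_state) - v0) / v0
        assert drift < 1e-3 * 15.0 / 60.0  # < 0.1% per simulated minute
        assert np.all(np.isfinite(ts.p_ao)) and np.all(np.isfinite(ts.p_lv))

    def test_valve_flows_never_retrograde(self):
        ts = simulate(default_config(80.0), 3.0)
        assert ts.q_av.min() >= 0.0
        assert ts.q_mv.min() >= 0.0

    def test_compartment_pressures_consistent_with_final_volumes(self):
        config = default_config(80.0)
        ts = simulate(config, 2.0)
        for c in config.compartments:
            v = ts.final_state.compartment_volumes[c.name]
            assert ts.compartment_pressures[c.name][-1] == pytest.approx(
                (v - c.unstressed_volume) / c.compliance, rel=1e-9)

    def test_constant_elastance_relaxes_to_equilibrium(self):
        config = default_config(80.0)
        chambers = {n: replace(ch, E_max=ch.E_min * (1 + 1e-9))
                    for n, ch in config.chambers.items()}
        config = replace(config, chambers=chambers)
        ts = simulate(config, 25.0)
        last = ts.time > ts.time[-1] - 1.0
        assert np.max(np.abs(ts.q_av[last])) < 0.5
        arterial = [ts.compartment_pressures[n][last] for n in
                    ("aortic_arch", "systemic_artery")]
        assert abs(arterial[0].mean() - arterial[1].mean()) < 1.0

    def test_rc_limit_matches_exponential_closed_form(self):
        """A charged arch draining into a near-infinite sink decays as exp(-t/RC)."""
        config = default_config(80.0)
        comps = []
        for c in config.compartments:
            if c.name == "aortic_arch":
                c = replace(c, compliance=0.5, resistance_out=2.0)
            elif c.name == "systemic_artery":
                c = replace(c, compliance=1e6)
            elif c.resistance_in > 0:
                c = replace(c, resistance_in=1e9, resistance_out=1e9)
            comps.append(c)
        config = replace(config, compartments=tuple(comps))
        # chambers at unstressed volume (zero pressure, valves shut), veins at
        # unstressed volume, arch charged to 50 mmHg above the sink
        cham = {n: config.chambers[n].V0_chamber for n in CHAMBER_NAMES}
        comp = {c.name: c.unstressed_volume for c in config.compartments}
        p0 = 50.0
        comp["aortic_arch"] += 0.5 * p0
        state = ModelState(cham, comp)
        config = replace(config, total_blood_volume=total_blood_volume(state))
        ts = simulate(config, 3.0, initial=state)
        c1, c2, r = 0.5, 1e6, 2.0
        tau = r * (c1 * c2 / (c1 + c2))
        p_inf = p0 * c1 / (c1 + c2)
        expected = p_inf + (p0 - p_inf) * np.exp(-ts.time / tau)
        observed = ts.compartment_pressures["aortic_arch"]
        assert np.max(np.abs(observed - expected)) / p0 < 0.005
        # 63.2% of the excess discharged at t = RC
        i = np.argmin(np.abs(ts.time - tau))
        assert observed[i] / p0 == pytest.approx(np.exp(-1), abs=0.005)


class TestRunToSteadyState:
    def test_normal_converges_well_before_maximum(self, normal_steady):
        ts, _ = normal_steady
        assert ts.steady_state.converged
        assert ts.steady_state.duration < 180.0

    def test_restart_from_steady_state_converges_within_six_beats(self, normal_steady):
        _, state = normal_steady
        ts, _ = run_to_steady_state(default_config(80.0), initial=state)
        assert ts.steady_state.converged
        assert ts.steady_state.n_beats <= 6

    def test_steady_lv_volume_is_periodic(self, normal_steady):
        ts, _ = normal_steady
        period = default_config(80.0).beat_period
        n = int(round(period * 1000))
        tail, prev = ts.v_lv[-n:], ts.v_lv[-2 * n:-n]
        assert np.max(np.abs(tail - prev)) < 0.5  # ml

    def test_non_convergence_is_flagged_not_fatal(self):
        ts, _ = run_to_steady_state(default_config(80.0), max_duration=1.5)
        assert not ts.steady_state.converged
        assert "maximum duration" in ts.steady_state.criterion


class TestConfigSerialization:
    def test_yaml_round_trip_preserves_every_parameter(self, tmp_path):
        config = default_config(80.0)
        path = tmp_path / "model.yaml"
        config.to_yaml(path)
        from pvloopva import ModelConfig
        assert ModelConfig.from_yaml(path) == config

    def test_rt_and_ca_match_packaged_normal_setting(self):
        config = default_config(80.0)
        assert config.arterial_compliance == pytest.approx(0.70, rel=1e-9)
        assert config.total_peripheral_resistance == pytest.approx(1.28, rel=1e-9)
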