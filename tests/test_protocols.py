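import numpy as np
import pytest
from hypothesis import given, strategies as st

from pvloopva import (
    COMPLIANCE_LEVELS,
    VcoParams,
    apply_vascular_scaling,
    compliance_setting,
    default_config,
    vco_resistance,
)


class TestComplianceSettings:
    def test_all_five_pairs_frozen(self):
        expected = {
            "normal": (0.70, 1.28),
            "90pct": (0.63, 1.41),
            "80pct": (0.56, 1.54),
            "60pct": (0.42, 1.805),
            "stiff": (0.19, 3.66),
        }
        assert set(COMPLIANCE_LEVELS) == set(expected)
        for level, (ca, rt) in expected.items():
            s = compliance_setting(level)
            assert (s.C_A, s.R_T) == (ca, rt)

    def test_unknown_level_lists_valid_labels(self):
        with pytest.raises(ValueError, match="normal"):
            compliance_setting("rigid")


class TestVascularScaling:
    def test_identity_when_already_on_target(self):
        config = default_config(80.0)
        same = apply_vascular_scaling(config, compliance_setting("normal"))
        for a, b in zip(config.compartments, same.compartments):
            assert b.compliance == pytest.approx(a.compliance, rel=1e-12)
            assert b.resistance_out == pytest.approx(a.resistance_out, rel=1e-12)

    def test_equivalents_hit_target_exactly(self):
        config = default_config(80.0)
        for level in COMPLIANCE_LEVELS:
            s = compliance_setting(level)
            scaled = apply_vascular_scaling(config, s)
            assert scaled.arterial_compliance == pytest.approx(s.C_A, rel=1e-9)
            assert scaled.total_peripheral_resistance == pytest.approx(s.R_T, rel=1e-9)

    def test_halving_target_halves_every_arterial_compliance(self):
        from pvloopva.protocols import ComplianceSetting
        config = default_config(80.0)
        target = ComplianceSetting("half", config.arterial_compliance / 2,
                                   config.total_peripheral_resistance)
        scaled = apply_vascular_scaling(config, target)
        from pvloopva.config import ARTERIAL_COMPARTMENTS
        for a, b in zip(config.compartments, scaled.compartments):
            if a.name in ARTERIAL_COMPARTMENTS:
                assert b.compliance == pytest.approx(a.compliance / 2, rel=1e-9)
            else:
                assert b.compliance == a.compliance

    def test_idempotent_and_order_independent(self):
        config = default_config(80.0)
        stiff = compliance_setting("stiff")
        once = apply_vascular_scaling(config, stiff)
        twice = apply_vascular_scaling(once, stiff)
        via_other = apply_vascular_scaling(
            apply_vascular_scaling(config, compliance_setting("60pct")), stiff)
        for a, b, c in zip(once.compartments, twice.compartments, via_other.compartments):
            assert b.compliance == pytest.approx(a.compliance, rel=1e-9)
            assert c.compliance == pytest.approx(a.compliance, rel=1e-9)
            assert b.resistance_out == pytest.approx(a.resistance_out, rel=1e-9)
            assert c.resistance_out == pytest.approx(a.resistance_out, rel=1e-9)


class TestVcoResistance:
    def test_before_start_is_baseline(self):
        p = VcoParams(start_time=5.0)
        assert vco_resistance(2.0, p, 0.025) == 0.025

    def test_after_ramp_is_multiplied(self):
        p = VcoParams(start_time=5.0, ramp_duration=8.0, resistance_multiplier=100.0)
        assert vco_resistance(13.0, p, 0.025) == pytest.approx(2.5)
        assert vco_resistance(60.0, p, 0.025) == pytest.approx(2.5)

    def test_exponential_midpoint_is_geometric_mean(self):
        p = VcoParams(start_time=0.0, ramp_duration=8.0, resistance_multiplier=100.0)
        assert vco_resistance(4.0, p, 1.0) == pytest.approx(10.0)

    def test_linear_midpoint_is_arithmetic_mean(self):
        p = VcoParams(start_time=0.0, ramp_duration=8.0,
                      resistance_multiplier=100.0, profile="linear")
        assert vco_resistance(4.0, p, 1.0) == pytest.approx(50.5)

    @given(st.floats(0, 30), st.floats(0, 30))
    def test_monotone_non_decreasing(self, t1, t2):
        p = VcoParams(start_time=2.0, ramp_duration=8.0, resistance_multiplier=100.0)
        lo, hi = sorted((t1, t2))
        assert vco_resistance(lo, p, 1.0) <= vco_resistance(hi, p, 1.0) + 1e-12

    def test_small_multiplier_warns(self):
        with pytest.warns(UserWarning, match="falling preload"):
            VcoParams(resistance_multiplier=1.0)


class TestVcoExperiment:
    def test_edv_strictly_decreasing_under_occlusion(self, normal_vco_ts):
        from pvloopva.relations import harvest_vco_beats
        _, family = harvest_vco_beats(normal_vco_ts, 80.0, edv_fall_fraction=1.0)
        edv = [float(b.v_lv[0]) for b in family]
        drops = np.diff(edv[:9])
        assert len(drops) >= 8
        assert np.all(drops < 0)

    def test_null_occlusion_leaves_beats_unchanged(self):
        import warnings
        from pvloopva import run_vco_experiment
        from pvloopva.relations import harvest_vco_beats
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts = run_vco_experiment(
                compliance_setting("normal"), 80.0,
                vco=VcoParams(resistance_multiplier=1.0), vco_window=4.0)
            _, family = harvest_vco_beats(ts, 80.0, edv_fall_fraction=1.0)
        edv = [float(b.v_lv[0]) for b in family]
        assert max(edv) - min(edv) < 0.5

    def test_stiff_first_beat_pes_exceeds_normal(self, phase1_table):
        t = phase1_table.set_index("level")
        assert t.at["stiff", "Pes_mmHg"] > t.at["normal", "Pes_mmHg"]


class TestStudyTables:
    def test_phase1_shape_and_levels(self, phase1_table):
        assert len(phase1_table) == 5
        assert list(phase1_table["level"]) == list(COMPLIANCE_LEVELS)
        assert phase1_table["error"].isna().all()

    def test_phase2_shape(self, phase2_table):
        assert len(phase2_table) == 6
        assert set(phase2_table["level"]) == {"normal", "stiff"}
        assert sorted(set(phase2_table["heart_rate"])) == [60.0, 100.0, 140.0]
        assert phase2_table["error"].isna().all()

    def test_phase1_pp_and_me_monotone(self, phase1_table):
        pp = phase1_table["PP_mmHg"].to_numpy(float)
        me = phase1_table["ME_pct"].to_numpy(float)
        assert np.all(np.diff(pp) > 0)
        assert np.all(np.diff(me) < 0)

    def test_phase2_edv_and_me_fall_with_rate(self, phase2_table):
        for level in ("normal", "stiff"):
            sub = phase2_table[phase2_table["level"] == level].sort_values("heart_rate")
            assert np.all(np.diff(sub["EDV_ml"].to_numpy(float)) < 0)
            assert np.all(np.diff(sub["ME_pct"].to_numpy(float)) < 0)
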