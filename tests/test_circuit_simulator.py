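"""Steady-state solver, protocol schedules and the measurement noise model."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from fickflow.circuit_simulator import (
    CircuitConfig,
    GasContents,
    OverVentilationError,
    apply_measurement_noise,
    capnometer_sd,
    measurement_record,
    oxygenator_exchange,
    records_from_protocol,
    run_protocol,
    solve_steady_state,
)
from fickflow.gas_content import normalization_constant
from fickflow.vq_normalization import VqPoint, normalize_vco2, vq_correction_factor


class TestOxygenatorExchange:
    def test_unit_vq_measures_reference(self, baseline_config):
        c_in = GasContents(cco2=46.0, co2=11.0)
        _, vco2, _ = oxygenator_exchange(2000.0, 2000.0, c_in, baseline_config)
        assert vco2 == pytest.approx(2000.0 * 5.0 / 100.0, rel=1e-12)

    def test_high_vq_eliminates_more(self, baseline_config):
        c_in = GasContents(cco2=46.0, co2=11.0)
        _, ref, _ = oxygenator_exchange(500.0, 500.0, c_in, baseline_config)
        _, high, _ = oxygenator_exchange(500.0, 1500.0, c_in, baseline_config)
        assert high > ref

    def test_normalization_closure(self, baseline_config):
        c_in = GasContents(cco2=46.0, co2=11.0)
        _, vco2, _ = oxygenator_exchange(500.0, 1500.0, c_in, baseline_config)
        c = normalization_constant(baseline_config.ph_venous,
                                   baseline_config.temp).c
        back = normalize_vco2(vco2, VqPoint(v=1500.0, q=500.0, c=c))
        assert back == pytest.approx(500.0 * 5.0 / 100.0, rel=1e-12)

    def test_over_ventilation_fails(self, baseline_config):
        c_in = GasContents(cco2=2.0, co2=11.0)
        with pytest.raises(OverVentilationError):
            oxygenator_exchange(100.0, 5000.0, c_in, baseline_config,
                                delta_ref=20.0)


class TestSteadyState:
    def test_conservation_at_baseline(self, baseline_state, baseline_config):
        st = baseline_state
        assert st.converged
        assert st.vco2_lung + st.vco2_ecmo == pytest.approx(
            baseline_config.resolved_chamber_vco2(), abs=1e-6)
        assert st.vo2_lung + st.vo2_ecmo == pytest.approx(
            baseline_config.chamber_vo2, abs=1e-6)

    def test_conservation_random_sweep(self):
        """Flow and exchange conservation over 200 random configurations."""
        rng = np.random.default_rng(20240817)
        checked = 0
        while checked < 200:
            q_e = rng.uniform(400.0, 3000.0)
            q_l = rng.uniform(100.0, 2500.0)
            cfg = CircuitConfig(
                q_ecmo=q_e, q_lung=q_l,
                shunt=rng.uniform(0.0, 0.9),
                v_ecmo=q_e * rng.uniform(0.5, 3.0),
                v_lung=rng.uniform(800.0, 2000.0),
                chamber_vco2=rng.uniform(60.0, 220.0),
                chamber_vo2=rng.uniform(20.0, 60.0),
            )
            try:
                st = solve_steady_state(cfg)
            except OverVentilationError:
                continue
            assert cfg.q_total == cfg.q_ecmo + cfg.q_lung
            assert st.vco2_lung + st.vco2_ecmo \
                == pytest.approx(cfg.resolved_chamber_vco2(), abs=1e-6)
            assert st.vo2_lung + st.vo2_ecmo \
                == pytest.approx(cfg.chamber_vo2, abs=1e-6)
            assert all(c.cco2 >= 0 and c.co2 >= 0
                       for c in st.contents.values())
            checked += 1

    def test_no_chamber_means_no_exchange(self, baseline_config):
        cfg = replace(baseline_config, chamber_vco2=0.0, chamber_vo2=0.0)
        st = solve_steady_state(cfg)
        assert st.vco2_lung == pytest.approx(0.0, abs=1e-12)
        assert st.vco2_ecmo == pytest.approx(0.0, abs=1e-12)
        cco2 = {p: c.cco2 for p, c in st.contents.items()}
        assert max(cco2.values()) - min(cco2.values()) < 1e-9

    def test_baseline_magnitudes_match_two_compartment_oracle(self, baseline_state,
                                                              baseline_config):
        """Independent mass-balance check of the baseline exchange split.

        Hand model: chamber CO2 partitions with weights q/f; ECMO at
        V/Q = 1 (f = 1, w = 2000), lung at V/Q = 3 (f = (3+c)/(1+c)/3).
        """
        cfg = baseline_config
        c = normalization_constant(cfg.ph_venous, cfg.temp).c
        f_lung = (3.0 + c) / (1.0 + c) / 3.0
        w_e, w_l = 2000.0, 500.0 / f_lung
        expect_ecmo = 130.0 * w_e / (w_e + w_l)
        assert baseline_state.vco2_ecmo == pytest.approx(expect_ecmo, rel=1e-9)
        # magnitudes are physiologic: tens of ml/min per unit
        assert 60.0 < baseline_state.vco2_ecmo < 110.0
        assert 30.0 < baseline_state.vco2_lung < 70.0
        drop = (baseline_state.contents["venous"].cco2
                - baseline_state.contents["aorta"].cco2)
        assert drop == pytest.approx(100.0 * 130.0 / 2500.0, rel=1e-9)

    def test_increasing_sweep_monotone(self, baseline_config):
        """More ECMO ventilation -> more measured VCO2, lower post-membrane content."""
        prev_vco2, prev_pm = -np.inf, np.inf
        for v in (1000.0, 2000.0, 4000.0, 6000.0):
            st = solve_steady_state(replace(baseline_config, v_ecmo=v))
            assert st.vco2_ecmo > prev_vco2
            assert st.contents["post_membrane"].cco2 < prev_pm
            prev_vco2, prev_pm = st.vco2_ecmo, st.contents["post_membrane"].cco2

    def test_full_shunt_limit(self, baseline_config):
        """shunt = 1: no lung gas exchange, LA content equals venous."""
        st = solve_steady_state(replace(baseline_config, shunt=1.0))
        assert st.vco2_lung == 0.0
        assert st.vo2_lung == 0.0
        assert st.contents["left_atrium"].cco2 \
            == pytest.approx(st.contents["venous"].cco2, abs=1e-9)
        assert st.vco2_ecmo == pytest.approx(
            baseline_config.resolved_chamber_vco2(), abs=1e-9)


class TestProtocol:
    @pytest.mark.parametrize("step_id,expected_rows", [
        ("1a", 12), ("1b", 12), ("2a", 8), ("2b", 4),
    ])
    def test_schedule_sizes(self, step_id, expected_rows):
        assert len(run_protocol(step_id)) == expected_rows

    def test_1a_keeps_total_flow_and_unit_vq(self):
        for step, _ in run_protocol("1a", shunt_levels=[0.0]):
            assert step.q_ecmo + step.q_lung == pytest.approx(2500.0)
            assert step.vq_ecmo == pytest.approx(1.0)

    def test_1b_traverses_vq_ratios(self):
        ratios = sorted({round(s.vq_ecmo, 4) for s, _ in run_protocol("1b", [0.0])})
        assert ratios == [0.75, 1.0, 1.5, 3.0]

    def test_2a_partial_transfer_loses_total_flow(self):
        rows = [s for s, _ in run_protocol("2a") if s.transfer_fraction == 0.5]
        full_wean = min(rows, key=lambda s: s.q_ecmo)
        assert full_wean.q_lung == pytest.approx(500.0 + 0.5 * 1500.0)
        assert full_wean.q_ecmo + full_wean.q_lung == pytest.approx(1750.0)

    def test_2b_constant_lung_flow_zero_shunt(self):
        for step, _ in run_protocol("2b"):
            assert step.q_lung == pytest.approx(500.0)
            assert step.shunt == 0.0

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError):
            run_protocol("3c")


class TestMeasurementNoise:
    def test_noise_model_matches_spec_interval(self):
        """At 40 mmHg the empirical 95 % interval is +-(3.3 + 3.2) mmHg."""
        rng = np.random.default_rng(7)
        draws = 40.0 + rng.normal(0.0, capnometer_sd(40.0), size=10_000)
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert hi - 40.0 == pytest.approx(3.3 + 0.08 * 40.0, abs=0.25)
        assert 40.0 - lo == pytest.approx(3.3 + 0.08 * 40.0, abs=0.25)

    def test_noise_deterministic_for_seed(self):
        a = records_from_protocol("1a", noise=True, seed=42)
        b = records_from_protocol("1a", noise=True, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_off_equals_state(self, records_1a):
        again = records_from_protocol("1a")
        pd.testing.assert_frame_equal(records_1a, again)
        rec = records_1a.iloc[0].to_dict()
        noisy = apply_measurement_noise(rec, 3)
        assert noisy["exhaust_pco2_ecmo"] != rec["exhaust_pco2_ecmo"]
        same = apply_measurement_noise(rec, 3)
        assert same == noisy
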