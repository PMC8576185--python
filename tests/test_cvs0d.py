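"""Unit and property tests of the closed-loop 0D circulation model."""

import math

import numpy as np
import pytest

from lvadest import HeartFailureParams, PumpSetting, simulate
from lvadest.cvs0d import (afferent_firing, compartment_pressure,
                           compartment_volume, effector_target,
                           inertial_flow_derivative,
                           instantaneous_elastance,
                           passive_ventricular_pressure, simulate_effector,
                           valve_flow, volume_derivative)


class TestPassivePressure:
    def test_zero_volume_gives_zero_pressure(self):
        assert passive_ventricular_pressure(0.0, 0.014, 1.5) == 0.0

    def test_strictly_increasing_and_convex(self):
        v = np.linspace(0.0, 250.0, 100)
        p = passive_ventricular_pressure(v, 0.0125, 1.5)
        assert np.all(np.diff(p) > 0)
        assert np.all(np.diff(p, 2) > 0)

    def test_matches_direct_arithmetic(self):
        # independent scalar evaluation of P0*(exp(kE*V)-1)
        expected = 1.5 * (math.exp(0.0125 * 120.0) - 1.0)
        assert passive_ventricular_pressure(120.0, 0.0125, 1.5) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(5.222534, abs=1e-6)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            passive_ventricular_pressure(-1.0, 0.0125, 1.5)


class TestActivation:
    def test_peak_activation_gives_full_elastance(self):
        period = 0.8
        tsys = 0.5 - 0.075 / period
        u, e = instantaneous_elastance(tsys / 2.0, period, 2.0)
        assert u == pytest.approx(1.0)
        assert e == pytest.approx(2.0)

    def test_diastole_gives_zero_activation(self):
        u, e = instantaneous_elastance(0.7, 0.8, 2.0)
        assert u == 0.0 and e == 0.0

    def test_waveform_is_continuous_over_one_beat(self):
        period = 0.85
        phases = np.linspace(0.0, period, 20000, endpoint=False)
        u, _ = instantaneous_elastance(phases, period, 1.0)
        assert np.max(np.abs(np.diff(u))) < 1e-3
        assert u.min() >= 0.0 and u.max() <= 1.0

    def test_phase_outside_beat_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_elastance(0.9, 0.8, 1.0)


class TestValveFlow:
    def test_forward_gradient(self):
        assert valve_flow(100.0, 80.0, 0.01) == pytest.approx(2000.0)

    def test_diode_closed_for_reversed_gradient(self):
        assert valve_flow(80.0, 100.0, 0.01) == 0.0
        assert valve_flow(50.0, 50.0, 0.01) == 0.0

    def test_continuity_at_zero_gradient(self):
        eps = np.array([1e-9, 1e-6, 1e-3])
        assert valve_flow(80.0 + eps, 80.0, 0.01) == pytest.approx(eps / 0.01,
                                                                   rel=1e-6)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            valve_flow(100.0, 80.0, 0.0)


class TestVascularRelations:
    def test_volume_constant_when_flows_balance(self):
        assert volume_derivative(120.0, 120.0) == 0.0

    def test_momentum_equilibrium(self):
        # P_in - P_out - R*Q = 0 -> dQ/dt = 0
        assert inertial_flow_derivative(100.0, 94.0, 0.06, 2.2e-4, 100.0) == 0.0

    def test_pressure_volume_relation(self):
        assert compartment_volume(10.0, 1.5, 500.0) == pytest.approx(515.0)
        assert compartment_pressure(515.0, 1.5, 500.0) == pytest.approx(10.0)


class TestBaroreflex:
    def test_setpoint_is_a_fixed_point(self, cfg):
        aff = cfg.baroreflex["afferent"]
        f_cs, f_es, f_ev = afferent_firing(aff["P_n"], cfg)
        assert f_cs == pytest.approx(0.5 * (aff["f_min"] + aff["f_max"]))
        assert f_es == pytest.approx(cfg.basal_f_es())
        assert f_ev == pytest.approx(cfg.basal_f_ev())

    def test_zero_gain_effector_is_constant(self, cfg):
        t = np.linspace(0.0, 30.0, 3001)
        f_es = np.full_like(t, 10.0)  # strong sympathetic input
        x = simulate_effector(f_es, t, gain=0.0, tau=8.0, delay=2.0,
                              f_es_min=2.66, x0=0.0)
        assert np.all(x == 0.0)

    def test_hypotension_step_response_is_monotone_and_bounded(self, cfg):
        # sustained hypotension -> raised f_es -> elastance effector rises
        # monotonically to the saturating static value
        eff = cfg.baroreflex["efferent"]
        t = np.linspace(0.0, 60.0, 6001)
        f_hyp = 12.0
        f = np.full_like(t, f_hyp)
        gain = 0.475
        x = simulate_effector(f, t, gain=gain, tau=8.0, delay=2.0,
                              f_es_min=eff["f_es_min"],
                              x0=gain * cfg.basal_sympathetic_drive())
        plateau = effector_target(f_hyp, gain, eff["f_es_min"])
        assert np.all(np.diff(x) >= -1e-12)
        assert x[-1] <= plateau + 1e-9
        assert x[-1] == pytest.approx(plateau, rel=1e-3)

    def test_firing_is_monotone_in_pressure(self, cfg):
        p = np.linspace(40.0, 160.0, 200)
        f_cs, f_es, _ = afferent_firing(p, cfg)
        assert np.all(np.diff(f_cs) > 0)      # afferent rises with pressure
        assert np.all(np.diff(f_es) < 0)      # sympathetic falls with pressure


class TestSimulate:
    def test_output_grid_has_n_plus_one_uniform_samples(self, sim_mid_5000):
        s = sim_mid_5000
        assert s.t.size == s.N + 1 == 2001
        assert np.allclose(np.diff(s.t), s.T / s.N)

    def test_blood_volume_conserved(self, sim_mid_5000):
        v = sim_mid_5000.total_volume
        assert np.max(np.abs(v - v[0])) < 1e-3 * v[0]

    def test_arterial_pressures_nonnegative_and_finite(self, sim_mid_5000,
                                                       sim_severe_6000):
        for s in (sim_mid_5000, sim_severe_6000):
            for arr in (s.sap, s.pap, s.v_lv):
                assert np.all(np.isfinite(arr))
            assert np.all(s.sap >= 0) and np.all(s.pap >= 0)

    def test_valves_never_permit_backflow(self, sim_mid_5000, sim_severe_4000):
        for s in (sim_mid_5000, sim_severe_4000):
            assert np.all(s.q_av >= 0.0)

    def test_deterministic_bit_identical(self, hf_mid, cfg, table):
        a = simulate(hf_mid, PumpSetting(4600.0), config=cfg, table=table)
        b = simulate(hf_mid, PumpSetting(4600.0), config=cfg, table=table)
        for name in ("sap", "pap", "p_lv", "v_lv", "q_av", "q_pump"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_full_unloading_closes_aortic_valve(self, sim_severe_6000):
        s = sim_severe_6000
        last5 = s.t >= s.T - 5.0
        assert np.all(s.q_av[last5] == 0.0)

    def test_lv_unloading_is_monotone_in_pump_speed(self, hf_mid, cfg, table):
        edv = []
        for rpm in (4000.0, 5000.0, 6000.0):
            s = simulate(hf_mid, PumpSetting(rpm), config=cfg, table=table)
            edv.append(s.v_lv[s.t >= s.T - 5.0].max())
        assert edv[0] > edv[1] > edv[2]

    def test_zero_pump_limit_reaches_periodic_steady_state(self,
                                                           sim_healthy_nopump):
        s = sim_healthy_nopump
        assert np.all(s.q_pump == 0.0)
        dt = s.T / s.N
        onsets = s.beat_onsets[s.beat_onsets > s.T - 5.0]
        spacing = np.diff(onsets)
        # the rhythm is periodic: constant beat spacing ...
        assert np.allclose(spacing, spacing.mean(), atol=0.01)
        # ... consistent with the regulated heart period (the phase clock
        # integrates 1/T over the pulsating within-beat baroreflex state,
        # so the spacing is the effective, not the end-sample, period)
        assert abs(spacing.mean() - s.heart_period[-1]) < 0.05
        # one beat apart, the pressure traces coincide
        lag = int(round(spacing.mean() / dt))
        tail = s.sap[s.t >= s.T - 5.0]
        resid = tail[lag:] - tail[:-lag]
        assert np.sqrt(np.mean(resid ** 2)) < 0.05 * np.std(tail)

    def test_step_refinement_converges(self, hf_mid, cfg, table):
        coarse = simulate(hf_mid, PumpSetting(5000.0), config=cfg, table=table,
                          dt_max=5e-4)
        fine = simulate(hf_mid, PumpSetting(5000.0), config=cfg, table=table,
                        dt_max=1.25e-4)
        rms = np.sqrt(np.mean((coarse.sap - fine.sap) ** 2))
        assert rms < 0.01 * np.std(fine.sap)

    def test_odd_grid_count_rejected(self, hf_mid):
        with pytest.raises(ValueError):
            simulate(hf_mid, PumpSetting(5000.0), N=1999)

    def test_invalid_hf_parameters_rejected(self):
        with pytest.raises(ValueError):
            HeartFailureParams(0.0, 1.0, 0.3, 0.012)

    def test_result_frame_round_trip(self, sim_mid_5000, tmp_path):
        path = tmp_path / "run.csv"
        sim_mid_5000.save_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "sap", "pap", "p_lv", "v_lv",
                                    "q_av", "q_pump", "p_pv", "rpm"]
        assert np.allclose(df.sap.to_numpy(), sim_mid_5000.sap)
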