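"""Single-cell model: input pre-processing, vector field, phase-plane
analysis and stochastic integration."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import brentq

from camprelay import (CellParams, SimConfig, drift_field, fixed_points,
                       hopf_threshold, input_signal, nullclines,
                       simulate_cell, step_protocol)
from camprelay.metrics import detect_spikes
from camprelay.model import IntegrationError, resting_state


def drive_to_conc(drive, params):
    """Invert I(x) = a*log(1 + x/Kd)."""
    return params.Kd * np.expm1(drive / params.a)


class TestInputSignal:
    def test_zero_at_zero(self, params):
        assert input_signal(0.0, params) == 0.0

    def test_value_at_kd(self, params):
        # a * ln 2 at the threshold concentration
        assert input_signal(params.Kd, params) == \
            pytest.approx(0.058 * np.log(2.0), abs=1e-12)

    def test_monotone(self, params):
        x = np.geomspace(1e-8, 1e6, 200)
        y = input_signal(x, params)
        assert np.all(np.diff(y) > 0)
        assert input_signal(10 * params.Kd, params) > input_signal(params.Kd, params)

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            input_signal(-1.0, params)


class TestDriftField:
    def test_origin(self, params):
        dA, dR = drift_field(0.0, 0.0, 0.0, params)
        assert dA == 0.0
        assert dR == pytest.approx(0.12)  # eps * c0

    def test_cubic_root(self, params):
        # f(sqrt(3)) = 0, so dA/dt = -R = 0 at R = 0
        dA, _ = drift_field(np.sqrt(3.0), 0.0, 0.0, params)
        assert dA == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("drive", [0.0, 0.5, 1.0])
    def test_zero_at_fixed_points(self, params, drive):
        for A_star, R_star, _ in fixed_points(params, drive):
            dA, dR = drift_field(A_star, R_star, drive, params)
            assert abs(dA) < 1e-10 and abs(dR) < 1e-10


class TestPhasePlane:
    def test_nullclines_at_origin(self, params):
        R_A, R_R = nullclines(params, 0.0, [0.0])
        assert R_A[0] == 0.0
        assert R_R[0] == pytest.approx(params.c0 / params.gamma)  # 2.4

    def test_drive_shifts_activator_nullcline_only(self, params):
        A = np.linspace(-3, 3, 31)
        a0, r0 = nullclines(params, 0.0, A)
        a1, r1 = nullclines(params, 0.7, A)
        assert np.allclose(a1 - a0, 0.7)
        assert np.array_equal(r0, r1)

    def test_fixed_point_is_nullcline_intersection(self, params):
        A_star, R_star, _ = fixed_points(params, 0.3)[0]
        R_A, R_R = nullclines(params, 0.3, [A_star])
        assert R_A[0] == pytest.approx(R_star, abs=1e-8)
        assert R_R[0] == pytest.approx(R_star, abs=1e-8)

    def test_resting_point_against_root_oracle(self, params):
        # independent 1-D bracketing on the nullcline-difference function
        g = lambda A: A - A**3 / 3.0 - (A + params.c0) / params.gamma
        A_oracle = brentq(g, -3.0, 0.0, xtol=1e-14)
        pts = fixed_points(params, 0.0)
        assert len(pts) == 1
        A_star, R_star, cls = pts[0]
        assert A_star == pytest.approx(A_oracle, abs=1e-10)
        assert A_star == pytest.approx(-1.4286, abs=5e-4)
        assert R_star == pytest.approx(-0.457, abs=5e-4)
        assert cls == "stable"  # excitable, below the bifurcation

    def test_classification_flips_at_trace_zero(self, params):
        # stability boundary at A*^2 = 1 - eps*gamma = 0.95
        A_flip = -np.sqrt(1 - params.epsilon * params.gamma)
        for dA in (-1e-3, 1e-3):
            A_star = A_flip + dA
            drive = ((A_star + params.c0) / params.gamma
                     - A_star + A_star**3 / 3.0)
            pts = fixed_points(params, drive)
            labels = {cls for A, _, cls in pts
                      if abs(A - A_star) < 1e-6}
            assert labels == ({"stable"} if dA < 0 else {"unstable"})

    def test_hopf_threshold_value(self, params):
        # closed-form corollary of the reconstructed equations
        assert hopf_threshold(params) == pytest.approx(1.1167, abs=1e-4)

    def test_hopf_requires_eps_gamma_below_one(self):
        with pytest.raises(ValueError):
            hopf_threshold(CellParams(epsilon=2.5, gamma=0.5))

    def test_below_threshold_is_stable(self, params):
        assert fixed_points(params, 0.0)[0][2] == "stable"


class TestSimulateCell:
    def test_equilibrium_stays_put(self, det_params, rest):
        cfg = SimConfig(t_end=100.0)
        tr = simulate_cell(det_params, 0.0, cfg, initial_state=rest)
        assert np.max(np.abs(tr.A - rest[0])) < 1e-8
        assert np.max(np.abs(tr.R - rest[1])) < 1e-8

    def test_seed_reproducibility(self, params):
        cfg = SimConfig(t_end=50.0, seed=77)
        t1 = simulate_cell(params, 1.0, cfg)
        t2 = simulate_cell(params, 1.0, cfg)
        assert np.array_equal(t1.A, t2.A) and np.array_equal(t1.R, t2.R)
        t3 = simulate_cell(params, 1.0, SimConfig(t_end=50.0, seed=78))
        assert not np.array_equal(t1.A, t3.A)

    def test_uniform_grid_and_finite(self, params):
        cfg = SimConfig(t_end=30.0, record_stride=10)
        tr = simulate_cell(params, 1.0, cfg)
        assert np.allclose(np.diff(tr.times), cfg.dt * 10)
        assert np.all(np.isfinite(tr.A))

    def test_blowup_raises_with_time(self, det_params):
        with pytest.raises(IntegrationError, match="t="):
            simulate_cell(det_params, 0.0, SimConfig(t_end=5.0),
                          initial_state=(1e160, 0.0))

    def test_protocol_shorter_than_run_rejected(self, det_params):
        proto = step_protocol(1.0, 5.0, 20.0)
        with pytest.raises(ValueError):
            simulate_cell(det_params, proto, SimConfig(t_end=50.0))

    def test_csv_roundtrip(self, params, tmp_path):
        from camprelay.model import CellTrace
        cfg = SimConfig(t_end=10.0, seed=5)
        tr = simulate_cell(params, 1.0, cfg)
        path = tmp_path / "trace.csv"
        tr.save_csv(path, params, cfg)
        back = CellTrace.load_csv(path)
        assert np.allclose(back.A, tr.A)
        assert (tmp_path / "trace.csv.json").exists()


class TestExcitableDynamics:
    def test_single_spike_then_rest_below_threshold(self, det_params, rest):
        # fast sub-threshold steps elicit exactly one accommodation spike
        dc = hopf_threshold(det_params)
        for frac in (0.5, 0.7, 0.9):
            conc = drive_to_conc(frac * dc, det_params)
            tr = simulate_cell(det_params, float(conc), SimConfig(t_end=400.0),
                               initial_state=rest)
            assert len(detect_spikes(tr.times, tr.A)) == 1, frac
            A_star = fixed_points(det_params, frac * dc)[0][0]
            assert abs(tr.A[-1] - A_star) < 1e-3

    def test_sustained_oscillation_above_threshold(self, det_params, rest):
        dc = hopf_threshold(det_params)
        conc = drive_to_conc(1.2 * dc, det_params)
        counts = []
        for t_end in (400.0, 800.0):
            tr = simulate_cell(det_params, float(conc),
                               SimConfig(t_end=t_end), initial_state=rest)
            w = tr.window(100.0)
            counts.append(len(detect_spikes(w.times, w.A)))
        # spike count grows roughly linearly with the horizon
        assert counts[1] >= 1.7 * counts[0] > 0

    def test_finite_frequency_at_onset(self, det_params, rest):
        # supercritical Hopf with finite frequency: period just above
        # threshold within a factor 2 of the period at 1.5x threshold
        dc = hopf_threshold(det_params)
        periods = []
        for frac in (1.05, 1.5):
            conc = drive_to_conc(frac * dc, det_params)
            tr = simulate_cell(det_params, float(conc),
                               SimConfig(t_end=600.0), initial_state=rest)
            w = tr.window(200.0)
            s = detect_spikes(w.times, w.A)
            periods.append(np.mean(np.diff(s.spike_times)))
        assert periods[0] < 2.0 * periods[1]


class TestOracleEquivalence:
    def _oracle(self, params, proto, times, y0):
        from scipy.integrate import solve_ivp

        def rhs(t, y):
            drive = input_signal(proto(min(t, proto.t_end)), params)
            return drift_field(y[0], y[1], drive, params)

        sol = solve_ivp(rhs, (0.0, times[-1]), y0, t_eval=times,
                        rtol=1e-10, atol=1e-12, max_step=0.5, method="LSODA")
        return sol.y

    def test_smooth_protocol_matches_adaptive_oracle(self, det_params, rest):
        # sub-excitation step: sup-norm <= 1e-3 at dt = 0.005 over t = 50
        dc = hopf_threshold(det_params)
        conc = drive_to_conc(0.25 * dc, det_params)
        proto = step_protocol(float(conc), 5.0, 50.0)
        tr = simulate_cell(det_params, proto, SimConfig(t_end=50.0,
                                                        record_stride=1),
                           initial_state=rest)
        y = self._oracle(det_params, proto, tr.times, rest)
        assert np.max(np.abs(y[0] - tr.A)) < 1e-3
        assert np.max(np.abs(y[1] - tr.R)) < 1e-3

    def test_spiking_protocol_matches_oracle_coarsely(self, det_params, rest):
        # across a relaxation spike the O(dt) upstroke phase error dominates
        proto = step_protocol(1.0, 5.0, 50.0)
        tr = simulate_cell(det_params, proto, SimConfig(t_end=50.0,
                                                        record_stride=1),
                           initial_state=rest)
        y = self._oracle(det_params, proto, tr.times, rest)
        assert np.max(np.abs(y[0] - tr.A)) < 2e-2


class TestInputSignalProperties:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(a=st.floats(0.01, 1.0), kd=st.floats(1e-8, 1.0),
           x=st.floats(0.0, 1e6), y=st.floats(0.0, 1e6))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_monotone_nonnegative(a, kd, x, y):
        p = CellParams(a=a, Kd=kd)
        lo, hi = sorted((x, y))
        assert 0.0 <= input_signal(lo, p) <= input_signal(hi, p)
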