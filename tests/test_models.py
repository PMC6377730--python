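"""Model construction, integration accuracy, sensitivities, oscillation classifier."""
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from oscifit import (
    DynamicModel,
    build_case_study,
    detect_sustained_oscillations,
    simulate,
    simulate_with_sensitivities,
)
from oscifit.casestudies import CASE_STUDIES


class TestCaseStudyRegistry:
    def test_unknown_name_raises(self):
        with pytest.raises(KeyError, match="no such case study"):
            build_case_study("nope")

    @pytest.mark.parametrize(
        "name,n_params,n_states,n_obs,lo,hi",
        [
            ("fhn", 3, 2, 1, 1e-5, 1e5),
            ("go", 8, 3, 2, 1e-3, 1e3),
            ("rp", 4, 6, 1, 1e-3, 500.0),
            ("eo", 7, 3, 2, 1e-3, 1e3),
        ],
    )
    def test_dimensions_and_bounds(self, name, n_params, n_states, n_obs, lo, hi):
        m = build_case_study(name)
        assert m.n_params == n_params
        assert m.n_states == n_states
        assert m.n_observables() == n_obs
        assert m.bounds[0][0] == lo and m.bounds[1][0] == hi

    def test_go_observation_variants(self):
        m = build_case_study("go", "validation")
        assert m.observable_names("fitting") == ("x1", "x3")
        assert m.observable_names("validation") == ("x1", "x2", "x3")

    def test_rp_observation_variants(self):
        m = build_case_study("rp")
        assert m.observable_names("fitting") == ("m3",)
        assert m.observable_names("validation") == ("p3", "m3")

    def test_validation_falls_back_with_warning_for_fhn(self):
        m = build_case_study("fhn")
        with pytest.warns(UserWarning, match="no separate validation"):
            assert m.resolve_variant("validation") == "fitting"

    def test_rp_printed_nominal_mapping_warns(self):
        with pytest.warns(UserWarning, match="outside the declared bound"):
            m = build_case_study("rp", nominal_mapping="printed")
        assert m.nominal[-1] == 0.3

    def test_wide_bounds_default_to_log_scale(self):
        m = build_case_study("go")
        assert m.search_scale[:7] == ("log10",) * 7
        assert m.search_scale[7] == "linear"  # Hill coefficient, narrow range

    def test_invalid_model_definitions_rejected(self):
        with pytest.raises(ValueError, match="unknown symbols"):
            DynamicModel("bad", ("x",), ("k",), ("-k*y",),
                         {"fitting": {"x": "x"}}, [1.0], ([0.1], [1.0]))
        with pytest.raises(ValueError, match="theta_min < theta_max"):
            DynamicModel("bad", ("x",), ("k",), ("-k*x",),
                         {"fitting": {"x": "x"}}, [1.0], ([1.0], [1.0]))
        with pytest.raises(ValueError, match="log10-scaled"):
            DynamicModel("bad", ("x",), ("k",), ("-k*x",),
                         {"fitting": {"x": "x"}}, [1.0], ([-1.0], [1e4]),
                         search_scale=("log10",))


class TestSimulate:
    def test_single_time_point_returns_x0(self, decay_model):
        traj = simulate(decay_model, [1.0], x0=[0.7], times=[0.0])
        assert traj.states.shape == (1, 1)
        assert traj.states[0, 0] == 0.7
        assert traj.observables[0, 0] == 0.7

    def test_exponential_decay_closed_form(self, decay_model):
        traj = simulate(decay_model, [1.0], x0=[1.0], times=[0.0, 1.0])
        assert traj.ok
        assert traj.states[-1, 0] == pytest.approx(math.exp(-1.0), abs=1e-6)

    def test_initial_state_preserved(self, fhn_model):
        traj = simulate(fhn_model, fhn_model.nominal, times=np.linspace(0, 20, 5))
        assert np.allclose(traj.states[0], fhn_model.default_x0, atol=1e-10)

    def test_fhn_spikes_and_matches_independent_integrator(self, fhn_model):
        times = np.linspace(0.0, 20.0, 101)
        traj = simulate(fhn_model, fhn_model.nominal, times=times)
        v = traj.observables[:, 0]
        assert np.sum(np.diff(np.sign(v)) != 0) >= 2  # spiking

        a, b, g = fhn_model.nominal

        def rhs(t, x):
            return [g * (x[0] - x[0] ** 3 / 3 + x[1]),
                    -(x[0] - a + b * x[1]) / g]

        ref = solve_ivp(rhs, (0, 20), [-1.0, 1.0], t_eval=times, rtol=1e-12,
                        atol=1e-12, method="LSODA", dense_output=False)
        assert np.max(np.abs(traj.states - ref.y.T)) < 1e-5

    def test_decreasing_times_rejected(self, decay_model):
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate(decay_model, [1.0], times=[0.0, 2.0, 1.0])

    def test_out_of_bounds_theta_warns_but_runs(self, decay_model):
        with pytest.warns(UserWarning, match="outside bounds"):
            traj = simulate(decay_model, [100.0], times=[0.0, 0.1])
        assert traj.ok

    def test_blowup_flagged_infeasible_not_raised(self):
        m = DynamicModel("explode", ("x",), ("k",), ("k*x**2",),
                         {"fitting": {"x": "x"}}, [1.0], ([0.1], [10.0]))
        traj = simulate(m, [5.0], times=np.linspace(0, 10, 11))
        assert not traj.ok
        assert 0.0 <= traj.fraction_solved < 1.0

    @pytest.mark.parametrize("name", sorted(CASE_STUDIES))
    def test_tolerance_refinement_stability(self, name):
        """Tightening integrator tolerances 10x barely moves the observables."""
        m = build_case_study(name)
        times = np.linspace(*m.default_horizon, m.n_points)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y1 = simulate(m, m.nominal, times=times).observables
            y2 = simulate(m, m.nominal, times=times, rtol=1e-9,
                          atol=1e-11).observables
        scale = np.max(np.abs(y1))
        assert np.max(np.abs(y1 - y2)) / scale < 1e-5


class TestSensitivities:
    def test_decay_sensitivity_closed_form(self, decay_model):
        # d/dtheta e^{-theta t} = -t e^{-theta t}
        _, sens = simulate_with_sensitivities(decay_model, [1.0], x0=[1.0],
                                              times=[0.0, 1.0])
        assert sens.dy_dtheta[-1, 0, 0] == pytest.approx(-math.exp(-1.0),
                                                         abs=1e-6)

    def test_zero_at_t0(self, fhn_model):
        _, sens = simulate_with_sensitivities(fhn_model, fhn_model.nominal,
                                              times=np.linspace(0, 20, 7))
        assert np.all(sens.dx_dtheta[0] == 0.0)

    def test_chain_rule_for_observables(self, go_model):
        # observables are plain state selections: dy/dtheta rows of dx/dtheta
        traj, sens = simulate_with_sensitivities(
            go_model, go_model.nominal, times=np.linspace(0, 100, 9))
        assert np.allclose(sens.dy_dtheta[:, 0, :], sens.dx_dtheta[:, 0, :])
        assert np.allclose(sens.dy_dtheta[:, 1, :], sens.dx_dtheta[:, 2, :])

    @pytest.mark.parametrize("name", ["fhn", "go"])
    def test_matches_finite_differences_at_nominal(self, name):
        m = build_case_study(name)
        times = np.linspace(*m.default_horizon, 8)
        _, sens = simulate_with_sensitivities(m, m.nominal, times=times)
        fd = _fd_sensitivities(m, m.nominal, times)
        scale = np.max(np.abs(fd))
        assert np.max(np.abs(sens.dy_dtheta - fd)) / scale < 1e-3

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_matches_finite_differences_random_theta(self, draw_seed):
        """Property: analytic and finite-difference sensitivities agree
        for random in-bounds FHN parameter draws."""
        m = build_case_study("fhn")
        rng = np.random.default_rng(draw_seed)
        # draw log-uniform but within a feasible (integrable) region
        theta = 10.0 ** rng.uniform(-1.0, 1.0, size=3)
        times = np.linspace(0.0, 20.0, 6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj, sens = simulate_with_sensitivities(m, theta, times=times)
            if not traj.ok:
                return
            fd = _fd_sensitivities(m, theta, times)
        scale = max(np.max(np.abs(fd)), 1e-12)
        assert np.max(np.abs(sens.dy_dtheta - fd)) / scale < 1e-3


def _fd_sensitivities(model, theta, times, h_rel=1e-5):
    theta = np.asarray(theta, dtype=float)
    cols = []
    for j in range(len(theta)):
        h = h_rel * max(abs(theta[j]), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        yp = simulate(model, tp, times=times, rtol=1e-10, atol=1e-12).observables
        ym = simulate(model, tm, times=times, rtol=1e-10, atol=1e-12).observables
        cols.append((yp - ym) / (2 * h))
    return np.stack(cols, axis=-1)


class TestOscillationClassifier:
    def test_harmonic_is_sustained_with_2pi_period(self, harmonic_model):
        out = detect_sustained_oscillations(harmonic_model, [1.0],
                                            horizon=(0.0, 100.0))
        assert out["classification"] == "sustained"
        assert out["period"] == pytest.approx(2 * math.pi, rel=1e-3)

    def test_relaxation_is_steady(self, decay_model):
        out = detect_sustained_oscillations(decay_model, [1.0],
                                            horizon=(0.0, 60.0))
        assert out["classification"] == "steady"

    def test_goodwin_nominal_oscillates(self, go_model):
        out = detect_sustained_oscillations(go_model, go_model.nominal)
        assert out["classification"] == "sustained"
        assert out["period"] > 0

    def test_goodwin_hill_scan_contiguous_split(self, go_model):
        """Damped below a threshold Hill coefficient, sustained above it."""
        labels = []
        for n in range(1, 13):
            theta = go_model.nominal.copy()
            theta[-1] = n
            labels.append(detect_sustained_oscillations(
                go_model, theta)["classification"])
        sustained = [lab == "sustained" for lab in labels]
        first = sustained.index(True)
        assert all(sustained[first:])
        assert not any(sustained[:first])
        assert first + 1 >= 8  # threshold consistent with n >= 8
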