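"""Cost functions, NRMSE and FIM-based statistics against hand oracles."""
import math

import numpy as np
import pandas as pd
import pytest

from oscifit import (
    Experiment,
    ExperimentData,
    fit_statistics,
    log_likelihood,
    nls_cost,
    nrmse,
    regularisation_penalty,
    regularised_cost,
    simulate,
)
from oscifit.models import PENALTY_COST
from oscifit.objective import nrmse_from_values, pseudo_inverse


def _decay_dataset(model, theta, times, sigma, x0=1.0, value_offset=0.0):
    traj = simulate(model, [theta], x0=[x0], times=times)
    df = pd.DataFrame({"observable": "x", "time": times,
                       "value": traj.observables[:, 0] + value_offset,
                       "sigma": sigma})
    return ExperimentData([Experiment("e1", [x0], df)])


class TestExperimentData:
    def test_rejects_nonpositive_sigma(self):
        df = pd.DataFrame({"observable": "x", "time": [0.0], "value": [1.0],
                           "sigma": [0.0]})
        with pytest.raises(ValueError, match="non-positive sigma"):
            Experiment("e", [1.0], df)

    def test_rejects_nan_measurements(self):
        df = pd.DataFrame({"observable": "x", "time": [0.0],
                           "value": [float("nan")], "sigma": [0.1]})
        with pytest.raises(ValueError, match="NaN"):
            Experiment("e", [1.0], df)

    def test_rejects_unknown_observable(self, decay_model):
        df = pd.DataFrame({"observable": "bogus", "time": [0.0],
                           "value": [1.0], "sigma": [0.1]})
        data = ExperimentData([Experiment("e", [1.0], df)])
        with pytest.raises(ValueError, match="bogus"):
            data.validate_against(decay_model)

    def test_csv_round_trip(self, tmp_path, decay_model):
        data = _decay_dataset(decay_model, 1.0, np.linspace(0, 2, 5), 0.1)
        path = tmp_path / "data.csv"
        data.to_csv(path)
        back = ExperimentData.from_csv(path, x0=[1.0])
        pd.testing.assert_frame_equal(back.experiments[0].observations,
                                      data.experiments[0].observations)


class TestNlsCost:
    def test_perfect_fit_is_zero(self, decay_model):
        data = _decay_dataset(decay_model, 1.0, np.linspace(0, 2, 6), 0.1)
        assert nls_cost(decay_model, [1.0], data).cost == pytest.approx(0.0,
                                                                       abs=1e-12)

    def test_single_point_hand_value(self, decay_model):
        # y(0)=1.0 simulated; measured 1.2 with sigma 0.1 -> ((-0.2)/0.1)^2 = 4
        df = pd.DataFrame({"observable": "x", "time": [0.0], "value": [1.2],
                           "sigma": [0.1]})
        data = ExperimentData([Experiment("e", [1.0], df)])
        res = nls_cost(decay_model, [1.0], data)
        assert res.cost == pytest.approx(4.0, abs=1e-12)

    def test_equals_brute_force_double_sum(self, decay_model):
        """Two experiments, residuals summed by an explicit double loop."""
        times = np.linspace(0.0, 2.0, 4)
        e1 = _decay_dataset(decay_model, 1.0, times, 0.2,
                            value_offset=0.05).experiments[0]
        e2 = _decay_dataset(decay_model, 1.0, times, 0.3, x0=2.0,
                            value_offset=-0.1).experiments[0]
        data = ExperimentData([e1, e2])
        res = nls_cost(decay_model, [1.0], data)
        brute = 0.0
        for exp in data.experiments:
            traj = simulate(decay_model, [1.0], x0=exp.x0,
                            times=exp.observations["time"].to_numpy())
            for i, row in exp.observations.reset_index().iterrows():
                brute += ((traj.observables[i, 0] - row["value"])
                          / row["sigma"]) ** 2
        assert res.cost == pytest.approx(brute, rel=1e-12)
        assert res.cost == pytest.approx(res.residuals @ res.residuals)

    def test_infeasible_simulation_becomes_penalty(self):
        from oscifit import DynamicModel
        m = DynamicModel("explode", ("x",), ("k",), ("k*x**2",),
                         {"fitting": {"x": "x"}}, [1.0], ([0.1], [10.0]))
        df = pd.DataFrame({"observable": "x", "time": [0.0, 5.0],
                           "value": [1.0, 1.0], "sigma": [0.1, 0.1]})
        data = ExperimentData([Experiment("e", [1.0], df)])
        res = nls_cost(m, [5.0], data)
        assert not res.feasible
        assert res.cost >= PENALTY_COST


class TestLogLikelihood:
    def test_perfect_fit_unit_sigma(self, decay_model):
        times = np.linspace(0.0, 2.0, 7)
        data = _decay_dataset(decay_model, 1.0, times, 1.0)
        ll = log_likelihood(decay_model, [1.0], data)
        assert ll == pytest.approx(-(len(times) / 2) * math.log(2 * math.pi))

    def test_single_point_hand_value(self, decay_model):
        df = pd.DataFrame({"observable": "x", "time": [0.0], "value": [1.2],
                           "sigma": [0.1]})
        data = ExperimentData([Experiment("e", [1.0], df)])
        expected = -2.0 - math.log(0.1 * math.sqrt(2 * math.pi))
        assert log_likelihood(decay_model, [1.0], data) == pytest.approx(expected)

    def test_argmax_matches_argmin_of_nls(self, decay_model):
        """Likelihood and weighted NLS rank a theta grid identically."""
        data = _decay_dataset(decay_model, 1.0, np.linspace(0, 2, 6), 0.1,
                              value_offset=0.02)
        grid = np.linspace(0.5, 1.5, 11)
        costs = [nls_cost(decay_model, [t], data).cost for t in grid]
        lls = [log_likelihood(decay_model, [t], data) for t in grid]
        assert np.argmin(costs) == np.argmax(lls)


class TestRegularisation:
    def test_zero_at_reference(self):
        assert regularisation_penalty([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_doubling_gives_n_params(self):
        for ref in ([1.0, 10.0], [0.3, 7.0, 40.0]):
            ref = np.asarray(ref)
            assert regularisation_penalty(2 * ref, ref) == pytest.approx(len(ref))

    def test_hand_value(self):
        # ((0.5/1)^2 + (-5/10)^2) = 0.5
        assert regularisation_penalty([1.5, 5.0], [1.0, 10.0]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        theta = rng.uniform(0.5, 2.0, 4)
        ref = rng.uniform(0.5, 2.0, 4)
        for c in (0.01, 1.0, 250.0):
            assert regularisation_penalty(c * theta, c * ref) == pytest.approx(
                regularisation_penalty(theta, ref))

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            regularisation_penalty([1.0], [0.0])

    def test_regularised_cost_composition(self, decay_model):
        data = _decay_dataset(decay_model, 1.0, np.linspace(0, 2, 6), 0.1,
                              value_offset=0.05)
        q = nls_cost(decay_model, [1.0], data).cost
        # alpha=0 degenerates to plain NLS; theta=ref leaves cost unchanged
        assert regularised_cost(decay_model, [1.0], data, 0.0,
                                [2.0]) == pytest.approx(q)
        assert regularised_cost(decay_model, [1.0], data, 50.0,
                                [1.0]) == pytest.approx(q)
        # Q=q, Gamma=((1-2)/2)^2=0.25, alpha=10 -> q+2.5
        assert regularised_cost(decay_model, [1.0], data, 10.0,
                                [2.0]) == pytest.approx(q + 2.5)


class TestNrmse:
    def test_perfect_fit_zero(self):
        assert nrmse_from_values([(np.array([0.0, 1.0]),
                                   np.array([0.0, 1.0]))]) == 0.0

    def test_half_range_offset_is_half(self):
        # range 1, each residual 0.5 -> sqrt((0.25+0.25)/2) = 0.5
        y = np.array([0.5, 1.5])
        meas = np.array([0.0, 1.0])
        assert nrmse_from_values([(y, meas)]) == pytest.approx(0.5)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        series = []
        for scale in (1.0, 50.0):
            meas = rng.uniform(0, scale, 8)
            sim = meas + rng.normal(0, 0.05 * scale, 8)
            series.append((sim, meas))
        total, n = 0.0, 0
        for sim, meas in series:
            r = meas.max() - meas.min()
            for yi, mi in zip(sim, meas):
                total += ((yi - mi) / r) ** 2
                n += 1
        assert nrmse_from_values(series) == pytest.approx(
            math.sqrt(total / n), rel=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        meas = rng.uniform(0, 1, 10)
        sim = meas + rng.normal(0, 0.1, 10)
        base = nrmse_from_values([(sim, meas)])
        assert nrmse_from_values([(3.0 * sim + 7.0, 3.0 * meas + 7.0)]) == \
            pytest.approx(base)

    def test_constant_series_excluded_with_warning(self):
        good = (np.array([0.5, 1.5]), np.array([0.0, 1.0]))
        flat = (np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        with pytest.warns(UserWarning, match="constant measured series"):
            assert nrmse_from_values([good, flat]) == pytest.approx(0.5)


class TestFitStatistics:
    def test_pseudo_inverse_diagonal_closed_form(self):
        inv, deficient = pseudo_inverse(np.diag([4.0, 25.0]))
        assert not deficient
        assert np.allclose(inv, np.diag([0.25, 0.04]))

    def test_rank_deficiency_detected(self):
        J = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        inv, deficient = pseudo_inverse(J.T @ J)
        assert deficient

    def test_statistics_at_good_fit(self, decay_model):
        data = _decay_dataset(decay_model, 1.0, np.linspace(0.2, 3, 12), 0.05)
        st = fit_statistics(decay_model, [1.0], data)
        assert st.nrmse == pytest.approx(0.0, abs=1e-8)
        assert st.r_squared["x"] == pytest.approx(1.0, abs=1e-10)
        assert st.chi2_stat == pytest.approx(0.0, abs=1e-12)
        assert st.chi2_dof == 11
        assert st.correlation[0, 0] == 1.0
        assert st.bounds_status == ("Bounds not active",)
        # diagonal 1-parameter case: ci95 = 1.96 / ||J col||
        Jnorm = math.sqrt(st.fim[0, 0])
        assert st.ci95[0] == pytest.approx(1.96 / Jnorm)

    def test_duplicated_parameter_gives_unit_correlation(self):
        """Two parameters entering only as a product are perfectly correlated."""
        from oscifit import DynamicModel
        m = DynamicModel("prod", ("x",), ("k1", "k2"), ("-k1*k2*x",),
                         {"fitting": {"x": "x"}}, [1.0],
                         ([0.1, 0.1], [10.0, 10.0]), nominal=[1.0, 1.0])
        times = np.linspace(0.1, 2, 8)
        traj = simulate(m, [1.0, 1.0], x0=[1.0], times=times)
        df = pd.DataFrame({"observable": "x", "time": times,
                           "value": traj.observables[:, 0], "sigma": 0.1})
        data = ExperimentData([Experiment("e", [1.0], df)])
        with pytest.warns(UserWarning, match="non-identifiable"):
            st = fit_statistics(m, [1.0, 1.0], data)
        assert abs(st.correlation[0, 1]) == pytest.approx(1.0, abs=1e-6)

    def test_chi2_skipped_when_dof_nonpositive(self, decay_model):
        df = pd.DataFrame({"observable": "x", "time": [0.5], "value": [0.6],
                           "sigma": [0.1]})
        data = ExperimentData([Experiment("e", [1.0], df)])
        st = fit_statistics(decay_model, [1.0], data)
        assert math.isnan(st.chi2_pvalue)

    def test_expected_cost_near_n_for_matched_noise(self, decay_model):
        """E[Q_NLS(theta*)] ~ n when data noise matches the stored sigma."""
        rng = np.random.default_rng(42)
        times = np.linspace(0.1, 3, 20)
        traj = simulate(decay_model, [1.0], x0=[1.0], times=times)
        y_star = traj.observables[:, 0]
        costs = []
        for _ in range(40):
            sigma = 0.1 * np.abs(y_star)
            noisy = y_star + rng.normal(0, sigma)
            df = pd.DataFrame({"observable": "x", "time": times,
                               "value": noisy, "sigma": sigma})
            data = ExperimentData([Experiment("e", [1.0], df)])
            costs.append(nls_cost(decay_model, [1.0], data).cost)
        n = len(times)
        assert abs(np.mean(costs) - n) < 3 * math.sqrt(2 * n)
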