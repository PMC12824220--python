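"""DDM model zoo, trial-parameter mapping, simulator, and closed-form oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssmlab import (
    count_free_params,
    model_names,
    model_registry,
    simulate_trials,
    static_absorption_probability,
    static_first_passage_density,
    trial_params,
)
from ssmlab.ddm import INTERCEPT


def _const_params(n, **kw):
    base = dict(v=0.0, a=0.6, theta=0.0, z=0.5, t0=0.0, p_outlier=0.0)
    base.update(kw)
    return {k: np.full(n, float(v)) for k, v in base.items()}


class TestRegistry:
    def test_original_star_row(self):
        spec = model_registry("Original*")
        assert spec.bound_type == "static"
        assert spec.formulas["v"] == ("signVD",)
        assert spec.formulas["a"] == (INTERCEPT, "absVD")
        assert spec.extra_params == {"z", "p_outlier"}
        assert spec.coding == "response"

    def test_vdov_both_row(self):
        spec = model_registry("VDOV both")
        assert spec.bound_type == "angle"
        full = (INTERCEPT, "absMaxVD", "absMinVD", "maxOV", "minOV")
        assert spec.formulas["a"] == full
        assert spec.formulas["theta"] == full

    def test_all_thirteen_plus_original_present(self):
        names = set(model_names())
        expected = {"Original", "Original*", "VD", "OV", "VDOV"} | {
            f"{base} {kind}" for base in ("VD", "OV", "VDOV")
            for kind in ("both", "init", "rate")
        }
        assert expected <= names

    def test_unknown_name_lists_valid(self):
        with pytest.raises(KeyError, match="Original\\*"):
            model_registry("nonsense")

    @pytest.mark.parametrize(
        "name,expected",
        [("Original*", 5), ("VDOV both", 14), ("VD", 7), ("OV", 7),
         ("VDOV", 9), ("VD init", 8), ("VD rate", 8), ("VD both", 10),
         ("VDOV init", 10), ("VDOV rate", 10)],
    )
    def test_free_parameter_counts(self, name, expected):
        # non-decision time is excluded by the counting convention
        assert count_free_params(model_registry(name)) == expected


class TestTrialParams:
    @pytest.fixture
    def regressors(self):
        return pd.DataFrame({
            "signVD": [0.1, -0.2], "absVD": [0.1, 0.2],
            "maxVD": [0.2, -0.3], "minVD": [0.0, -0.1],
            "absMaxVD": [0.5, 0.3], "absMinVD": [0.0, 0.1],
            "maxOV": [1.0, 1.2], "minOV": [0.6, 0.8], "OV": [1.6, 2.0],
        })

    def test_null_slopes_give_link_transformed_intercepts(self, regressors):
        spec = model_registry("VD")
        coefs = {"v_maxVD": 0.0, "v_minVD": 0.0, "a_Intercept": 0.3,
                 "a_absMaxVD": 0.0, "a_absMinVD": 0.0,
                 "z": 0.4, "p_outlier": 0.01, "t0": 0.15}
        p = trial_params(spec, coefs, regressors)
        np.testing.assert_allclose(p["v"], 0.0)
        np.testing.assert_allclose(p["a"], np.log1p(np.exp(0.3)))
        np.testing.assert_allclose(p["z"], 0.4)
        np.testing.assert_allclose(p["t0"], 0.15)

    def test_drift_is_linear_in_regressors(self, regressors):
        spec = model_registry("Original*")
        coefs = {"v_signVD": 2.0, "a_Intercept": 0.0, "a_absVD": 0.0,
                 "z": 0.5, "p_outlier": 0.0, "t0": 0.1}
        p1 = trial_params(spec, coefs, regressors)
        doubled = regressors.assign(signVD=regressors["signVD"] * 2)
        p2 = trial_params(spec, coefs, doubled)
        np.testing.assert_allclose(p2["v"], 2 * p1["v"])

    def test_threshold_dot_product_by_hand(self):
        # pre-link threshold 1.0 - 0.2 * 0.5 = 0.9
        spec = model_registry("Original*")
        regressors = pd.DataFrame({"signVD": [0.0], "absVD": [0.5]})
        coefs = {"v_signVD": 0.0, "a_Intercept": 1.0, "a_absVD": -0.2,
                 "z": 0.5, "p_outlier": 0.0, "t0": 0.1}
        p = trial_params(spec, coefs, regressors)
        assert p["a"][0] == pytest.approx(np.log1p(np.exp(0.9)))

    def test_dimension_mismatch_rejected(self, regressors):
        spec = model_registry("Original*")
        with pytest.raises(ValueError, match="missing coefficients"):
            trial_params(spec, {"v_signVD": 1.0}, regressors)


class TestSimulator:
    def test_zero_drift_symmetric(self):
        n = 100_000
        ch, _ = simulate_trials(_const_params(n), dt=0.002, deadline=50.0, seed=1)
        p = (ch == 1).mean()
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_zero_collapse_identical_to_static(self):
        n = 500
        p_static = _const_params(n, v=1.0)
        p_angle = _const_params(n, v=1.0)
        p_angle["theta"] = np.zeros(n)
        c1, r1 = simulate_trials(p_static, dt=0.005, deadline=2.0, seed=9)
        c2, r2 = simulate_trials(p_angle, dt=0.005, deadline=2.0, seed=9)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(r1, r2)

    def test_matches_two_barrier_closed_form(self):
        # barriers 0 and 2 with start 1: P(upper) = (1-e^-2)/(1-e^-4) ~ 0.8808
        n = 100_000
        p_true = static_absorption_probability(1.0, 1.0, 0.5)
        assert p_true == pytest.approx(0.880797, abs=1e-6)
        ch, _ = simulate_trials(_const_params(n, v=1.0, a=1.0), dt=0.002,
                                deadline=100.0, seed=3)
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs((ch == 1).mean() - p_true) < 3 * se

    def test_full_lapse_gives_uniform_rts_and_even_choices(self):
        n = 10_000
        ch, rt = simulate_trials(_const_params(n, v=5.0, p_outlier=1.0),
                                 dt=0.005, deadline=0.75, seed=4)
        assert abs((ch == 1).mean() - 0.5) < 3 * np.sqrt(0.25 / n)
        ks = stats.kstest(rt, stats.uniform(loc=0, scale=0.75).cdf)
        assert ks.pvalue > 0.01

    def test_accuracy_nondecreasing_in_drift(self):
        n = 20_000
        accs = []
        for v in [0.5, 1.5, 3.0, 6.0]:
            ch, _ = simulate_trials(_const_params(n, v=v, a=0.5), dt=0.005,
                                    deadline=5.0, seed=7)
            accs.append((ch == 1).mean())
        se = np.sqrt(0.25 / n)
        assert all(b >= a - 3 * se for a, b in zip(accs, accs[1:]))

    def test_extreme_drift_accuracy_approaches_one(self):
        n = 5_000
        ch, _ = simulate_trials(_const_params(n, v=40.0, a=0.5), dt=0.001,
                                deadline=0.75, seed=2)
        assert (ch == 1).mean() > 0.995

    def test_collapse_reduces_rt_skew(self):
        # the mechanism that lets collapsing bounds capture the data's skew
        n = 50_000
        _, rt_static = simulate_trials(_const_params(n, v=1.0, a=0.8),
                                       dt=0.002, deadline=3.0, seed=5)
        p = _const_params(n, v=1.0, a=0.8)
        p["theta"] = np.full(n, 1.0)
        _, rt_angle = simulate_trials(p, dt=0.002, deadline=3.0, seed=5)
        assert stats.skew(rt_angle[np.isfinite(rt_angle)]) < stats.skew(
            rt_static[np.isfinite(rt_static)]
        )

    def test_halving_dt_stable_choice_probability(self):
        n = 50_000
        ch1, _ = simulate_trials(_const_params(n, v=1.0), dt=0.004,
                                 deadline=10.0, seed=6)
        ch2, _ = simulate_trials(_const_params(n, v=1.0), dt=0.002,
                                 deadline=10.0, seed=16)
        p1, p2 = (ch1 == 1).mean(), (ch2 == 1).mean()
        se = np.sqrt(2 * 0.25 / n)
        assert abs(p1 - p2) < 2 * se

    def test_deterministic_given_seed(self):
        p = _const_params(200, v=1.0)
        a = simulate_trials(p, dt=0.005, deadline=0.75, seed=42)
        b = simulate_trials(p, dt=0.005, deadline=0.75, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    @pytest.mark.parametrize("dt,deadline", [(-0.1, 1.0), (0.0, 1.0), (0.005, 0.0)])
    def test_invalid_step_or_deadline(self, dt, deadline):
        with pytest.raises(ValueError):
            simulate_trials(_const_params(5), dt=dt, deadline=deadline, seed=0)

    def test_single_trial_wrapper_matches_batch(self):
        from ssmlab import simulate_ddm_trial

        ch, rt = simulate_ddm_trial(v=1.0, a=0.5, t0=0.1, dt=0.005,
                                    deadline=0.75, seed=11)
        chb, rtb = simulate_trials(_const_params(1, v=1.0, a=0.5, t0=0.1),
                                   dt=0.005, deadline=0.75, seed=11)
        assert ch == chb[0]
        assert rt == rtb[0] or (np.isnan(rt) and np.isnan(rtb[0]))


class TestStaticOracle:
    def test_zero_drift_absorption_equals_start(self):
        for z in [0.2, 0.5, 0.8]:
            assert static_absorption_probability(0.0, 1.0, z) == pytest.approx(z)

    @pytest.mark.parametrize("v,a,z", [(1.0, 1.0, 0.5), (2.0, 0.5, 0.3),
                                       (-1.5, 0.8, 0.6)])
    def test_density_integrates_to_absorption_probabilities(self, v, a, z):
        t = np.arange(5e-4, 30.0, 5e-4)
        fu, fl = static_first_passage_density(v, a, z, t)
        p_up = static_absorption_probability(v, a, z)
        assert np.trapezoid(fu, t) == pytest.approx(p_up, abs=1e-3)
        assert np.trapezoid(fu + fl, t) == pytest.approx(1.0, abs=1e-3)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            static_absorption_probability(1.0, -1.0, 0.5)
        with pytest.raises(ValueError):
            static_absorption_probability(1.0, 1.0, 1.5)
        with pytest.raises(ValueError):
            static_first_passage_density(1.0, 1.0, 0.5, np.array([0.0, 0.1]))
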