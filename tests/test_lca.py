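"""Rectified leaky competing accumulator: drives, dynamics, datasets."""

import numpy as np
import pandas as pd
import pytest

from ssmlab import LCAParams, build_design, input_drive, simulate_lca_dataset, simulate_lca_trial
from ssmlab._kernels import lca_trajectory
from ssmlab.lca import trial_drives


class TestInputDrive:
    def test_hand_arithmetic(self):
        assert input_drive(1.0, 0.5, 0.8, 0.4) == pytest.approx(0.6)

    def test_full_weight_on_max(self):
        assert input_drive(2.0, 1.0, 0.7, 0.1) == pytest.approx(1.4)

    def test_zero_drive(self):
        assert input_drive(0.0, 0.3, 0.8, 0.4) == 0.0

    def test_ratio_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            input_drive(1.0, 1.2, 0.8, 0.4)


class TestParams:
    def test_exactly_eight_parameters(self):
        assert len(LCAParams.param_names()) == 8

    @pytest.mark.parametrize("field", ["t0", "b", "k", "w", "a0", "c", "sigma"])
    def test_positivity_enforced(self, field):
        with pytest.raises(ValueError):
            LCAParams(**{field: -0.1})

    def test_ratio_bounded(self):
        with pytest.raises(ValueError):
            LCAParams(m=1.5)


class TestSingleTrial:
    def test_noise_free_crossing_time(self):
        # I1 t = a0 - c t  =>  t* = a0 / (I1 + c); leak/inhibition off
        p = LCAParams(t0=0.1, b=10.0, m=1.0, k=1e-9, w=1e-9, a0=0.5, c=1.0,
                      sigma=1e-9)
        winner, rt = simulate_lca_trial(p, (0.4, 0.4), (0.0, 0.0), dt=0.0005,
                                        deadline=5.0, seed=0)
        t_star = 0.5 / (10.0 * 0.4 + 1.0)
        assert winner == 1
        assert rt - 0.1 == pytest.approx(t_star, abs=0.002)

    def test_symmetric_race_is_fair(self):
        p = LCAParams()
        wins = 0
        n = 4000
        design = pd.DataFrame({
            "subject_id": np.ones(n, dtype=int), "trial": np.arange(n) + 1,
            "v_left_high": 0.5, "v_left_low": 0.3,
            "v_right_high": 0.5, "v_right_low": 0.3,
        })
        table = simulate_lca_dataset(p, design, dt=0.002, deadline=5.0, seed=3)
        wins = (table["correct"] == 1).sum()
        resp = table["correct"].notna().sum()
        assert abs(wins / resp - 0.5) < 3 * np.sqrt(0.25 / resp)

    def test_zero_drive_small_noise_omits(self):
        p = LCAParams(b=1e-6, sigma=0.01, a0=1.1, c=1.0)
        winner, rt = simulate_lca_trial(p, (0.0, 0.0), (0.0, 0.0), dt=0.001,
                                        deadline=0.75, seed=1)
        # ReLU pins activations near zero; bound floor (a0/c > window) unreached
        assert winner == 0 and np.isnan(rt)

    def test_invalid_dt_or_deadline(self):
        with pytest.raises(ValueError):
            simulate_lca_trial(LCAParams(), (0.5, 0.3), (0.4, 0.2), dt=-1)
        with pytest.raises(ValueError):
            simulate_lca_trial(LCAParams(t0=0.5), (0.5, 0.3), (0.4, 0.2),
                               deadline=0.4)


class TestDynamics:
    def test_activations_never_negative(self):
        p = LCAParams(b=0.5, sigma=1.2, k=8.0, w=8.0)
        for seed in range(30):
            path = lca_trajectory(0.2, 0.1, p.k, p.w, p.a0, p.c, p.sigma, p.t0,
                                  0.001, 0.75, seed, False)
            assert (path >= 0).all()

    def test_unconstrained_accumulator_behaves_like_drifted_walk(self):
        # k = w = 0 with strong drive: mean activation tracks I * t
        drive = 3.0
        t_probe = 0.2
        acts = []
        for seed in range(300):
            path = lca_trajectory(drive, 0.0, 1e-12, 1e-12, 50.0, 1e-12, 0.3,
                                  0.0, 0.001, 0.5, seed, False)
            acts.append(path[int(t_probe / 0.001), 0])
        se = np.std(acts) / np.sqrt(len(acts))
        assert np.mean(acts) == pytest.approx(drive * t_probe, abs=3 * se + 0.01)

    def test_overall_value_speeds_decisions(self, design_small):
        p = LCAParams()
        table = simulate_lca_dataset(p, design_small, dt=0.002, deadline=0.75,
                                     seed=5, n_concat=3)
        resp = table[table["response"] != "omitted"]
        high = resp[resp["OV"] > resp["OV"].median()]["rt"]
        low = resp[resp["OV"] <= resp["OV"].median()]["rt"]
        assert high.mean() < low.mean() - 0.02

    def test_doubling_drive_speeds_responses(self, design_small):
        fast = simulate_lca_dataset(LCAParams(b=12.0), design_small, dt=0.002,
                                    deadline=0.75, seed=6)
        slow = simulate_lca_dataset(LCAParams(b=6.0), design_small, dt=0.002,
                                    deadline=0.75, seed=6)
        assert (
            fast.loc[fast.response != "omitted", "rt"].mean()
            < slow.loc[slow.response != "omitted", "rt"].mean()
        )

    def test_fit_and_sample_dt_agree(self, design_small):
        p = LCAParams()
        coarse = simulate_lca_dataset(p, design_small, dt=0.005, deadline=0.75,
                                      seed=7, n_concat=4)
        fine = simulate_lca_dataset(p, design_small, dt=0.001, deadline=0.75,
                                    seed=8, n_concat=4)
        n = len(coarse)
        se = np.sqrt(2 * 0.25 / n)
        acc_c = coarse["correct"].mean()
        acc_f = fine["correct"].mean()
        assert abs(acc_c - acc_f) < 3 * se

    def test_printed_inhibition_variant_differs(self, design_small):
        cross = simulate_lca_dataset(LCAParams(), design_small, seed=9)
        printed = simulate_lca_dataset(LCAParams(), design_small, seed=9,
                                       printed_inhibition=True)
        assert not cross["rt"].equals(printed["rt"])


class TestDataset:
    def test_concatenation_reaches_study_scale(self, design_default):
        table = simulate_lca_dataset(LCAParams(), design_default, dt=0.005,
                                     seed=1, n_concat=3)
        assert len(table) == 3 * 22 * 160  # ~10,000 trials as in the mimicry fits

    def test_deterministic(self, design_small):
        a = simulate_lca_dataset(LCAParams(), design_small, seed=2)
        b = simulate_lca_dataset(LCAParams(), design_small, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_n_concat(self, design_small):
        with pytest.raises(ValueError):
            simulate_lca_dataset(LCAParams(), design_small, n_concat=0)

    def test_constant_drive_removes_value_sensitivity(self, design_small):
        table = simulate_lca_dataset(LCAParams(), design_small, seed=3,
                                     n_concat=3, constant_drive=True)
        resp = table[table["response"] != "omitted"]
        high = resp[resp["OV"] > resp["OV"].median()]["rt"]
        low = resp[resp["OV"] <= resp["OV"].median()]["rt"]
        se = np.sqrt(high.var() / len(high) + low.var() / len(low))
        assert abs(high.mean() - low.mean()) < 3 * se

    def test_drives_follow_equation_four(self, design_small):
        p = LCAParams(b=2.0, m=0.75)
        i_corr, i_inc = trial_drives(p, design_small)
        row = design_small.iloc[0]
        left = 2.0 * (0.75 * row.v_left_high + 0.25 * row.v_left_low)
        right = 2.0 * (0.75 * row.v_right_high + 0.25 * row.v_right_low)
        left_sum = row.v_left_high + row.v_left_low
        right_sum = row.v_right_high + row.v_right_low
        expect_corr = left if left_sum >= right_sum else right
        assert i_corr[0] == pytest.approx(expect_corr)
        assert sorted([i_corr[0], i_inc[0]]) == pytest.approx(sorted([left, right]))
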