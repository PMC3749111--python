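"""Scoring metrics and leave-one-out cross-validation mechanics."""

import numpy as np
import pandas as pd
import pytest

from ecogarm import PipelineConfig, TrialSet, loo_cv, nrmse, pearson_cc
from ecogarm.evaluation import _aggregate


class TestPearsonCC:
    def test_identity_and_negation(self, rng):
        x = rng.standard_normal(50)
        assert pearson_cc(x, x) == 1.0
        assert pearson_cc(-x, x) == -1.0

    def test_hand_computed_value(self):
        # 6 / sqrt(5 * 9), recomputed by brute force
        assert abs(pearson_cc([1, 2, 3, 4], [1, 2, 2, 5]) - 0.894427) < 1e-6

    def test_constant_series_flagged_not_zero(self):
        assert np.isnan(pearson_cc(np.ones(10), np.arange(10.0)))

    def test_affine_invariance(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        assert abs(pearson_cc(3.2 * x + 7, y) - pearson_cc(x, y)) < 1e-12

    def test_matches_brute_force_formula_on_random_pairs(self, rng):
        for _ in range(100):
            x, y = rng.standard_normal(30), rng.standard_normal(30)
            dx, dy = x - x.mean(), y - y.mean()
            expect = (dx @ dy) / np.sqrt((dx @ dx) * (dy @ dy))
            assert abs(pearson_cc(x, y) - expect) < 1e-12


class TestNRMSE:
    def test_identity_is_zero(self, rng):
        x = rng.standard_normal(20)
        assert nrmse(x, x) == 0.0

    def test_hand_computed_value(self):
        assert abs(nrmse([0, 1, 3], [0, 1, 2]) - 0.288675) < 1e-6

    def test_constant_offset_identity(self, rng):
        y = rng.standard_normal(30)
        c = 0.37
        expect = abs(c) / np.ptp(y)
        assert abs(nrmse(y + c, y) - expect) < 1e-12

    def test_scaling_law(self, rng):
        pred, actual = rng.standard_normal(25), rng.standard_normal(25)
        a, b = 4.0, 1.3
        assert abs(nrmse(a * pred + b, a * actual + b) - nrmse(pred, actual)) < 1e-12

    def test_constant_actual_flagged(self):
        assert np.isnan(nrmse([1.0, 2.0], [3.0, 3.0]))

    def test_std_normalization_mode(self, rng):
        pred, actual = rng.standard_normal(30), rng.standard_normal(30)
        rmse = np.sqrt(np.mean((pred - actual) ** 2))
        assert abs(nrmse(pred, actual, "std") - rmse / np.std(actual, ddof=1)) < 1e-12

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            pred, actual = rng.standard_normal(30), rng.standard_normal(30)
            expect = np.sqrt(np.mean((pred - actual) ** 2)) / (actual.max() - actual.min())
            assert abs(nrmse(pred, actual) - expect) < 1e-12


def synthetic_feature_cv(seed=0, n_trials=3, snr=np.inf):
    """Feature-level LOO problem: slow envelopes + exactly linear target."""
    rng = np.random.default_rng(seed)
    fs, trial_s, rest_s = 100.0, 8.0, 3.0
    n_bands = 7
    n_ch = 1
    n = int((n_trials * (trial_s + rest_s) + rest_s) * fs)
    t = np.arange(n) / fs
    env = np.column_stack(
        [1 + 0.5 * np.sin(2 * np.pi * f * t + p)
         for f, p in zip(np.linspace(0.2, 0.9, n_ch * n_bands),
                         rng.uniform(0, 2 * np.pi, n_ch * n_bands))]
    )
    if np.isfinite(snr):
        env = env + (0.5 / np.sqrt(2 * snr)) * rng.standard_normal(env.shape)
    w_true = rng.standard_normal(n_bands)
    y = env @ np.concatenate([w_true, np.zeros(env.shape[1] - n_bands)]) + 0.3
    intervals = []
    for k in range(n_trials):
        s = int((rest_s + k * (trial_s + rest_s)) * fs)
        intervals.append((s, s + int(trial_s * fs)))
    trials = TrialSet(intervals=intervals, fs=fs)
    cfg = PipelineConfig(n_lags=10, regression={"validation_fraction": 0.1})
    return env, y, trials, cfg


class TestLooCV:
    def test_one_row_per_trial_and_variable(self):
        env, y, trials, cfg = synthetic_feature_cv()
        rep = loo_cv(None, trials, {"a": y, "b": -y}, cfg, envelopes=env)
        assert len(rep.per_trial) == trials.n_trials * 2
        assert sorted(rep.per_trial["variable"].unique()) == ["a", "b"]
        assert set(rep.per_trial["trial"]) == {0, 1, 2}

    def test_noise_free_linear_target_decoded_nearly_perfectly(self):
        env, y, trials, cfg = synthetic_feature_cv()
        rep = loo_cv(None, trials, {"y": y}, cfg, envelopes=env)
        assert rep.aggregate["mean_cc"].iloc[0] >= 0.99

    def test_exactly_k_fits_per_target(self):
        env, y, trials, cfg = synthetic_feature_cv()
        rep = loo_cv(None, trials, {"y": y}, cfg, keep_models=True, envelopes=env)
        assert len(rep.models) == trials.n_trials

    def test_corrupting_held_out_trial_leaves_training_fits_unchanged(self):
        env, y, trials, cfg = synthetic_feature_cv()
        base = loo_cv(None, trials, {"y": y}, cfg, envelopes=env)
        k = 1
        s, e = trials.intervals[k]
        env2, y2 = env.copy(), y.copy()
        rng = np.random.default_rng(99)
        env2[s:e] = rng.standard_normal((e - s, env.shape[1]))
        y2[s:e] = rng.standard_normal(e - s)
        corrupted = loo_cv(None, trials, {"y": y2}, cfg, envelopes=env2)
        h0 = base.per_trial.set_index("trial")["model_hash"]
        h1 = corrupted.per_trial.set_index("trial")["model_hash"]
        assert h0[k] == h1[k]              # fold-k model never saw trial k
        assert base.per_trial.set_index("trial")["cc"][k] != pytest.approx(
            corrupted.per_trial.set_index("trial")["cc"][k]
        )

    def test_fewer_than_two_trials_rejected(self):
        env, y, trials, cfg = synthetic_feature_cv()
        one = TrialSet(intervals=trials.intervals[:1], fs=trials.fs)
        with pytest.raises(ValueError):
            loo_cv(None, one, {"y": y}, cfg, envelopes=env)

    def test_aggregate_matches_brute_force_sem(self):
        per_trial = pd.DataFrame(
            {
                "trial": [0, 1, 2],
                "variable": ["y"] * 3,
                "cc": [0.8, 0.9, 0.7],
                "nrmse": [0.2, 0.1, 0.3],
                "duration_s": [8.0] * 3,
                "model_hash": ["x"] * 3,
            }
        )
        agg = _aggregate(per_trial).iloc[0]
        cc = np.array([0.8, 0.9, 0.7])
        assert abs(agg["mean_cc"] - cc.mean()) < 1e-12
        assert abs(agg["sem_cc"] - cc.std(ddof=1) / np.sqrt(3)) < 1e-12


class TestPerBand:
    def test_band_restriction_column_count_and_signal_band_wins(self):
        # build features where only band 0 carries the target
        rng = np.random.default_rng(3)
        env, y, trials, cfg = synthetic_feature_cv()
        n = env.shape[0]
        t = np.arange(n) / 100.0
        env = rng.standard_normal((n, 2 * 7)) * 0.3 + 1.0
        drive = np.sin(2 * np.pi * 0.4 * t)
        env[:, 0] += drive      # channel 0, band 0
        env[:, 7] += drive      # channel 1, band 0
        y = drive
        cc_by_band = {}
        for band in ("delta", "alpha", "gamma2"):
            rep = loo_cv(None, trials, {"y": y}, cfg, envelopes=env, band=band)
            cc_by_band[band] = rep.aggregate["mean_cc"].iloc[0]
            assert rep.band_condition == band
        assert cc_by_band["delta"] > max(cc_by_band["alpha"], cc_by_band["gamma2"])

    def test_unknown_band_rejected(self):
        env, y, trials, cfg = synthetic_feature_cv()
        from ecogarm import per_band_cv

        with pytest.raises(ValueError):
            per_band_cv(None, trials, {"y": y}, cfg, band="sigma", envelopes=env)
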