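"""Design matrix contracts, per-timepoint OLS, and cluster permutation."""

import numpy as np
import pandas as pd
import pytest

from metaphysio import (
    ClusterPermutationTest,
    TrialwiseGLM,
    build_design_matrix,
    extract_condition_means,
    group_cluster_permutation,
)


@pytest.fixture(scope="module")
def trials():
    from metaphysio import generate_behavior

    return generate_behavior(n_trials=320, n_blocks=5, seed=21)


class TestDesignMatrix:
    def test_column_order_and_count(self, trials):
        d = build_design_matrix(trials)
        assert d.columns == [
            "intercept", "noise", "cue", "confidence", "noise_x_confidence",
            "cue_x_confidence", "cue_x_noise", "cue_x_noise_x_confidence",
            "mean_orientation", "rt",
        ]
        d9 = build_design_matrix(trials, include_cue_by_noise=False)
        assert "cue_x_noise" not in d9.columns and len(d9.columns) == 9

    def test_z_score_contract(self, trials):
        d = build_design_matrix(trials)
        X = d.values[:, 1:]
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-12)

    def test_balanced_coding_makes_main_effects_orthogonal(self, trials):
        d = build_design_matrix(trials)
        assert d.X["noise"] @ d.X["cue"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_confidence_raises_named_error(self, trials):
        bad = trials.copy()
        bad["confidence"] = 50
        with pytest.raises(ValueError, match="confidence"):
            build_design_matrix(bad)


class TestTrialwiseGLM:
    def test_noiseless_construction_recovered_exactly(self, trials, rng):
        d = build_design_matrix(trials)
        beta = rng.standard_normal((10, 40))
        fit = TrialwiseGLM().fit(d, d.values @ beta)
        np.testing.assert_allclose(fit.coef_, beta, atol=1e-10)

    def test_pure_noise_betas_average_to_zero(self, trials):
        d = build_design_matrix(trials)
        means = []
        for s in range(20):
            y = np.random.default_rng(s).standard_normal((len(trials), 30))
            means.append(TrialwiseGLM().fit(d, y).coef_[1:].mean())
        assert np.mean(means) == pytest.approx(0.0, abs=0.005)

    def test_time_varying_boxcar_recovered(self, trials, rng):
        d = build_design_matrix(trials)
        beta = np.zeros((10, 60))
        beta[1, 20:40] = 2.5  # boxcar on the noise regressor
        fit = TrialwiseGLM().fit(d, d.values @ beta)
        np.testing.assert_allclose(fit.coef_[1], beta[1], atol=1e-10)

    def test_overparameterised_fit_rejected(self):
        with pytest.raises(ValueError, match="regressors"):
            TrialwiseGLM().fit(np.ones((5, 8)), np.ones((5, 10)))

    def test_trial_order_invariance(self, trials, rng):
        d = build_design_matrix(trials)
        y = rng.standard_normal((len(trials), 25))
        perm = rng.permutation(len(trials))
        a = TrialwiseGLM().fit(d.values, y).coef_
        b = TrialwiseGLM().fit(d.values[perm], y[perm]).coef_
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestClusterPermutation:
    def test_saturated_effect_spans_window_at_minimum_p(self, rng):
        betas = 5.0 + 0.1 * rng.standard_normal((12, 80))
        # extent: the single positive cluster spans the whole window
        res = group_cluster_permutation(betas, "cue", n_perm=500, random_state=0)
        pos = [c for c in res.clusters if c.sign == "positive"]
        assert len(pos) == 1
        assert pos[0].extent == 80
        assert pos[0].p_perm <= 0.05
        # mass separates the saturated effect from every sign-flip null,
        # reaching the minimum attainable p (extent ties at the full window
        # for the rare strongly imbalanced flips, so it cannot)
        res_m = group_cluster_permutation(
            betas, "cue", statistic="mass", n_perm=500, random_state=0
        )
        pos_m = [c for c in res_m.clusters if c.sign == "positive"]
        assert pos_m[0].p_perm == pytest.approx(1 / 501)

    def test_injected_window_localised(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            betas = rng.standard_normal((12, 100))
            betas[:, 40:70] += 1.6  # per-point t ~ 5 at n=12
            res = group_cluster_permutation(betas, "x", n_perm=300, random_state=s)
            sig = [c for c in res.significant(0.05) if c.sign == "positive"]
            if not sig:
                continue
            c = max(sig, key=lambda c: c.extent)
            inter = max(0, min(c.end_idx, 69) - max(c.start_idx, 40) + 1)
            union = max(c.end_idx, 69) - min(c.start_idx, 40) + 1
            if inter / union >= 0.5:
                hits += 1
        assert hits >= 18

    def test_sign_symmetry_is_exact(self, rng):
        betas = rng.standard_normal((10, 60))
        betas[:, 10:30] += 0.8
        a = ClusterPermutationTest(random_state=7).fit(betas)
        b = ClusterPermutationTest(random_state=7).fit(-betas)
        np.testing.assert_allclose(b.t_obs_, -a.t_obs_, atol=1e-12)
        pos_a = [(c.start_idx, c.end_idx, c.p_perm) for c in a.result_.clusters if c.sign == "positive"]
        neg_b = [(c.start_idx, c.end_idx, c.p_perm) for c in b.result_.clusters if c.sign == "negative"]
        assert pos_a == neg_b

    def test_zero_betas_produce_no_clusters(self):
        res = group_cluster_permutation(np.zeros((8, 50)), "x", n_perm=200, random_state=0)
        assert res.clusters == []

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            ClusterPermutationTest().fit(np.ones((4, 50)))

    def test_low_n_perm_warns(self, rng):
        with pytest.warns(UserWarning):
            ClusterPermutationTest(n_perm=50, random_state=0).fit(rng.standard_normal((8, 30)))

    def test_mass_statistic_available(self, rng):
        betas = rng.standard_normal((10, 60))
        betas[:, 20:40] += 1.0
        res = group_cluster_permutation(
            betas, "x", statistic="mass", n_perm=200, random_state=0
        )
        assert any(c.p_perm <= 0.05 for c in res.clusters)


class TestConditionMeans:
    def test_zero_nuisance_betas_leave_raw_means(self, trials, rng):
        d = build_design_matrix(trials)
        idx = [d.columns.index(n) for n in ("mean_orientation", "rt")]
        beta = rng.standard_normal((10, 20))
        beta[idx] = 0.0
        y = d.values @ beta
        t_ms = np.arange(20) * 100.0
        out = extract_condition_means(y, trials, t_ms, (0.0, 1900.0))
        raw = pd.DataFrame({"condition": trials["cue"] + "_" + trials["variance"],
                            "value": y.mean(axis=1)})
        raw_means = raw.groupby("condition")["value"].mean()
        for _, row in out.iterrows():
            assert row["mean"] == pytest.approx(raw_means[row["condition"]], abs=1e-9)

    def test_single_sample_window(self, trials, rng):
        y = rng.standard_normal((len(trials), 10))
        t_ms = np.arange(10) * 100.0
        out = extract_condition_means(y, trials, t_ms, (300.0, 300.0))
        assert len(out) == 4

    def test_median_split_labels(self, trials, rng):
        y = rng.standard_normal((len(trials), 10))
        out = extract_condition_means(
            y, trials, np.arange(10) * 100.0, (0.0, 900.0), median_split_confidence=True
        )
        assert set(out["condition"]) == {
            "neutral_low_conf", "neutral_high_conf", "disgust_low_conf", "disgust_high_conf",
        }
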