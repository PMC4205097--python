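"""Mixed logistic model, LOOCV, ROC/AUC, LR tests, bootstrap AUC comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import special

from oscimp import prediction


def _logit_table(n=400, beta=(-1.0, 1.0), cluster_sd=0.0, n_clusters=4, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    cluster = rng.integers(0, n_clusters, n)
    u = cluster_sd * rng.standard_normal(n_clusters)
    eta = beta[0] + beta[1] * x + u[cluster]
    y = rng.random(n) < special.expit(eta)
    return pd.DataFrame(
        {"label": y.astype(int), "x": x, "rat_id": [f"r{c}" for c in cluster]}
    )


class TestFitMixedLogistic:
    def test_fe_only_matches_statsmodels_logit(self):
        table = _logit_table(seed=1)
        res = prediction.fit_mixed_logistic(table, ["x"], fe_only=True)
        sm_res = sm.Logit(table["label"], sm.add_constant(table[["x"]])).fit(disp=0)
        assert np.allclose(res.params.to_numpy(), sm_res.params.to_numpy(), atol=1e-5)
        assert res.loglik == pytest.approx(sm_res.llf, abs=1e-6)
        assert res.re_sd == 0.0

    def test_zero_cluster_variance_collapses_to_logit(self):
        table = _logit_table(cluster_sd=0.0, n_clusters=6, seed=2)
        res = prediction.fit_mixed_logistic(table, ["x"])
        sm_res = sm.Logit(table["label"], sm.add_constant(table[["x"]])).fit(disp=0)
        assert res.re_sd < 0.3
        assert np.allclose(res.params.to_numpy(), sm_res.params.to_numpy(), atol=0.1)

    def test_cluster_variance_recovered(self):
        table = _logit_table(n=1600, cluster_sd=1.5, n_clusters=8, seed=3)
        res = prediction.fit_mixed_logistic(table, ["x"])
        assert 0.5 < res.re_sd < 3.0
        assert res.params["x"] == pytest.approx(1.0, abs=0.35)
        assert res.converged

    def test_cluster_modes_track_true_intercepts(self):
        rng = np.random.default_rng(4)
        n, k = 2000, 8
        cluster = np.repeat(np.arange(k), n // k)
        u_true = np.linspace(-1.5, 1.5, k)
        y = rng.random(n) < special.expit(u_true[cluster])
        table = pd.DataFrame(
            {"label": y.astype(int), "rat_id": [f"r{c}" for c in cluster]}
        )
        res = prediction.fit_mixed_logistic(table, [])
        modes = np.array([res.cluster_modes[f"r{c}"] for c in range(k)])
        assert np.corrcoef(modes, u_true)[0, 1] > 0.9

    def test_single_class_rejected(self):
        table = _logit_table(seed=5)
        table["label"] = 1
        with pytest.raises(ValueError):
            prediction.fit_mixed_logistic(table, ["x"])

    def test_separation_triggers_penalised_refit(self):
        n = 60
        x = np.linspace(-2, 2, n)
        table = pd.DataFrame(
            {
                "label": (x > 0).astype(int),
                "x": x,
                "rat_id": ["a", "b"] * (n // 2),
            }
        )
        with pytest.warns(UserWarning):
            res = prediction.fit_mixed_logistic(table, ["x"], fe_only=True)
        assert res.penalised
        assert np.all(np.isfinite(res.params.to_numpy()))

    def test_predict_matches_expit_oracle(self):
        table = _logit_table(seed=6)
        res = prediction.fit_mixed_logistic(table, ["x"], fe_only=True)
        X = prediction._with_const(table)
        expected = special.expit(
            res.params["const"] + res.params["x"] * table["x"].to_numpy()
        )
        assert np.allclose(res.predict(X), expected)


class TestLoocv:
    def test_intercept_only_equals_leave_one_out_prevalence(self):
        """For the intercept-only fixed model the MLE probability is the
        training-set prevalence, so LOOCV has a closed form."""
        table = _logit_table(n=40, seed=7)
        probs = prediction.loocv_predict(table, [], fe_only=True)
        y = table["label"].to_numpy()
        expected = (y.sum() - y) / (len(y) - 1)
        assert np.allclose(probs, expected, atol=1e-6)

    def test_lone_positive_fold_warns_and_uses_prevalence(self):
        y = np.zeros(20, dtype=int)
        y[3] = 1
        table = pd.DataFrame(
            {"label": y, "x": np.random.default_rng(8).standard_normal(20),
             "rat_id": "r0"}
        )
        with pytest.warns(UserWarning, match="prevalence"):
            probs = prediction.loocv_predict(table, ["x"], fe_only=True)
        assert probs[3] == pytest.approx(0.0)

    def test_informative_predictor_beats_chance_auc(self):
        table = _logit_table(n=300, beta=(-0.5, 2.0), seed=9)
        probs = prediction.loocv_predict(table, ["x"], fe_only=True)
        assert prediction.auc_pair_counting(table["label"].to_numpy(), probs) > 0.7


class TestAuc:
    def test_four_point_oracle(self):
        """Classic example: one discordant pair out of four -> AUC 0.75."""
        auc = prediction.auc_pair_counting([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8])
        assert auc == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        assert prediction.auc_pair_counting([0, 0, 1, 1], [1.0] * 4) == pytest.approx(0.5)

    def test_tie_counts_exactly_one_half(self):
        # pairs: (0.2 vs 0.5)=1, (0.5 vs 0.5)=0.5 -> (1 + 0.5) / 2
        auc = prediction.auc_pair_counting([0, 0, 1], [0.2, 0.5, 0.5])
        assert auc == pytest.approx(0.75)

    def test_perfect_and_inverted_rankings(self):
        assert prediction.auc_pair_counting([0, 1], [0.1, 0.9]) == 1.0
        assert prediction.auc_pair_counting([0, 1], [0.9, 0.1]) == 0.0

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 100)
        y[0], y[1] = 0, 1
        s = rng.standard_normal(100)
        a = prediction.auc_pair_counting(y, s)
        b = prediction.auc_pair_counting(y, np.exp(3 * s))
        assert a == pytest.approx(b)

    def test_roc_sweep_consistency(self):
        labels = np.array([0, 0, 1, 1, 0, 1])
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.55])
        roc = prediction.roc_auc(labels, scores)
        assert roc.auc == pytest.approx(
            prediction.auc_pair_counting(labels, scores)
        )
        assert roc.tpr[0] == 0 and roc.tpr[-1] == 1
        assert roc.fpr[0] == 0 and roc.fpr[-1] == 1
        # accuracy oracle at the no-positive-calls threshold: all negatives right
        assert roc.accuracy[0] == pytest.approx((labels == 0).mean())
        # best threshold calls the top three positive: TP=2, TN=2 -> 4/6
        assert roc.accuracy.max() == pytest.approx(4 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            prediction.auc_pair_counting([1, 1], [0.2, 0.4])


class TestLikelihoodRatio:
    def test_matches_statsmodels_llr(self):
        table = _logit_table(n=300, seed=10)
        small = prediction.fit_mixed_logistic(table, [], fe_only=True)
        large = prediction.fit_mixed_logistic(table, ["x"], fe_only=True)
        stat, df, p = prediction.likelihood_ratio_compare(small, large)
        sm_res = sm.Logit(table["label"], sm.add_constant(table[["x"]])).fit(disp=0)
        assert stat == pytest.approx(sm_res.llr, abs=1e-5)
        assert df == 1
        assert p == pytest.approx(sm_res.llr_pvalue, abs=1e-8)

    def test_non_nested_rejected(self):
        table = _logit_table(seed=11)
        table["z"] = table["x"] ** 2
        a = prediction.fit_mixed_logistic(table, ["x"], fe_only=True)
        b = prediction.fit_mixed_logistic(table, ["z"], fe_only=True)
        with pytest.raises(ValueError):
            prediction.likelihood_ratio_compare(a, b)

    def test_different_data_rejected(self):
        a = prediction.fit_mixed_logistic(_logit_table(n=100, seed=12), [], fe_only=True)
        b = prediction.fit_mixed_logistic(_logit_table(n=120, seed=12), ["x"], fe_only=True)
        with pytest.raises(ValueError):
            prediction.likelihood_ratio_compare(a, b)


class TestBootstrapAuc:
    def _scores(self, n=300, seed=13):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        good = y + 0.5 * rng.standard_normal(n)  # informative
        bad = rng.standard_normal(n)  # noise
        return y, good, bad

    def test_identical_scores_give_null_result(self):
        y, good, _ = self._scores()
        out = prediction.bootstrap_auc_difference(
            y, good, good, n_boot=200, rng=np.random.default_rng(0)
        )
        assert out.d == 0.0
        assert out.p == 1.0

    def test_informative_vs_noise_is_significant(self):
        y, good, bad = self._scores()
        out = prediction.bootstrap_auc_difference(
            y, good, bad, n_boot=500, rng=np.random.default_rng(1)
        )
        assert out.auc_1 > out.auc_2
        assert out.d > 2.0
        assert out.p < 0.05

    def test_seeded_reproducibility(self):
        y, good, bad = self._scores()
        a = prediction.bootstrap_auc_difference(
            y, good, bad, n_boot=100, rng=np.random.default_rng(2)
        )
        b = prediction.bootstrap_auc_difference(
            y, good, bad, n_boot=100, rng=np.random.default_rng(2)
        )
        assert a.d == b.d and a.p == b.p

    def test_sign_antisymmetry(self):
        y, good, bad = self._scores()
        ab = prediction.bootstrap_auc_difference(
            y, good, bad, n_boot=300, rng=np.random.default_rng(3)
        )
        ba = prediction.bootstrap_auc_difference(
            y, bad, good, n_boot=300, rng=np.random.default_rng(3)
        )
        assert ab.d == pytest.approx(-ba.d)


class TestFeatureTable:
    def _inputs(self):
        trials = pd.DataFrame(
            {
                "trial_id": ["t0", "t1", "t2", "t3"],
                "rat_id": ["r0", "r0", "r0", "r0"],
                "outcome": ["correct", "premature", "omission", "incorrect"],
                "prev_rewarded": [True, False, True, False],
                "wait_start_latency": [0.5, 0.4, 0.6, 0.7],
            }
        )
        rows = []
        for tid in ["t0", "t1", "t3"]:
            for ch, region, val in [
                ("c0", "NAcbC", 1.0),
                ("c1", "NAcbC", 3.0),
                ("c2", "PRL", 10.0),
            ]:
                rows.append(
                    {
                        "trial_id": tid,
                        "channel_id": ch,
                        "region": region,
                        "rat_id": "r0",
                        "value": val + (0.0 if tid != "t1" else 1.0),
                    }
                )
        table = pd.DataFrame(rows)
        return trials, {"gamma_nacbc": (table, "NAcbC")}

    def test_electrode_average_and_label(self):
        trials, wt = self._inputs()
        out = prediction.build_trial_feature_table(trials, wt)
        assert "omission" not in set(
            trials.set_index("trial_id").loc[out["trial_id"], "outcome"]
        )
        row_t0 = out[out["trial_id"] == "t0"].iloc[0]
        assert row_t0["gamma_nacbc"] == pytest.approx(2.0)  # mean of 1 and 3
        assert row_t0["label"] == 0
        row_t1 = out[out["trial_id"] == "t1"].iloc[0]
        assert row_t1["gamma_nacbc"] == pytest.approx(3.0)
        assert row_t1["label"] == 1

    def test_trials_without_features_dropped(self):
        trials, wt = self._inputs()
        table, region = wt["gamma_nacbc"]
        wt = {"gamma_nacbc": (table[table["trial_id"] != "t3"], region)}
        out = prediction.build_trial_feature_table(trials, wt)
        assert set(out["trial_id"]) == {"t0", "t1"}
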