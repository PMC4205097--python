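"""Predicting premature responses trial-by-trial: GLMM, LOOCV, ROC/AUC.

Run with ``python examples/05_prediction.py``.
"""

import numpy as np

from oscimp import (
    SimConfig,
    perievent_stats as pes,
    pipeline,
    prediction,
    synthetic,
)

cfg = SimConfig(n_rats=3, session_duration=600.0, seed=9)
sessions = synthetic.simulate_cohort(cfg)
trials = pipeline.analysed_history_trials(pipeline.cohort_trials(sessions))
tensors = pipeline.cohort_tensors(sessions, measures=("gamma60",))

# One LFP feature per trial: wait-start gamma power, averaged over each
# region's electrodes (no electrode-level pseudoreplication).
win = pes.AnalysisWindow("waitstart_gamma60", "wait_start", "gamma60", -0.25, 0.25)
table = pes.window_average(tensors[("wait_start", "gamma60")], win)
features = prediction.build_trial_feature_table(
    trials,
    {
        "gamma60_nacbc": (table, "NAcbC"),
        "gamma60_prl": (table, "PRL"),
    },
)
y = features["label"].to_numpy()
print(f"{len(features)} trials, {y.mean():.1%} premature")

behaviour_terms = ["prev_rewarded", "wait_start_latency"]
lfp_terms = ["gamma60_nacbc", "gamma60_prl"]

scores = {}
for name, terms in [("behaviour", behaviour_terms),
                    ("lfp", lfp_terms),
                    ("full", behaviour_terms + lfp_terms)]:
    probs = prediction.loocv_predict(features, terms)
    scores[name] = probs
    auc = prediction.auc_pair_counting(y, probs)
    print(f"LOOCV AUC ({name:>9}): {auc:.4f}")

# Does adding the LFP features improve the likelihood?
small = prediction.fit_mixed_logistic(features, behaviour_terms)
large = prediction.fit_mixed_logistic(features, behaviour_terms + lfp_terms)
stat, df, p = prediction.likelihood_ratio_compare(small, large)
print(f"\nLR test (behaviour vs full): chi2({df}) = {stat:.2f}, p = {p:.4f}")

# Bootstrap comparison of the cross-validated AUCs.
boot = prediction.bootstrap_auc_difference(
    y, scores["full"], scores["behaviour"],
    n_boot=1000, rng=np.random.default_rng(0),
)
print(f"AUC difference = {boot.auc_1 - boot.auc_2:+.4f}, "
      f"D = {boot.d:.2f}, p = {boot.p:.3f}")
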