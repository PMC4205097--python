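"""Single-trial prediction of premature responses.

A mixed logistic model (binomial GLMM, logit link, rat-level random
intercept) is fitted by maximising the marginal likelihood with adaptive
Gauss-Hermite quadrature (one-dimensional integral per rat). Out-of-sample
probabilities come from leave-one-out cross-validation; classifier quality is
summarised by the ROC curve, AUC (pair counting with ties at 1/2) and the
accuracy-vs-threshold curve; models are compared with likelihood-ratio tests
and a stratified bootstrap test on the AUC difference
D = (AUC1 - AUC2) / sd(bootstrap AUC differences), referred to the standard
normal (two-tailed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

_GH_POINTS = 15


@dataclass
class MixedLogitResult:
    """Fitted mixed (or plain) logistic model."""

    params: pd.Series  # fixed-effect coefficients
    re_sd: float  # random-intercept SD (0 in fixed-effects mode)
    loglik: float
    cluster_modes: dict  # group label -> posterior mode of its intercept
    exog_names: list
    n_obs: int
    converged: bool
    penalised: bool = False
    bse: pd.Series | None = None

    @property
    def df_model(self) -> int:
        return len(self.params) + (1 if self.re_sd > 0 else 0)

    def predict(self, X: pd.DataFrame, groups=None) -> np.ndarray:
        """Per-row response probability.

        For rows from clusters seen in fitting, the cluster's posterior-mode
        intercept is added; unseen clusters get the population-level (zero)
        intercept.
        """
        eta = np.asarray(X[self.exog_names], dtype=float) @ self.params.to_numpy()
        if groups is not None and self.cluster_modes:
            u = np.array([self.cluster_modes.get(g, 0.0) for g in np.asarray(groups)])
            eta = eta + u
        return special.expit(eta)


def _cluster_loglik_and_mode(y, eta, sd, n_quad=_GH_POINTS, u0=0.0):
    """Adaptive Gauss-Hermite marginal log-likelihood of one cluster.

    Returns (log integral of prod_i p(y_i | eta_i + u) * phi(u; 0, sd^2) du,
    posterior mode of u).
    """
    if sd <= 0:
        ll = np.sum(y * eta - np.logaddexp(0, eta))
        return ll, 0.0
    var = sd * sd
    u = u0
    for _ in range(50):  # Newton for the mode of the integrand's log
        p = special.expit(eta + u)
        g = np.sum(y - p) - u / var
        h = -np.sum(p * (1 - p)) - 1.0 / var
        step = g / h
        u -= step
        if abs(step) < 1e-10:
            break
    p = special.expit(eta + u)
    h = np.sum(p * (1 - p)) + 1.0 / var  # positive curvature at the mode
    tau = 1.0 / np.sqrt(h)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    uu = u + np.sqrt(2.0) * tau * nodes
    # log integrand at the quadrature points
    le = (
        np.sum(
            y[:, None] * (eta[:, None] + uu[None, :])
            - np.logaddexp(0, eta[:, None] + uu[None, :]),
            axis=0,
        )
        - 0.5 * (uu / sd) ** 2
        - 0.5 * np.log(2 * np.pi * var)
    )
    lw = np.log(weights) + nodes**2 + np.log(np.sqrt(2.0) * tau)
    ll = special.logsumexp(le + lw)
    return float(ll), float(u)


def _marginal_negloglik(theta, X, y, group_idx, n_groups, penalty=0.0):
    beta = theta[:-1]
    sd = np.exp(theta[-1])
    eta = X @ beta
    total = 0.0
    for g in range(n_groups):
        sel = group_idx == g
        ll, _ = _cluster_loglik_and_mode(y[sel], eta[sel], sd)
        total += ll
    if penalty > 0:
        total -= penalty * np.sum(beta[1:] ** 2) if len(beta) > 1 else 0.0
    return -total


def fit_mixed_logistic(
    table: pd.DataFrame,
    formula_terms: list[str],
    label_col: str = "label",
    group_col: str = "rat_id",
    fe_only: bool = False,
    start: np.ndarray | None = None,
    maxiter: int = 200,
) -> MixedLogitResult:
    """Fit the premature-response GLMM.

    ``formula_terms`` names the predictor columns (an intercept is always
    included; pass an empty list for the intercept-only model). Both classes
    must be present and, unless ``fe_only``, at least two clusters. Complete
    separation triggers a ridge-penalised refit with a warning.
    """
    y = table[label_col].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    exog_names = ["const"] + list(formula_terms)
    X = np.column_stack(
        [np.ones(len(table))]
        + [table[c].astype(float).to_numpy() for c in formula_terms]
    )
    groups = table[group_col].to_numpy()
    labels, group_idx = np.unique(groups, return_inverse=True)
    if not fe_only and labels.size < 2:
        raise ValueError("mixed fit needs >= 2 clusters; use fe_only=True")

    penalty = 0.0
    result = _optimize_mixed(X, y, group_idx, labels.size, fe_only, start, maxiter, penalty)
    beta = result["beta"]
    if np.max(np.abs(beta)) > 30.0:  # symptom of complete separation
        warnings.warn("possible complete separation: refitting with a ridge penalty")
        penalty = 1.0
        result = _optimize_mixed(X, y, group_idx, labels.size, fe_only, start, maxiter, penalty)
        result["penalised"] = True

    sd = result["sd"]
    eta = X @ result["beta"]
    modes = {}
    if sd > 0:
        for g, lab in enumerate(labels):
            sel = group_idx == g
            _, modes[lab] = _cluster_loglik_and_mode(y[sel], eta[sel], sd)
    return MixedLogitResult(
        params=pd.Series(result["beta"], index=exog_names),
        re_sd=sd,
        loglik=result["loglik"],
        cluster_modes=modes,
        exog_names=exog_names,
        n_obs=len(y),
        converged=result["converged"],
        penalised=result.get("penalised", False),
        bse=pd.Series(result["bse"], index=exog_names) if result["bse"] is not None else None,
    )


def _optimize_mixed(X, y, group_idx, n_groups, fe_only, start, maxiter, penalty):
    p = X.shape[1]

    def nll_fixed(beta):
        eta = X @ beta
        val = -np.sum(y * eta - np.logaddexp(0, eta))
        if penalty > 0:
            val += penalty * np.sum(beta**2)
        return val

    def grad_fixed(beta):
        mu = special.expit(X @ beta)
        g = -X.T @ (y - mu)
        if penalty > 0:
            g += 2 * penalty * beta
        return g

    beta0 = start[:p] if start is not None else np.zeros(p)
    fe = optimize.minimize(nll_fixed, beta0, jac=grad_fixed, method="BFGS", options={"maxiter": maxiter})
    if fe_only:
        mu = special.expit(X @ fe.x)
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None])
        try:
            bse = np.sqrt(np.diag(np.linalg.inv(H)))
        except np.linalg.LinAlgError:
            bse = None
        return {
            "beta": fe.x,
            "sd": 0.0,
            "loglik": -nll_fixed(fe.x) + (penalty * np.sum(fe.x**2) if penalty else 0.0),
            "converged": bool(fe.success),
            "bse": bse,
        }

    theta0 = np.concatenate([fe.x, [np.log(0.5)]])
    if start is not None and start.size == p + 1:
        theta0 = start.copy()

    def nll(theta):
        return _marginal_negloglik(theta, X, y, group_idx, n_groups, penalty)

    opt = optimize.minimize(nll, theta0, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6})
    # BFGS reports failure on "precision loss" even at a well-resolved
    # optimum; accept the fit when the scaled gradient is small.
    grad_ok = opt.jac is not None and np.max(np.abs(opt.jac)) < 1e-4 * max(
        1.0, float(len(y))
    )
    opt.success = bool(opt.success or grad_ok)
    beta, log_sd = opt.x[:-1], opt.x[-1]
    sd = float(np.exp(log_sd))
    if sd < 1e-4:  # boundary: variance effectively zero
        sd = 0.0
    # standard errors from the numeric inverse Hessian (fixed effects block)
    bse = None
    if opt.hess_inv is not None:
        hi = np.asarray(opt.hess_inv)
        diag = np.diag(hi)[:p]
        if np.all(diag > 0):
            bse = np.sqrt(diag)
    return {
        "beta": beta,
        "sd": sd,
        "loglik": -nll(opt.x),
        "converged": bool(opt.success),
        "bse": bse,
    }


def loocv_predict(
    table: pd.DataFrame,
    formula_terms: list[str],
    label_col: str = "label",
    group_col: str = "rat_id",
    fe_only: bool = False,
    warm_start: bool = True,
) -> np.ndarray:
    """Leave-one-out cross-validated probability for every trial.

    Trial ``i``'s probability comes from a model refitted to all other trials
    (warm-started from the full fit by default; warm and cold starts agree to
    numerical precision because the likelihood is the same). Folds whose
    training data lose a class fall back to the training prevalence, with a
    warning.
    """
    full = fit_mixed_logistic(table, formula_terms, label_col, group_col, fe_only=fe_only)
    start = np.concatenate(
        [full.params.to_numpy(), [np.log(max(full.re_sd, 1e-3))]]
    ) if not fe_only else full.params.to_numpy()
    probs = np.empty(len(table))
    idx = np.arange(len(table))
    for i in idx:
        train = table.iloc[np.delete(idx, i)]
        if train[label_col].nunique() < 2:
            warnings.warn("single-class training fold; using class prevalence")
            probs[i] = float(train[label_col].mean())
            continue
        fit = fit_mixed_logistic(
            train,
            formula_terms,
            label_col,
            group_col,
            fe_only=fe_only,
            start=start if warm_start else None,
        )
        row = table.iloc[[i]]
        probs[i] = fit.predict(_with_const(row), groups=row[group_col])[0]
    return probs


def _with_const(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["const"] = 1.0
    return out


@dataclass
class RocResult:
    """ROC sweep, AUC and accuracy-vs-threshold curve."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    accuracy: np.ndarray  # accuracy at each threshold
    curve: pd.DataFrame = field(repr=False, default=None)


def auc_pair_counting(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the probability a random positive outranks a random negative,
    ties counted 1/2 (rank/Mann-Whitney form)."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> RocResult:
    """Full ROC sweep with AUC and the accuracy formula
    (TP + TN) / (TP + FP + TN + FN) at each threshold."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    tps = np.concatenate([[0], np.cumsum(sorted_labels)])
    fps = np.concatenate([[0], np.cumsum(~sorted_labels)])
    thresholds = np.concatenate([[np.inf], scores[order]])
    tpr = tps / n_pos
    fpr = fps / n_neg
    acc = (tps + (n_neg - fps)) / (n_pos + n_neg)
    auc = auc_pair_counting(labels, scores)
    curve = pd.DataFrame(
        {"threshold": thresholds, "tpr": tpr, "fpr": fpr, "accuracy": acc}
    )
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc, accuracy=acc, curve=curve)


def likelihood_ratio_compare(model_small: MixedLogitResult, model_large: MixedLogitResult):
    """Likelihood-ratio test of nested models fitted to the same trials.

    Returns ``(chi_square, df, p)`` with the statistic ``2 * delta logLik``
    and df the difference in parameter count.
    """
    if model_small.n_obs != model_large.n_obs:
        raise ValueError("models must be fitted to the same data rows")
    small_terms = set(model_small.exog_names)
    large_terms = set(model_large.exog_names)
    if not small_terms <= large_terms:
        raise ValueError("models are not nested")
    df = model_large.df_model - model_small.df_model
    stat = max(0.0, 2.0 * (model_large.loglik - model_small.loglik))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return float(stat), int(df), p


@dataclass
class BootstrapComparison:
    """Bootstrap AUC-difference test between two score vectors."""

    d: float
    p: float
    auc_1: float
    auc_2: float
    n_boot: int
    delta_draws: np.ndarray = field(repr=False, default=None)


def bootstrap_auc_difference(
    labels: np.ndarray,
    scores_1: np.ndarray,
    scores_2: np.ndarray,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> BootstrapComparison:
    """Two-sided bootstrap test of AUC(scores_1) vs AUC(scores_2).

    Trials are resampled with replacement, stratified by class so every
    resample contains both classes; D = (AUC1 - AUC2) / sd(bootstrap
    differences) is referred to the standard normal.
    """
    rng = rng or np.random.default_rng()
    labels = np.asarray(labels).astype(bool)
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    if not (labels.shape == s1.shape == s2.shape):
        raise ValueError("labels and score vectors must be aligned")
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    auc1 = auc_pair_counting(labels, s1)
    auc2 = auc_pair_counting(labels, s2)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, pos.size, replace=True), rng.choice(neg, neg.size, replace=True)]
        )
        lb = labels[idx]
        deltas[b] = auc_pair_counting(lb, s1[idx]) - auc_pair_counting(lb, s2[idx])
    sd = deltas.std()
    if sd == 0:
        d, p = 0.0, 1.0
    else:
        d = (auc1 - auc2) / sd
        p = float(2 * stats.norm.sf(abs(d)))
    return BootstrapComparison(d=float(d), p=p, auc_1=auc1, auc_2=auc2, n_boot=n_boot, delta_draws=deltas)


def build_trial_feature_table(
    trials: pd.DataFrame,
    window_tables: dict,
) -> pd.DataFrame:
    """One row per analysed trial: electrode-averaged LFP features + behaviour.

    ``window_tables`` maps a feature name (e.g. ``gamma60_nacbc_waitstart``)
    to ``(table, region)`` where ``table`` is a
    :func:`~oscimp.perievent_stats.window_average` output; values are averaged
    across the region's electrodes per trial, so there is one data point per
    physical trial (no electrode-level pseudoreplication). The label is
    premature vs non-premature.
    """
    base = trials[trials["outcome"].isin(["correct", "incorrect", "premature"])].copy()
    base = base[base["prev_rewarded"].notna()]
    out = pd.DataFrame(
        {
            "trial_id": base["trial_id"].to_numpy(),
            "rat_id": base["rat_id"].to_numpy() if "rat_id" in base else np.nan,
            "label": (base["outcome"] == "premature").astype(int).to_numpy(),
            "prev_rewarded": base["prev_rewarded"].astype(bool).astype(int).to_numpy(),
            "wait_start_latency": base["wait_start_latency"].to_numpy(),
        }
    ).set_index("trial_id")
    for name, (table, region) in window_tables.items():
        sub = table[table["region"] == region]
        per_trial = sub.groupby("trial_id")["value"].mean()
        out[name] = per_trial
        if out["rat_id"].isna().all():
            out["rat_id"] = sub.groupby("trial_id")["rat_id"].first()
    out = out.dropna().reset_index()
    return out
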