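"""Trait-impulsivity analysis.

Rats are screened on three long-delay (7 s) sessions; the screening score is
the mean premature count over the three, and the high-impulsivity (HI)
criterion is 50 or more premature responses on each session. Ten LFP-derived
variables (trial-averaged window measures and condition contrasts from NAcbC
and PRL) are extracted per rat, decomposed with a correlation-matrix PCA
followed by oblique (oblimin) rotation targeting 4 factors, and component
scores are regressed on screening scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

from .perievent_stats import AnalysisWindow, PeriEventTensor, window_average

#: HI criterion: premature responses on each long-delay screening session.
HI_THRESHOLD = 50
N_SCREENING_SESSIONS = 3


def screening_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Per-rat screening score and HI flag from long-delay session counts.

    ``records`` has one row per (rat_id, session) with a ``premature_count``
    column. Rats without exactly three sessions are excluded with a warning.
    Returns columns ``rat_id, counts, screening_score, is_hi``.
    """
    rows = []
    for rat, sub in records.groupby("rat_id"):
        counts = sub["premature_count"].to_numpy()
        if counts.size != N_SCREENING_SESSIONS:
            warnings.warn(f"rat {rat}: {counts.size} screening sessions, excluded")
            continue
        rows.append(
            {
                "rat_id": rat,
                "counts": counts.tolist(),
                "screening_score": float(counts.mean()),
                "is_hi": bool((counts >= HI_THRESHOLD).all()),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FeatureSpec:
    """One LFP variable: a window measure, optionally a condition contrast.

    ``contrast``: ``None`` (plain trial average), ``'outcome'`` (correct
    minus error trials) or ``'prev_reward'`` (previously rewarded minus
    non-rewarded).
    """

    name: str
    region: str
    measure: str
    event: str
    t_lo: float
    t_hi: float
    contrast: str | None = None


def default_feature_specs() -> list[FeatureSpec]:
    """The declared 10-variable set: five contrasts per region (NAcbC, PRL)."""
    specs = []
    for region in ("NAcbC", "PRL"):
        r = region.lower()
        specs += [
            FeatureSpec(f"{r}_waitstart_gamma60_prevreward", region, "gamma60", "wait_start", -0.25, 0.25, "prev_reward"),
            FeatureSpec(f"{r}_postpoke_gamma60_outcome", region, "gamma60", "nose_poke", 0.25, 2.0, "outcome"),
            FeatureSpec(f"{r}_postpoke_theta_outcome", region, "theta", "nose_poke", 1.0, 2.0, "outcome"),
            FeatureSpec(f"{r}_waitstart_theta_prevreward", region, "theta", "wait_start", 0.75, 2.0, "prev_reward"),
            FeatureSpec(f"{r}_postpoke_pac_outcome", region, "pac", "nose_poke", 0.75, 2.0, "outcome"),
        ]
    return specs


def _spec_value(table: pd.DataFrame, spec: FeatureSpec) -> float:
    sub = table[table["region"] == spec.region]
    if sub.empty:
        return float("nan")
    if spec.contrast is None:
        return float(sub["value"].mean())
    if spec.contrast == "outcome":
        a = sub.loc[sub["outcome"] == "correct", "value"]
        b = sub.loc[sub["outcome"].isin(["incorrect", "premature"]), "value"]
    elif spec.contrast == "prev_reward":
        a = sub.loc[sub["prev_rewarded"].astype(bool), "value"]
        b = sub.loc[~sub["prev_rewarded"].astype(bool), "value"]
    else:
        raise ValueError(f"unknown contrast {spec.contrast!r}")
    if a.empty or b.empty:
        return float("nan")
    return float(a.mean() - b.mean())


def extract_rat_features(
    tensors: dict,
    specs: list[FeatureSpec] | None = None,
) -> pd.DataFrame:
    """Per-rat feature matrix (rats x variables).

    ``tensors`` maps ``(event, measure)`` to a :class:`PeriEventTensor`
    covering all rats. For each spec the window is averaged per
    trial-electrode pair, then over all of a rat's trials in the spec's
    region (or contrasted between conditions). Rats with a missing entry
    (e.g. no electrodes in a required region) are excluded; the exclusion
    count is logged via a warning.
    """
    specs = specs or default_feature_specs()
    tables = {}
    for spec in specs:
        key = (spec.event, spec.measure)
        if key not in tensors:
            raise KeyError(f"no tensor for event/measure {key}")
        window = AnalysisWindow(spec.name, spec.event, spec.measure, spec.t_lo, spec.t_hi)
        tables[spec.name] = window_average(tensors[key], window)
    rats = sorted(
        set().union(*[set(t["rat_id"].unique()) for t in tables.values()])
    )
    rows = []
    for rat in rats:
        row = {"rat_id": rat}
        for spec in specs:
            t = tables[spec.name]
            row[spec.name] = _spec_value(t[t["rat_id"] == rat], spec)
        rows.append(row)
    out = pd.DataFrame(rows)
    complete = out.dropna()
    n_excluded = len(out) - len(complete)
    if n_excluded:
        warnings.warn(f"{n_excluded} rat(s) excluded for missing features")
    return complete.reset_index(drop=True)


@dataclass
class PcaResult:
    """Correlation-matrix PCA with an oblique-rotation pass."""

    loadings: pd.DataFrame  # unrotated, variables x components
    variance_explained: np.ndarray  # fractions, non-increasing
    rotated_loadings: pd.DataFrame  # variables x n_factors after oblimin
    scores: pd.DataFrame  # per-rat rotated component scores
    unrotated_scores: pd.DataFrame
    rotation: str = "oblimin (gamma=0, direct quartimin)"


def pca_analyze(features: pd.DataFrame, n_factors: int = 4) -> PcaResult:
    """PCA of the standardised feature matrix, then oblimin rotation.

    Eigendecomposition of the correlation matrix gives unrotated loadings
    (eigenvector x sqrt(eigenvalue)) and variance-explained fractions; the
    leading ``n_factors`` components are rotated obliquely and per-rat scores
    computed by least squares against the rotated loadings.
    """
    ids = features["rat_id"] if "rat_id" in features else pd.Series(range(len(features)))
    X = features.drop(columns=["rat_id"], errors="ignore")
    var_names = list(X.columns)
    if len(features) <= n_factors:
        raise ValueError("need more rats than factors")
    Z = np.asarray(X, dtype=float)
    sd = Z.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance feature")
    Z = (Z - Z.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    rank = np.linalg.matrix_rank(corr)
    if rank < corr.shape[0]:
        warnings.warn(f"rank-deficient correlation matrix (rank {rank})")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    loadings = evecs * np.sqrt(evals)
    var_explained = evals / evals.sum()

    A = loadings[:, :n_factors]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        L_rot, _ = rotate_factors(A, "quartimin")
    # align signs so each rotated component loads positively on balance
    signs = np.sign(L_rot.sum(axis=0))
    signs[signs == 0] = 1.0
    L_rot = L_rot * signs

    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    rot_names = [f"PC{i + 1}" for i in range(n_factors)]
    unrot_scores = Z @ evecs
    rot_scores = Z @ np.linalg.pinv(L_rot.T)  # regression scores: Z ~ S @ L'
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=var_names, columns=comp_names),
        variance_explained=var_explained,
        rotated_loadings=pd.DataFrame(L_rot, index=var_names, columns=rot_names),
        scores=pd.DataFrame(rot_scores, index=ids, columns=rot_names),
        unrotated_scores=pd.DataFrame(unrot_scores, index=ids, columns=comp_names),
    )


def regress_pc_on_score(
    pc_scores: pd.Series,
    screening: pd.Series,
    subgroup: pd.Series | None = None,
) -> dict:
    """OLS of a component score on the screening score.

    Returns ``{'slope', 'intercept', 'r2', 'p', 'n'}`` (two-sided p for the
    slope). ``subgroup`` optionally restricts to a boolean mask (e.g. HI
    rats); at least 3 rats must remain.
    """
    x = np.asarray(screening, dtype=float)
    y = np.asarray(pc_scores, dtype=float)
    if subgroup is not None:
        mask = np.asarray(subgroup, dtype=bool)
        x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need >= 3 rats after filtering")
    if x.std() == 0:
        raise ValueError("zero-variance screening score")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "n": int(x.size),
    }
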