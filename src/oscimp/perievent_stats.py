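"""Two-tier peri-event statistics.

Tier one scans each of the 76 points of the 25 Hz peri-event grid (-1 to
+2 s) with a linear mixed model (fixed effects: velocity, upcoming outcome,
previous reward, brain region; random velocity slope and intercept by rat and
intercept by channel within rat), tests each factor with a Wald chi-square,
and reports contiguous runs below the Bonferroni-corrected threshold
P < 0.01 / 75 = 0.00013 that last strictly longer than 0.2 s.

Tier two averages the measure inside named analysis windows and fits the
full-factorial model (outcome x previous reward x region, velocity covariate,
same random structure), Bonferroni-correcting by the number of windows (9)
and following up with all-pair contrasts.

Factors are coded with orthogonal sum-to-zero contrasts so the Wald tests are
type-3. Non-converging fits fall back along a documented ladder (drop the
velocity random slope, then the channel level, then all random effects); the
fallback level is recorded per fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import PeriEventTensor

#: Bonferroni-corrected pointwise threshold: P<0.01 over 75 grid intervals
#: (3 s of peri-event data sampled at 25 Hz), printing as 0.00013.
POINTWISE_ALPHA = 0.01
POINTWISE_COMPARISONS = 75
POINTWISE_THRESHOLD = POINTWISE_ALPHA / POINTWISE_COMPARISONS

#: Epochs must last strictly longer than this (seconds) to be reported.
MIN_EPOCH_DURATION = 0.2

#: Number of analysis windows used for the tier-two Bonferroni correction.
N_ANALYSIS_WINDOWS = 9

#: Fallback ladder labels, in order of application.
FALLBACKS = ("full", "no_velocity_slope", "no_channel", "fixed_effects")


@dataclass(frozen=True)
class AnalysisWindow:
    """Named peri-event window of one measure around one event."""

    name: str
    event: str  # 'wait_start' | 'nose_poke'
    measure: str  # 'gamma60' | 'theta' | 'pac'
    t_lo: float
    t_hi: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.t_lo < self.t_hi <= 2.0):
            raise ValueError(f"window [{self.t_lo}, {self.t_hi}] outside [-1, 2]")


#: Declared default window set (the published set is in supplementary tables
#: not reproduced here); fully configurable.
DEFAULT_WINDOWS = [
    AnalysisWindow("waitstart_gamma60", "wait_start", "gamma60", -0.25, 0.25),
    AnalysisWindow("waitstart_theta", "wait_start", "theta", 0.75, 2.0),
    AnalysisWindow("waitstart_pac", "wait_start", "pac", -1.0, 0.0),
    AnalysisWindow("nosepoke_gamma60_pre", "nose_poke", "gamma60", -0.5, 0.0),
    AnalysisWindow("nosepoke_gamma60_post", "nose_poke", "gamma60", 0.25, 2.0),
    AnalysisWindow("nosepoke_theta_pre", "nose_poke", "theta", -0.5, 0.0),
    AnalysisWindow("nosepoke_theta_post", "nose_poke", "theta", 1.0, 2.0),
    AnalysisWindow("nosepoke_pac_pre", "nose_poke", "pac", -1.0, 0.0),
    AnalysisWindow("nosepoke_pac_post", "nose_poke", "pac", 0.75, 2.0),
]


@dataclass
class ScanResult:
    """Pointwise-scan output: per-(time, factor) tests plus significant epochs."""

    table: pd.DataFrame  # columns: time, factor, statistic, df, p, fallback
    epochs: dict  # factor -> list of (t_start, t_end)
    threshold: float = POINTWISE_THRESHOLD
    min_duration: float = MIN_EPOCH_DURATION


@dataclass
class WindowModelResult:
    """Tier-two windowed-model output for one analysis window."""

    window: AnalysisWindow | None
    terms: pd.DataFrame  # term, statistic, df, p, p_corrected
    posthoc: dict = field(default_factory=dict)
    fallback: str = "full"
    metadata: dict = field(default_factory=dict)


def _long_frame(tensor: PeriEventTensor, k: int) -> pd.DataFrame:
    """Long-format rows (trial x electrode) for time index ``k``."""
    nt, ne = tensor.n_trials, tensor.n_electrodes
    tc = tensor.trial_covariates
    ec = tensor.electrode_covariates
    df = pd.DataFrame(
        {
            "value": tensor.values[:, :, k].ravel(),
            "outcome": np.repeat(tc["outcome"].to_numpy(), ne),
            "prev_rewarded": np.repeat(
                tc["prev_rewarded"].astype(bool).to_numpy(), ne
            ),
            "rat_id": np.tile(ec["rat_id"].to_numpy(), nt),
            "region": np.tile(ec["region"].to_numpy(), nt),
            "channel_id": np.tile(ec["channel_id"].to_numpy(), nt),
        }
    )
    if tensor.velocity is not None:
        df["velocity"] = np.repeat(tensor.velocity[:, k], ne)
    return df


def _fixed_terms(df: pd.DataFrame, interactions: bool = False) -> list[str]:
    """Model terms for the factors that vary in ``df``."""
    factors = []
    for col in ("outcome", "prev_rewarded", "region"):
        if df[col].nunique() > 1:
            factors.append(f"C({col}, Sum)")
    terms = []
    if "velocity" in df.columns and df["velocity"].std() > 0:
        terms.append("velocity")
    if interactions and len(factors) > 1:
        terms.append(" * ".join(factors))
    else:
        terms.extend(factors)
    return terms


def _check_cells(df: pd.DataFrame, factors: list[str]) -> bool:
    """True if every cell of the factorial crossing is populated."""
    cols = [f.split("(")[1].split(",")[0] for f in factors]
    counts = df.groupby(cols, observed=False).size()
    full = np.prod([df[c].nunique() for c in cols])
    return len(counts) == full and (counts > 0).all()


def _fit_ladder(df: pd.DataFrame, formula: str, use_velocity_slope: bool = True):
    """Fit the mixed model, degrading the random structure on failure.

    Returns ``(result, model, fallback_label)``. The final rung is an
    ordinary least-squares fit.
    """
    multi_rat = df["rat_id"].nunique() > 1
    multi_chan = df.groupby("rat_id")["channel_id"].nunique().max() > 1
    attempts = []
    if multi_rat:
        vc = {"channel": "0 + C(channel_id)"} if multi_chan else None
        if use_velocity_slope and "velocity" in formula:
            attempts.append(("full", "~velocity", vc))
        attempts.append(("no_velocity_slope", "~1", vc))
        attempts.append(("no_channel", "~1", None))
    attempts.append(("fixed_effects", None, None))

    for label, re_formula, vc in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if re_formula is None:
                    md = sm.OLS.from_formula(formula, data=df)
                    res = md.fit()
                else:
                    md = sm.MixedLM.from_formula(
                        formula,
                        data=df,
                        groups=df["rat_id"],
                        re_formula=re_formula,
                        vc_formula=vc,
                    )
                    res = md.fit(reml=False, method=["lbfgs", "powell"], maxiter=200)
            if not np.isfinite(np.asarray(res.params, dtype=float)).all():
                continue
            return res, md, label
        except (np.linalg.LinAlgError, ValueError, KeyError):
            continue
    raise RuntimeError("all model fits failed, including fixed-effects")


def _term_tests(res, md, formula_terms: list[str]) -> pd.DataFrame:
    """Wald chi-square test for each named model term (type-3 with Sum coding)."""
    di = md.data.design_info
    n_par = len(np.asarray(res.params))
    rows = []
    for term_name in di.term_names:
        if term_name == "Intercept":
            continue
        slc = di.term_name_slices[term_name]
        k = slc.stop - slc.start
        L = np.zeros((k, n_par))
        for r, c in enumerate(range(slc.start, slc.stop)):
            L[r, c] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wt = res.wald_test(L, use_f=False, scalar=True)
        rows.append(
            {
                "term": term_name,
                "statistic": float(wt.statistic),
                "df": k,
                "p": float(wt.pvalue),
            }
        )
    return pd.DataFrame(rows)


_FACTOR_LABELS = {
    "velocity": "velocity",
    "C(outcome, Sum)": "outcome",
    "C(prev_rewarded, Sum)": "prev_rewarded",
    "C(region, Sum)": "region",
}


def _as_tensor_list(tensors) -> list:
    if isinstance(tensors, PeriEventTensor):
        return [tensors]
    return list(tensors)


def pointwise_scan(
    tensors,
    threshold: float = POINTWISE_THRESHOLD,
    min_duration: float = MIN_EPOCH_DURATION,
) -> ScanResult:
    """Fit the peri-event mixed model at every time point and find epochs.

    ``tensors`` is one :class:`PeriEventTensor` or a per-rat list sharing the
    same offset grid. At each grid point the measure is modelled with fixed
    effects velocity, outcome, previous reward and region, random velocity
    slope/intercept by rat and intercept by channel within rat. Contiguous
    runs of per-factor p-values below ``threshold`` lasting strictly longer
    than ``min_duration`` seconds are reported as significant epochs.
    """
    tensor_list = _as_tensor_list(tensors)
    rows = []
    times = np.asarray(tensor_list[0].offsets, dtype=float)
    for k in range(times.size):
        df = pd.concat(
            [_long_frame(t, k) for t in tensor_list], ignore_index=True
        )
        terms = _fixed_terms(df, interactions=False)
        formula = "value ~ " + " + ".join(terms) if terms else "value ~ 1"
        res, md, fallback = _fit_ladder(df, formula)
        tests = _term_tests(res, md, terms)
        for _, t in tests.iterrows():
            rows.append(
                {
                    "time": times[k],
                    "factor": _FACTOR_LABELS.get(t["term"], t["term"]),
                    "statistic": t["statistic"],
                    "df": t["df"],
                    "p": t["p"],
                    "fallback": fallback,
                }
            )
    table = pd.DataFrame(rows)
    epochs = {
        factor: find_epochs(
            sub.sort_values("time")["time"].to_numpy(),
            sub.sort_values("time")["p"].to_numpy(),
            threshold,
            min_duration,
        )
        for factor, sub in table.groupby("factor")
    }
    return ScanResult(table=table, epochs=epochs, threshold=threshold, min_duration=min_duration)


def find_epochs(
    times: np.ndarray,
    p_values: np.ndarray,
    threshold: float = POINTWISE_THRESHOLD,
    min_duration: float = MIN_EPOCH_DURATION,
) -> list:
    """Contiguous sub-threshold runs lasting strictly longer than the rule.

    Duration is measured between the first and last point of a run, so on the
    25 Hz grid a 6-point run (0.20 s) fails and a 7-point run (0.24 s) is the
    shortest reportable epoch.
    """
    sig = np.asarray(p_values) < threshold
    epochs = []
    i = 0
    n = sig.size
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            if times[j] - times[i] > min_duration:
                epochs.append((float(times[i]), float(times[j])))
            i = j + 1
        else:
            i += 1
    return epochs


def window_average(tensors, window: AnalysisWindow) -> pd.DataFrame:
    """Per-(trial, electrode) time-mean over the closed analysis window.

    ``tensors`` is one :class:`PeriEventTensor` or a per-rat list. Velocity
    (when present) is averaged over the same window and carried as a
    trial-level covariate.
    """
    tensor_list = _as_tensor_list(tensors)
    if len(tensor_list) > 1:
        return pd.concat(
            [window_average(t, window) for t in tensor_list], ignore_index=True
        )
    tensor = tensor_list[0]
    times = np.asarray(tensor.offsets, dtype=float)
    sel = (times >= window.t_lo - 1e-9) & (times <= window.t_hi + 1e-9)
    if not sel.any():
        raise ValueError(f"window {window.name} contains no grid points")
    means = tensor.values[:, :, sel].mean(axis=2)
    nt, ne = means.shape
    tc, ec = tensor.trial_covariates, tensor.electrode_covariates
    df = pd.DataFrame(
        {
            "value": means.ravel(),
            "trial_id": np.repeat(tc["trial_id"].to_numpy(), ne) if "trial_id" in tc else np.repeat(np.arange(nt), ne),
            "outcome": np.repeat(tc["outcome"].to_numpy(), ne),
            "prev_rewarded": np.repeat(tc["prev_rewarded"].astype(bool).to_numpy(), ne),
            "rat_id": np.tile(ec["rat_id"].to_numpy(), nt),
            "region": np.tile(ec["region"].to_numpy(), nt),
            "channel_id": np.tile(ec["channel_id"].to_numpy(), nt),
        }
    )
    if tensor.velocity is not None:
        df["velocity"] = np.repeat(tensor.velocity[:, sel].mean(axis=1), ne)
    df.attrs["window"] = window
    return df


def windowed_model(
    table: pd.DataFrame,
    window: AnalysisWindow | None = None,
    n_windows: int = N_ANALYSIS_WINDOWS,
    posthoc_factors: tuple = ("outcome",),
) -> WindowModelResult:
    """Full-factorial mixed model on one window's per-trial-electrode means.

    Fixed effects: outcome x previous reward x region (all interactions) plus
    the velocity covariate; random structure as in the pointwise scan. Wald
    chi-square per term with sum-to-zero (type-3) coding; p-values multiplied
    by ``n_windows`` (capped at 1). Interactions whose factorial cells are
    not all populated are dropped with a warning. Post-hoc all-pair contrasts
    are run on ``posthoc_factors``.
    """
    df = table.copy()
    factor_terms = [
        f"C({c}, Sum)"
        for c in ("outcome", "prev_rewarded", "region")
        if df[c].nunique() > 1
    ]
    interactions = len(factor_terms) > 1 and _check_cells(df, factor_terms)
    if len(factor_terms) > 1 and not interactions:
        warnings.warn("empty factorial cell: interaction terms dropped")
    terms = []
    if "velocity" in df.columns and df["velocity"].std() > 0:
        terms.append("velocity")
    if interactions:
        terms.append(" * ".join(factor_terms))
    else:
        terms.extend(factor_terms)
    formula = "value ~ " + " + ".join(terms) if terms else "value ~ 1"
    res, md, fallback = _fit_ladder(df, formula)
    tests = _term_tests(res, md, terms)
    tests["p_corrected"] = np.minimum(1.0, n_windows * tests["p"])
    posthoc = {
        f: pairwise_contrasts(res, md, f)
        for f in posthoc_factors
        if df[f].nunique() > 1
    }
    return WindowModelResult(
        window=window,
        terms=tests,
        posthoc=posthoc,
        fallback=fallback,
        metadata={
            "n_windows": n_windows,
            "contrast_df": "residual (t); normal approximation for mixed fits",
        },
    )


def pairwise_contrasts(res, md, factor: str) -> pd.DataFrame:
    """All-pair level contrasts on a sum-coded factor, Bonferroni-adjusted.

    Level effects are recovered from the sum-to-zero coding (the omitted
    level's effect is minus the sum of the others); each pairwise difference
    is tested with a Wald t statistic using residual degrees of freedom.
    """
    di = md.data.design_info
    term = f"C({factor}, Sum)"
    if term not in di.term_name_slices:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    slc = di.term_name_slices[term]
    cols = list(range(slc.start, slc.stop))
    names = di.column_names[slc.start : slc.stop]
    # column labels look like "C(outcome, Sum)[S.correct]"
    coded_levels = [n.split("[S.")[1].rstrip("]") for n in names]
    all_levels = sorted(pd.unique(md.data.frame[factor]).astype(str))
    omitted = [lv for lv in all_levels if lv not in coded_levels]
    n_par = len(np.asarray(res.params))

    def effect_vector(level: str) -> np.ndarray:
        v = np.zeros(n_par)
        if level in coded_levels:
            v[cols[coded_levels.index(level)]] = 1.0
        else:  # omitted level: -sum of the coded effects
            for c in cols:
                v[c] = -1.0
        return v

    levels = coded_levels + omitted
    cov = np.asarray(res.cov_params())
    params = np.asarray(res.params, dtype=float)
    df_resid = max(int(res.nobs) - len(cols) - 1, 1)
    rows = []
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    for a, b in pairs:
        L = effect_vector(a) - effect_vector(b)
        est = float(L @ params)
        se = float(np.sqrt(L @ cov @ L))
        t = est / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df_resid) if np.isfinite(t) else np.nan
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se, "t": t, "p": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.minimum(1.0, out["p"] * len(pairs))
    return out


def build_tensor(
    measures: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    trial_covariates: pd.DataFrame,
    electrode_covariates: pd.DataFrame,
    velocity_series: np.ndarray | None = None,
    fs_velocity: float = 25.0,
    window: tuple = (-1.0, 2.0),
    measure: str = "",
    event: str = "",
) -> PeriEventTensor:
    """Assemble a PeriEventTensor from per-electrode measure series.

    ``measures`` is (n_electrodes, n_samples) at ``fs``; events whose window
    is incomplete on any electrode are dropped from all electrodes (and from
    the covariates). Velocity, when given, is aligned on the same grid.
    """
    from .spectral import peri_event_extract

    event_times = np.asarray(event_times, dtype=float)
    t_max = (measures.shape[1] - 1) / fs
    keep = (event_times + window[0] >= 0) & (event_times + window[1] <= t_max)
    kept_events = event_times[keep]
    segs = []
    offsets = None
    for sig in measures:
        s, offsets, _ = peri_event_extract(sig, fs, kept_events, window)
        segs.append(s)
    values = np.stack(segs, axis=1) if segs else np.empty((0, 0, 0))
    vel = None
    if velocity_series is not None:
        vel, _, _ = peri_event_extract(velocity_series, fs_velocity, kept_events, window)
    return PeriEventTensor(
        values=values,
        offsets=offsets,
        trial_covariates=trial_covariates.loc[keep].reset_index(drop=True),
        electrode_covariates=electrode_covariates.reset_index(drop=True),
        velocity=vel,
        n_dropped=int((~keep).sum()),
        measure=measure,
        event=event,
    )
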