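"""Behavioural event detection and summaries.

Wait-start is the first moment after trial start at which the head position
is strictly outside the rectangle surrounding the food magazine — the onset
of waiting/scanning behaviour. This module detects that event from 25 Hz
tracking, annotates reward history, derives the smoothed head velocity used
as a model covariate, and runs the 2x2 contingency analysis of premature
responding against previous-trial outcome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MagazineROI

#: Centred moving-average window (frames at 25 Hz) applied to velocity.
VELOCITY_SMOOTH_FRAMES = 5


def detect_wait_start(
    tracking: pd.DataFrame,
    roi: MagazineROI,
    t_trial_start: float,
    t_end: float | None = None,
) -> float:
    """Time of the first tracking sample at/after ``t_trial_start`` whose
    position is strictly outside ``roi``.

    Returns ``nan`` if the head never leaves the rectangle before ``t_end``
    (the trial's terminal event, or the end of the trace). Raises if the
    search interval is not covered by the trace (a tracking gap).
    """
    t = tracking["t"].to_numpy()
    if t_end is None:
        t_end = t[-1]
    sel = (t >= t_trial_start) & (t <= t_end)
    if not sel.any():
        raise ValueError("tracking gap: no samples cover the search interval")
    dt = np.diff(t[sel])
    if dt.size and dt.max() > 3.0 * np.median(np.diff(t)):
        raise ValueError("tracking gap overlapping the search interval")
    inside = roi.contains(tracking["x"].to_numpy()[sel], tracking["y"].to_numpy()[sel])
    outside_idx = np.flatnonzero(~inside)
    if outside_idx.size == 0:
        return float("nan")
    return float(t[sel][outside_idx[0]])


def detect_wait_starts(
    trials: pd.DataFrame, tracking: pd.DataFrame, roi: MagazineROI
) -> pd.DataFrame:
    """Fill ``t_wait_start``/``wait_start_latency`` for every analysed trial
    from the tracking trace; omissions and never-exiting trials get ``nan``."""
    out = trials.copy()
    detected = []
    for _, tr in trials.iterrows():
        t_term = tr["t_nosepoke"]
        if not np.isfinite(t_term):
            detected.append(float("nan"))
            continue
        detected.append(detect_wait_start(tracking, roi, tr["t_trial_start"], t_term))
    out["t_wait_start"] = detected
    out["wait_start_latency"] = out["t_wait_start"] - out["t_trial_start"]
    return out


def annotate_history(trials: pd.DataFrame) -> pd.DataFrame:
    """Fill ``prev_outcome``/``prev_rewarded`` from the immediately preceding
    analysed (non-omission) trial.

    The first analysed trial of the session — and any trial whose only
    predecessors are omissions — has no history and gets null values; such
    trials are excluded from history-conditioned analyses. Rows must be
    time-ordered.
    """
    if not trials["t_trial_start"].is_monotonic_increasing:
        raise ValueError("trials must be ordered by time")
    out = trials.copy()
    prev_outcome: list = []
    prev_rewarded: list = []
    last: str | None = None
    for outcome in trials["outcome"]:
        prev_outcome.append(last)
        prev_rewarded.append(None if last is None else last == "correct")
        if outcome != "omission":
            last = outcome
    out["prev_outcome"] = prev_outcome
    out["prev_rewarded"] = prev_rewarded
    return out


def contingency_chi_square(counts) -> tuple[float, int, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table.

    Returns ``(statistic, df, p)`` with ``df = 1`` and a two-sided p-value
    from the chi-square distribution. All margins must be positive.
    """
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    stat, p, df, _ = stats.chi2_contingency(table, correction=True)
    return float(stat), int(df), float(p)


def premature_contingency(trials: pd.DataFrame) -> pd.DataFrame:
    """2x2 counts of premature vs non-premature by previous reward.

    Rows: (premature, non-premature); columns: (prev correct, prev error).
    Only history-annotated analysed trials contribute.
    """
    t = trials[
        trials["outcome"].isin(["correct", "incorrect", "premature"])
        & trials["prev_rewarded"].notna()
    ]
    prem = t["outcome"] == "premature"
    prev_r = t["prev_rewarded"].astype(bool)
    return pd.DataFrame(
        [
            [int((prem & prev_r).sum()), int((prem & ~prev_r).sum())],
            [int((~prem & prev_r).sum()), int((~prem & ~prev_r).sum())],
        ],
        index=["premature", "non_premature"],
        columns=["prev_correct", "prev_error"],
    )


def velocity_from_tracking(tracking: pd.DataFrame) -> np.ndarray:
    """Head speed (tracking units/s) from frame-to-frame displacement,
    smoothed with a centred 5-frame moving average (length preserved by edge
    padding)."""
    t = tracking["t"].to_numpy()
    if t.size < 2:
        raise ValueError("need at least 2 tracking samples")
    if (np.diff(t) <= 0).any():
        raise ValueError("non-monotonic timestamps")
    dx = np.diff(tracking["x"].to_numpy())
    dy = np.diff(tracking["y"].to_numpy())
    speed = np.hypot(dx, dy) / np.diff(t)
    speed = np.concatenate([speed, speed[-1:]])  # length-preserving
    pad = VELOCITY_SMOOTH_FRAMES // 2
    padded = np.pad(speed, pad, mode="edge")
    kernel = np.ones(VELOCITY_SMOOTH_FRAMES) / VELOCITY_SMOOTH_FRAMES
    return np.convolve(padded, kernel, mode="valid")
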