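"""End-to-end orchestration: from simulated or loaded sessions to peri-event
tensors, trial feature tables and rat feature matrices.

Each rat contributes one tensor (its trials x its electrodes); cohort-level
statistics consume lists of tensors, keeping trials attached to the rat and
electrodes that produced them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import behaviour, pac, spectral
from .datatypes import GAMMA60, THETA, BandDefinition, SessionRecording
from .perievent_stats import build_tensor
from .synthetic import SimulatedSession

BANDS = {"gamma60": GAMMA60, "theta": THETA}


def band_power_series(recording: SessionRecording, band: BandDefinition) -> np.ndarray:
    """Session-z-scored band power per channel, (n_channels, n_samples)."""
    return np.vstack(
        [spectral.cwt_band_power(sig, recording.fs, band) for sig in recording.signals]
    )


def pac_time_series(
    recording: SessionRecording,
    pf: float = 2.75,
    af_band: tuple = (55.0, 60.0),
    window: float = 1.0,
    step: float = 0.02,
    fs_out: float = 25.0,
) -> tuple[np.ndarray, float]:
    """Moving-window PAC per channel, interpolated onto a uniform grid.

    Returns ``(series, fs_out)`` with ``series`` of shape
    (n_channels, n_samples_out) spanning the whole session.
    """
    n_out = int(round(recording.duration * fs_out))
    t_grid = np.arange(n_out) / fs_out
    out = np.empty((recording.n_channels, n_out))
    for i, sig in enumerate(recording.signals):
        t_c, v = pac.moving_window_pac(sig, recording.fs, pf, af_band, window, step)
        ok = np.isfinite(v)
        out[i] = np.interp(t_grid, t_c[ok], v[ok])
    return out, fs_out


def analysed_history_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials entering peri-event models: analysed outcome, known history."""
    t = trials[trials["outcome"].isin(["correct", "incorrect", "premature"])]
    return t[t["prev_rewarded"].notna()].copy()


def session_tensors(
    session: SimulatedSession,
    events: tuple = ("wait_start", "nose_poke"),
    measures: tuple = ("gamma60", "theta", "pac"),
) -> dict:
    """Peri-event tensors for one session, keyed ``(event, measure)``.

    Trial ids are globalised as ``"<rat>:<trial>"`` so cohort-level tables
    can be concatenated without collisions.
    """
    rec = session.recording
    trials = analysed_history_trials(session.trials)
    velocity = behaviour.velocity_from_tracking(session.tracking)
    fs_track = 1.0 / np.median(np.diff(session.tracking["t"]))

    series = {}
    for m in measures:
        if m == "pac":
            series[m] = pac_time_series(rec)
        else:
            series[m] = (band_power_series(rec, BANDS[m]), rec.fs)

    covariates = pd.DataFrame(
        {
            "trial_id": [f"{session.rat_id}:{t}" for t in trials["trial_id"]],
            "outcome": trials["outcome"].to_numpy(),
            "prev_rewarded": trials["prev_rewarded"].astype(bool).to_numpy(),
            "wait_start_latency": trials["wait_start_latency"].to_numpy(),
        }
    )
    out = {}
    for event in events:
        col = "t_wait_start" if event == "wait_start" else "t_nosepoke"
        times = trials[col].to_numpy()
        for m in measures:
            sig, fs = series[m]
            out[(event, m)] = build_tensor(
                sig,
                fs,
                times,
                covariates,
                rec.channels,
                velocity_series=velocity,
                fs_velocity=fs_track,
                measure=m,
                event=event,
            )
    return out


def cohort_tensors(sessions: list, **kwargs) -> dict:
    """Per-rat tensors across a cohort: ``(event, measure) -> [tensor, ...]``."""
    merged: dict = {}
    for s in sessions:
        for key, tensor in session_tensors(s, **kwargs).items():
            merged.setdefault(key, []).append(tensor)
    return merged


def cohort_trials(sessions: list) -> pd.DataFrame:
    """Concatenated trial tables with globally unique trial ids."""
    frames = []
    for s in sessions:
        t = s.trials.copy()
        t["rat_id"] = s.rat_id
        t["trial_id"] = [f"{s.rat_id}:{k}" for k in t["trial_id"]]
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
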