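"""Session-bundle persistence.

A session directory holds ``signals.npy`` (channels x samples), a
``session.yaml`` sidecar (sampling rate and channel table), ``trials.csv``
and ``tracking.csv``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import SessionRecording, TRIAL_COLUMNS, validate_trials

_SIDE = "session.yaml"
_SIG = "signals.npy"
_TRIALS = "trials.csv"
_TRACK = "tracking.csv"


def save_session(
    directory,
    recording: SessionRecording,
    trials: pd.DataFrame,
    tracking: pd.DataFrame,
) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / _SIG, recording.signals)
    sidecar = {
        "fs": float(recording.fs),
        "channels": recording.channels.to_dict(orient="records"),
    }
    (d / _SIDE).write_text(yaml.safe_dump(sidecar, sort_keys=False))
    validate_trials(trials)
    trials[TRIAL_COLUMNS].to_csv(d / _TRIALS, index=False)
    tracking[["t", "x", "y"]].to_csv(d / _TRACK, index=False)
    return d


def load_session(directory) -> tuple[SessionRecording, pd.DataFrame, pd.DataFrame]:
    d = Path(directory)
    sidecar = yaml.safe_load((d / _SIDE).read_text())
    recording = SessionRecording(
        signals=np.load(d / _SIG),
        fs=float(sidecar["fs"]),
        channels=pd.DataFrame(sidecar["channels"]),
    )
    trials = pd.read_csv(d / _TRIALS)
    tracking = pd.read_csv(d / _TRACK)
    return recording, validate_trials(trials), tracking
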