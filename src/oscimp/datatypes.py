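"""Core in-memory containers shared across the analysis pipeline.

Continuous signals live in :class:`SessionRecording`; per-trial events in a
pandas ``DataFrame`` following the :data:`TRIAL_COLUMNS` convention; head
tracking in a ``DataFrame`` with columns ``t, x, y``. Peri-event analyses
operate on :class:`PeriEventTensor` (trials x electrodes x time) and
cross-frequency coupling on :class:`Comodulogram`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column convention for trial tables (times in seconds from session start).
TRIAL_COLUMNS = [
    "trial_id",
    "t_trial_start",
    "t_wait_start",
    "t_stimulus",
    "t_nosepoke",
    "t_magazine_return",
    "outcome",
    "prev_outcome",
    "prev_rewarded",
    "wait_start_latency",
]

OUTCOMES = ("correct", "incorrect", "premature", "omission")
#: Outcomes entering peri-event analyses (omissions lack a nose-poke).
ANALYSED_OUTCOMES = ("correct", "incorrect", "premature")

REGIONS = ("PRL", "IL", "NAcbC", "NAcbSh")


@dataclass
class SessionRecording:
    """Continuous multi-electrode LFP with per-channel metadata.

    Parameters
    ----------
    signals : ndarray, shape (n_channels, n_samples)
        Voltage traces (arbitrary gain).
    fs : float
        Sampling rate in Hz.
    channels : DataFrame
        One row per channel: ``channel_id, rat_id, region, shank``.
    """

    signals: np.ndarray
    fs: float
    channels: pd.DataFrame

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (channels x samples)")
        if len(self.channels) != self.signals.shape[0]:
            raise ValueError("channel table rows must match signal rows")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_indices(self, region: str) -> np.ndarray:
        """Row indices of channels in ``region``."""
        return np.flatnonzero(self.channels["region"].to_numpy() == region)

    def check_nyquist(self, f_top: float, factor: float = 2.2) -> None:
        """Raise if ``fs`` is below ``factor`` times the top analysis frequency."""
        if self.fs < factor * f_top:
            raise ValueError(
                f"fs={self.fs} Hz too low for analyses up to {f_top} Hz "
                f"(need >= {factor * f_top} Hz)"
            )


@dataclass(frozen=True)
class BandDefinition:
    """Named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"invalid band {self.name}: [{self.f_lo}, {self.f_hi}]")


#: Band defaults: peak-power bands of the prefrontal/accumbens recordings.
THETA = BandDefinition("theta", 7.5, 9.5)
GAMMA60 = BandDefinition("gamma60", 55.0, 60.0)


@dataclass(frozen=True)
class MagazineROI:
    """Rectangle around the food magazine, in tracking coordinates."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate magazine rectangle")

    def contains(self, x, y) -> np.ndarray:
        """Boolean mask of points inside or on the boundary of the rectangle."""
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )


@dataclass
class PowerLawFit:
    """Coefficients of y = a * x**b fitted over ``f_range``."""

    a: float
    b: float
    f_range: tuple
    residual: float

    def __call__(self, x) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** self.b


@dataclass
class PeriEventTensor:
    """Trial x electrode x time array of a band measure aligned to an event.

    ``values[i, j, k]`` is the measure for trial ``trial_covariates.iloc[i]``
    on electrode ``electrode_covariates.iloc[j]`` at offset ``offsets[k]``
    seconds from the alignment event. ``velocity[i, k]`` carries the matching
    head-velocity covariate (shared across electrodes of a trial).
    """

    values: np.ndarray
    offsets: np.ndarray
    trial_covariates: pd.DataFrame
    electrode_covariates: pd.DataFrame
    velocity: np.ndarray | None = None
    n_dropped: int = 0
    measure: str = ""
    event: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be trials x electrodes x time")
        if v.shape[0] != len(self.trial_covariates):
            raise ValueError("trial covariates must align with values")
        if v.shape[1] != len(self.electrode_covariates):
            raise ValueError("electrode covariates must align with values")
        if v.shape[2] != len(self.offsets):
            raise ValueError("offsets must align with time axis")
        self.values = v

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[1]


@dataclass
class Comodulogram:
    """Phase-frequency x amplitude-frequency matrix of coupling values."""

    pf: np.ndarray
    af: np.ndarray
    esc: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.esc = np.asarray(self.esc, dtype=float)
        if self.esc.shape != (len(self.pf), len(self.af)):
            raise ValueError("esc matrix must be (len(pf), len(af))")

    def argmax(self, rel_threshold: float = 0.95) -> tuple:
        """(pf, af) of the coupling peak.

        The band-pass filters behind each cell are wider than the grid step,
        so neighbouring cells are strongly dependent and a true coupling shows
        up as a near-flat plateau whose literal maximum is decided by noise.
        The peak is therefore located as the |ESC|-weighted centroid of the
        region within ``rel_threshold`` of the maximum (the centre of the
        plateau), snapped to the nearest grid point.
        """
        a = np.abs(self.esc)
        peak = a.max()
        if peak == 0:
            return float(self.pf[0]), float(self.af[0])
        w = np.where(a >= rel_threshold * peak, a, 0.0)
        pf_c = float(w.sum(axis=1) @ self.pf / w.sum())
        af_c = float(w.sum(axis=0) @ self.af / w.sum())
        i = int(np.argmin(np.abs(np.asarray(self.pf) - pf_c)))
        j = int(np.argmin(np.abs(np.asarray(self.af) - af_c)))
        return float(self.pf[i]), float(self.af[j])


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-table convention and within-trial event ordering."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = ~trials["outcome"].isin(OUTCOMES)
    if bad.any():
        raise ValueError(f"unknown outcomes: {trials.loc[bad, 'outcome'].unique()}")
    for early, late in [
        ("t_trial_start", "t_wait_start"),
        ("t_wait_start", "t_nosepoke"),
    ]:
        both = trials[[early, late]].dropna()
        if (both[late] <= both[early]).any():
            raise ValueError(f"{late} must follow {early} within each trial")
    return trials


def analysed_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials ending in a correct, incorrect or premature response."""
    return trials[trials["outcome"].isin(ANALYSED_OUTCOMES)].copy()
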