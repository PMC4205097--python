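"""Phase-amplitude coupling via envelope-to-signal correlation (ESC).

ESC(pf, af) is the Pearson correlation between the band-pass-filtered
low-frequency (phase-giving) signal and the amplitude envelope of the
band-pass-filtered high-frequency signal. It is signed and bounded in
[-1, 1]; comodulogram displays use |ESC|, signed values are retained.

Default filter bandwidths (the toolbox's are unpublished): phase band
pf +/- 1 Hz, amplitude band af +/- 2.5 Hz unless an explicit band is given.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .datatypes import Comodulogram

#: Default half-bandwidths (Hz) of the phase and amplitude filters.
PF_HALF_BW = 1.0
AF_HALF_BW = 2.5

DEFAULT_PF_GRID = np.arange(1.5, 10.0 + 1e-9, 0.25)
DEFAULT_AF_GRID = np.arange(30.0, 80.0 + 1e-9, 2.5)


def bandpass(x: np.ndarray, fs: float, f_lo: float, f_hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    if not 0 < f_lo < f_hi < fs / 2:
        raise ValueError(f"band [{f_lo}, {f_hi}] invalid at fs={fs}")
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def amplitude_envelope(x_filtered: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude via the analytic-signal magnitude."""
    return np.abs(sps.hilbert(x_filtered))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("undefined correlation: constant input")
    return float(np.corrcoef(a, b)[0, 1])


def esc_from_components(filt_low: np.ndarray, amp_high: np.ndarray) -> float:
    """Signed ESC from precomputed filtered-low and high-envelope series."""
    if filt_low.shape != amp_high.shape:
        raise ValueError("component series must have equal length")
    return _pearson(filt_low, amp_high)


def esc(
    x: np.ndarray,
    fs: float,
    pf: float,
    af: float,
    pf_bw: float = 2 * PF_HALF_BW,
    af_bw: float = 2 * AF_HALF_BW,
) -> float:
    """ESC between phase frequency ``pf`` and amplitude frequency ``af``.

    ``pf_bw``/``af_bw`` are full bandwidths of the two zero-phase band-pass
    filters; the bands must not overlap, and the signal must span at least
    10 cycles of ``pf``.
    """
    if pf + pf_bw / 2 >= af - af_bw / 2:
        raise ValueError("phase and amplitude bands must be disjoint")
    x = np.asarray(x, dtype=float)
    if x.size < 10 * fs / pf:
        raise ValueError("signal shorter than 10 cycles of the phase frequency")
    filt_low = bandpass(x, fs, pf - pf_bw / 2, pf + pf_bw / 2)
    amp_high = amplitude_envelope(bandpass(x, fs, af - af_bw / 2, af + af_bw / 2))
    return esc_from_components(filt_low, amp_high)


def comodulogram_session(
    x: np.ndarray,
    fs: float,
    pf_grid: np.ndarray = DEFAULT_PF_GRID,
    af_grid: np.ndarray = DEFAULT_AF_GRID,
    meta: dict | None = None,
) -> Comodulogram:
    """Whole-recording comodulogram over a (pf, af) grid.

    The signal is filtered once per grid frequency; envelopes are cached per
    amplitude frequency. Entries are signed ESC values.
    """
    x = np.asarray(x, dtype=float)
    lows = [bandpass(x, fs, pf - PF_HALF_BW, pf + PF_HALF_BW) for pf in pf_grid]
    envs = [
        amplitude_envelope(bandpass(x, fs, af - AF_HALF_BW, af + AF_HALF_BW))
        for af in af_grid
    ]
    mat = np.empty((len(pf_grid), len(af_grid)))
    for i, lo in enumerate(lows):
        for j, env in enumerate(envs):
            mat[i, j] = _pearson(lo, env)
    return Comodulogram(pf=np.asarray(pf_grid), af=np.asarray(af_grid), esc=mat, meta=meta or {})


def comodulogram_cross_electrode(
    recording,
    region: str,
    pf_grid: np.ndarray = DEFAULT_PF_GRID,
    af_grid: np.ndarray = DEFAULT_AF_GRID,
) -> Comodulogram:
    """Cross-electrode control: phase and amplitude from different electrodes.

    ESC is computed for every ordered (phase-electrode, amplitude-electrode)
    pair in the region, self-pairs excluded, and averaged into one matrix.
    Artefactual within-electrode coupling cannot survive this control.
    """
    idx = recording.channel_indices(region)
    if idx.size < 2:
        raise ValueError(f"cross-electrode PAC needs >=2 channels in {region!r}")
    fs = recording.fs
    lows = {
        i: [bandpass(recording.signals[i], fs, pf - PF_HALF_BW, pf + PF_HALF_BW) for pf in pf_grid]
        for i in idx
    }
    envs = {
        i: [
            amplitude_envelope(bandpass(recording.signals[i], fs, af - AF_HALF_BW, af + AF_HALF_BW))
            for af in af_grid
        ]
        for i in idx
    }
    acc = np.zeros((len(pf_grid), len(af_grid)))
    n_pairs = 0
    for i in idx:
        for j in idx:
            if i == j:
                continue
            for a, lo in enumerate(lows[i]):
                for b, env in enumerate(envs[j]):
                    acc[a, b] += _pearson(lo, env)
            n_pairs += 1
    return Comodulogram(
        pf=np.asarray(pf_grid),
        af=np.asarray(af_grid),
        esc=acc / n_pairs,
        meta={"region": region, "n_pairs": n_pairs, "mode": "cross_electrode"},
    )


def moving_window_pac(
    x: np.ndarray,
    fs: float,
    pf: float = 2.75,
    af_band: tuple = (55.0, 60.0),
    window: float = 1.0,
    step: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved ESC in sliding windows.

    Filtering is done once over the full signal (avoiding per-window edge
    artifacts); the Pearson correlation is then evaluated in windows of
    ``window`` seconds advanced by ``step``. Returns ``(t_centres, pac)``;
    windows with zero variance yield ``nan``.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window * fs))
    s = int(round(step * fs))
    if x.size < w:
        raise ValueError("signal shorter than the analysis window")
    lo = bandpass(x, fs, pf - PF_HALF_BW, pf + PF_HALF_BW)
    env = amplitude_envelope(bandpass(x, fs, af_band[0], af_band[1]))

    # windowed Pearson r from cumulative sums
    def csum(v):
        c = np.concatenate([[0.0], np.cumsum(v)])
        return c

    starts = np.arange(0, x.size - w + 1, s)
    c_l, c_e = csum(lo), csum(env)
    c_ll, c_ee, c_le = csum(lo * lo), csum(env * env), csum(lo * env)
    sl = c_l[starts + w] - c_l[starts]
    se = c_e[starts + w] - c_e[starts]
    sll = c_ll[starts + w] - c_ll[starts]
    see = c_ee[starts + w] - c_ee[starts]
    sle = c_le[starts + w] - c_le[starts]
    cov = sle - sl * se / w
    var_l = sll - sl**2 / w
    var_e = see - se**2 / w
    denom = np.sqrt(np.clip(var_l, 0, None) * np.clip(var_e, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, np.nan)
    t_centres = (starts + (w - 1) / 2.0) / fs
    return t_centres, r


def circular_shift_null(
    x: np.ndarray,
    fs: float,
    pf: float,
    af: float,
    n_shuffles: int = 50,
    min_shift: float = 5.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """|ESC| distribution under circular time shifts of the amplitude stream.

    Shifting the high-frequency envelope by >= ``min_shift`` seconds destroys
    any phase-locked coupling while preserving both spectra, giving an
    empirical null for comodulogram peaks.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(x, dtype=float)
    filt_low = bandpass(x, fs, pf - PF_HALF_BW, pf + PF_HALF_BW)
    env = amplitude_envelope(bandpass(x, fs, af - AF_HALF_BW, af + AF_HALF_BW))
    lo_shift = int(min_shift * fs)
    hi_shift = x.size - lo_shift
    if hi_shift <= lo_shift:
        raise ValueError("signal too short for the requested minimum shift")
    out = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shift = int(rng.integers(lo_shift, hi_shift))
        out[k] = abs(_pearson(filt_low, np.roll(env, shift)))
    return out
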