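"""Signal preparation and time-frequency analysis.

The quantitative band measures are built from a complex Morlet continuous
wavelet transform (bandwidth 1, centre frequency 3 — 'cmor1-3') whose power
is z-scored against the whole session, matching the convention that a value
of +2 means two session SDs above that band's session mean. Whole-session
spectra use the multitaper method (time-bandwidth 2.5, 4 tapers, 5 s
windows). All z-scores use the population (n) SD convention.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import signal as sps

from .datatypes import BandDefinition, PowerLawFit, SessionRecording

#: FIR anti-aliasing order per unit decimation factor; gives a transition
#: band narrower than 8% of the output Nyquist with ~53 dB stopband.
_DECIMATE_TAPS_PER_FACTOR = 85


def decimate_signal(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Integer-factor downsampling after zero-phase FIR anti-alias filtering.

    ``fs_in`` must be an integer multiple of ``fs_out``. The low-pass cutoff
    sits at the output Nyquist frequency.
    """
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(f"fs_in/fs_out must be an integer, got {ratio}")
    if q == 1:
        return np.asarray(x, dtype=float).copy()
    order = _DECIMATE_TAPS_PER_FACTOR * q
    return sps.decimate(np.asarray(x, dtype=float), q, n=order, ftype="fir", zero_phase=True)


def attenuate_artifacts(
    x: np.ndarray,
    fs: float,
    k: float = 5.0,
    wavelet: str = "db4",
    max_level: int = 5,
    passthrough: bool = False,
) -> np.ndarray:
    """Attenuate large-amplitude transients by stationary-wavelet shrinkage.

    Detail coefficients whose magnitude exceeds ``k`` robust SDs (MAD/0.6745)
    of their level are clipped to that threshold; the approximation is left
    untouched and the signal reconstructed. A conservative stand-in for the
    published artifact-removal step: ordinary oscillatory content is far
    below the threshold and passes unchanged.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("signal must be finite")
    if passthrough or x.size == 0:
        return x.copy()
    level = min(max_level, pywt.swt_max_level(x.size))
    if level < 1:
        return x.copy()
    # swt needs length divisible by 2**level
    block = 2**level
    pad = (-x.size) % block
    xp = np.pad(x, (0, pad), mode="edge")
    coeffs = pywt.swt(xp, wavelet, level=level, norm=True)
    shrunk = []
    for cA, cD in coeffs:
        mad = np.median(np.abs(cD - np.median(cD)))
        sigma = mad / 0.6745 if mad > 0 else 0.0
        thr = k * sigma
        if thr > 0:
            cD = np.clip(cD, -thr, thr)
        shrunk.append((cA, cD))
    out = pywt.iswt(shrunk, wavelet, norm=True)
    return out[: x.size]


def rereference_common_average(
    recording: SessionRecording, region: str
) -> SessionRecording:
    """Subtract the in-region mean signal from every channel of ``region``.

    Channels outside the region are untouched. Requires at least two channels
    in the region.
    """
    idx = recording.channel_indices(region)
    if idx.size < 2:
        raise ValueError(f"re-referencing undefined for <2 channels in {region!r}")
    out = recording.signals.copy()
    out[idx] -= out[idx].mean(axis=0, keepdims=True)
    return SessionRecording(signals=out, fs=recording.fs, channels=recording.channels.copy())


def zscore_signal(x: np.ndarray) -> np.ndarray:
    """Standardise to mean 0, SD 1 (population SD)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant signal cannot be z-scored")
    return (x - x.mean()) / sd


def multitaper_psd(
    x: np.ndarray,
    fs: float,
    time_bandwidth: float = 2.5,
    n_tapers: int = 4,
    f_range: tuple = (1.0, 90.0),
    window: float = 5.0,
    step: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-recording multitaper PSD, averaged over sliding windows.

    Returns ``(freqs, psd)`` restricted to ``f_range``; convert to decibels
    with ``10 * log10(psd)``.
    """
    x = np.asarray(x, dtype=float)
    nwin = int(round(window * fs))
    nstep = int(round(step * fs))
    if x.size < nwin:
        raise ValueError("signal shorter than one analysis window")
    tapers = sps.windows.dpss(nwin, time_bandwidth, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    starts = range(0, x.size - nwin + 1, nstep)
    acc = np.zeros(freqs.size)
    for s in starts:
        seg = x[s : s + nwin]
        seg = seg - seg.mean()
        spectra = np.abs(np.fft.rfft(tapers * seg[None, :], axis=1)) ** 2
        acc += spectra.mean(axis=0)
    psd = acc / len(list(starts)) / fs
    sel = (freqs >= f_range[0]) & (freqs <= f_range[1])
    return freqs[sel], psd[sel]


def _morlet_scales(freqs: np.ndarray, fs: float, centre_freq: float) -> np.ndarray:
    # pywt: frequency = centre_freq * fs / scale
    return centre_freq * fs / np.asarray(freqs, dtype=float)


def cwt_power(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    bandwidth: float = 1.0,
    centre_freq: float = 3.0,
) -> np.ndarray:
    """Squared magnitude of the complex Morlet CWT at ``freqs`` (rows)."""
    wavelet = f"cmor{bandwidth:g}-{centre_freq:g}"
    scales = _morlet_scales(np.asarray(freqs), fs, centre_freq)
    coef, _ = pywt.cwt(
        np.asarray(x, dtype=float), scales, wavelet, sampling_period=1.0 / fs, method="fft"
    )
    return np.abs(coef) ** 2


def cwt_band_power(
    x: np.ndarray,
    fs: float,
    band: BandDefinition,
    bandwidth: float = 1.0,
    centre_freq: float = 3.0,
    n_voices: int = 3,
) -> np.ndarray:
    """Session-z-scored instantaneous power in ``band``.

    Power is averaged over ``n_voices`` frequencies spanning the band, then
    z-scored against the whole recording's mean and SD of that band power, so
    the output is in session-SD units.
    """
    if band.f_hi >= fs / 2:
        raise ValueError(f"band {band.name} exceeds Nyquist at fs={fs}")
    voices = np.linspace(band.f_lo, band.f_hi, max(2, n_voices))
    power = cwt_power(x, fs, voices, bandwidth, centre_freq).mean(axis=0)
    sd = power.std()
    if sd == 0:
        raise ValueError("degenerate (zero-variance) band power")
    return (power - power.mean()) / sd


def fit_power_law(freqs: np.ndarray, values: np.ndarray) -> PowerLawFit:
    """Fit ``y = a * x**b`` by least squares in log-log coordinates."""
    f = np.asarray(freqs, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = (f > 0) & (y > 0) & np.isfinite(y)
    if ok.sum() < 2:
        raise RuntimeError("power-law fit needs >= 2 positive points")
    lf, ly = np.log(f[ok]), np.log(y[ok])
    b, loga = np.polyfit(lf, ly, 1)
    resid = float(np.sqrt(np.mean((ly - (loga + b * lf)) ** 2)))
    return PowerLawFit(a=float(np.exp(loga)), b=float(b), f_range=(f[ok].min(), f[ok].max()), residual=resid)


def normalized_spectrogram(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    bandwidth: float = 1.0,
    centre_freq: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Display-only 1/f-normalised CWT spectrogram.

    Power-law curves are fitted to the per-frequency time-mean and time-SD of
    the spectrogram; the matrix is then ``(S - fit_mean(f)) / fit_sd(f)``,
    de-emphasising the 1/f background so event-related changes share one
    colour axis. Falls back to a per-frequency raw z-score (with a warning)
    if either fit fails. Not for quantitative analysis.
    """
    if freqs is None:
        freqs = np.geomspace(1.0, min(110.0, 0.45 * fs), 30)
    freqs = np.asarray(freqs, dtype=float)
    S = cwt_power(x, fs, freqs, bandwidth, centre_freq)
    mu = S.mean(axis=1)
    sd = S.std(axis=1)
    try:
        fit_mu = fit_power_law(freqs, mu)
        fit_sd = fit_power_law(freqs, sd)
        norm = (S - fit_mu(freqs)[:, None]) / fit_sd(freqs)[:, None]
    except RuntimeError:
        warnings.warn("power-law fit failed; falling back to raw per-frequency z")
        norm = (S - mu[:, None]) / np.where(sd > 0, sd, 1.0)[:, None]
    return freqs, norm


def peri_event_extract(
    series: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    window: tuple = (-1.0, 2.0),
    fs_out: float = 25.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Align a continuous series to events on a closed 25 Hz grid.

    Returns ``(segments, offsets, n_dropped)`` where ``segments`` has one row
    per retained event sampled at ``event + k / fs_out`` for offsets spanning
    the closed interval ``window`` (linear interpolation from the native
    grid). Events whose window is not fully inside the series are dropped and
    counted.
    """
    series = np.asarray(series, dtype=float)
    event_times = np.atleast_1d(np.asarray(event_times, dtype=float))
    k_lo = int(round(window[0] * fs_out))
    k_hi = int(round(window[1] * fs_out))
    offsets = np.arange(k_lo, k_hi + 1) / fs_out
    t_max = (series.size - 1) / fs
    rows = []
    n_dropped = 0
    t_native = np.arange(series.size) / fs
    for te in event_times:
        if te + offsets[0] < 0 or te + offsets[-1] > t_max:
            n_dropped += 1
            continue
        rows.append(np.interp(te + offsets, t_native, series))
    segs = np.asarray(rows, dtype=float) if rows else np.empty((0, offsets.size))
    return segs, offsets, n_dropped
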