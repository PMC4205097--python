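"""Spectral preprocessing chain: decimate, de-artifact, re-reference, PSD,
wavelet band power and the 1/f-normalised spectrogram.

Run with ``python examples/02_spectral_overview.py``.
"""

import numpy as np

from oscimp import SimConfig, spectral, synthetic
from oscimp.datatypes import GAMMA60, THETA

cfg = SimConfig(n_rats=1, session_duration=120.0, seed=7)
session = synthetic.simulate_session(cfg, 0)
rec = session.recording
fs = rec.fs

# 1. Decimation: a wide-band acquisition stream is brought down to 250 Hz.
fs_hi = 1500.0
t = np.arange(0, 10, 1 / fs_hi)
wideband = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 130 * t)
dec = spectral.decimate_signal(wideband, fs_hi, 250.0)
print(f"decimated {len(wideband)} -> {len(dec)} samples; "
      f"residual RMS of the 130 Hz tone: {np.sqrt(2) * dec[500:-500].std() - 1:.4f}")

# 2. Artifact attenuation: clip extreme wavelet coefficients.
x = rec.signals[0].copy()
x[10_000] += 25.0
clean = spectral.attenuate_artifacts(x, fs)
print(f"spike amplitude reduced from {x[10_000]:.1f} to {clean[10_000]:.1f}")

# 3. Common-average re-referencing within a region.
reref = spectral.rereference_common_average(rec, "NAcbC")
idx = rec.channel_indices("NAcbC")
print(f"NAcbC channels sum to {np.abs(reref.signals[idx].sum(axis=0)).max():.2e} "
      "after re-referencing")

# 4. Multitaper PSD shows the injected theta and gamma oscillations.
f, p = spectral.multitaper_psd(rec.signals[0], fs)
for name, band in [("theta", THETA), ("gamma60", GAMMA60)]:
    sel = (f >= band.f_lo) & (f <= band.f_hi)
    print(f"{name} band power ratio vs 20-30 Hz: "
          f"{p[sel].mean() / p[(f >= 20) & (f <= 30)].mean():.2f}")

# 5. Complex-Morlet band power, z-scored over the session.
z = spectral.cwt_band_power(rec.signals[0], fs, GAMMA60)
print(f"gamma60 z-power: mean {z.mean():.2e}, sd {z.std():.3f}")

# 6. 1/f-normalised spectrogram: the background slope is removed so narrow
# oscillations stand out at any frequency.
freqs, norm = spectral.normalized_spectrogram(rec.signals[0], fs)
profile = norm.mean(axis=1)
print("brightest normalised frequency: "
      f"{freqs[np.argmax(profile)]:.1f} Hz (z = {profile.max():.2f})")
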