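"""Synthetic 5-CSRTT session generator.

Produces complete cohorts (rats -> electrodes -> sessions -> trials -> LFP +
tracking) with the statistical structure the downstream analyses assume:

* trial outcomes drawn from a Markov chain conditioned on previous reward,
  so premature responses are more likely after errors;
* right-skewed wait-start latencies whose location differs by outcome and
  previous reward;
* LFP = 1/f background + delta (2.75 Hz) + theta with a waiting-period
  envelope + gamma whose instantaneous amplitude is modulated by delta phase
  (depth ``m``) and by event-locked gains;
* 25 Hz tracking traces that leave the magazine rectangle at each trial's
  wait-start latency.

Ground truth (envelopes, delta phase, per-trial gains) is stored with every
session so each downstream estimator has a recovery oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .datatypes import (
    MagazineROI,
    SessionRecording,
    TRIAL_COLUMNS,
    validate_trials,
)

#: Default magazine rectangle and scanning position (tracking units ~ cm).
DEFAULT_ROI = MagazineROI(0.0, 8.0, 0.0, 8.0)
_MAG_CENTRE = (4.0, 4.0)
_SCAN_POS = (20.0, 18.0)


@dataclass
class SimulatedSession:
    """One rat-session bundle: signals, trials, tracking and ground truth."""

    rat_id: int
    recording: SessionRecording
    trials: pd.DataFrame
    tracking: pd.DataFrame
    truth: dict = field(default_factory=dict)
    config: SimConfig | None = None


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    if median <= 0 or sigma <= 0:
        raise ValueError("latency parameters must be positive")
    return float(median * np.exp(sigma * rng.standard_normal()))


def _truncated_latency(
    rng: np.random.Generator, median: float, sigma: float, upper: float
) -> float:
    """Log-normal draw resampled (then clipped) to stay below ``upper``."""
    for _ in range(50):
        x = _lognormal(rng, median, sigma)
        if x < upper:
            return x
    return float(upper * 0.95)


def simulate_trial_sequence(
    cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate the per-trial event table for one session.

    Trials are generated sequentially until the session duration elapses or
    the cap of non-premature trials is reached. Each analysed outcome is
    drawn conditioned on whether the previous analysed trial was rewarded;
    omissions are drawn independently at ``cfg.omission_rate`` and do not
    update the reward-history state.
    """
    cfg.validate()
    outcomes = ["correct", "incorrect", "premature"]
    rows = []
    t = 5.0  # settling time before the first magazine poke
    prev_outcome: str | None = None
    prev_rewarded: bool | None = None
    n_counted = 0
    # A trial needs at most delay + hold + timeout + return time to play out.
    tail = cfg.wait_delay + cfg.limited_hold + cfg.timeout + 4.0

    while t + tail < cfg.session_duration and n_counted < cfg.max_trials:
        if rng.random() < cfg.omission_rate:
            outcome = "omission"
        else:
            if prev_rewarded is None:
                # first trial: average of the two conditional distributions
                p = {
                    o: 0.5
                    * (
                        cfg.outcome_markov[True][o]
                        + cfg.outcome_markov[False][o]
                    )
                    for o in outcomes
                }
            else:
                p = cfg.outcome_markov[prev_rewarded]
            outcome = rng.choice(outcomes, p=[p[o] for o in outcomes])

        t_start = t
        t_wait = t_stim = t_poke = np.nan
        if outcome == "omission":
            # rat stays at the magazine; stimulus comes and goes unanswered
            t_stim = t_start + cfg.wait_delay
            t_end = t_stim + cfg.limited_hold + cfg.timeout
            t_return = t_end + _lognormal(rng, *cfg.magazine_params["omission"])
        else:
            med, sig = cfg.latency_params[(outcome, bool(prev_rewarded))] if (
                prev_rewarded is not None
            ) else cfg.latency_params[(outcome, True)]
            latency = _truncated_latency(rng, med, sig, 0.92 * cfg.wait_delay)
            t_wait = t_start + latency
            if outcome == "premature":
                hi = max(0.3, cfg.wait_delay - latency - 0.1)
                t_poke = min(
                    t_wait + rng.uniform(0.15, hi),
                    t_start + cfg.wait_delay - 0.02,
                )
                t_return = (
                    t_poke
                    + cfg.timeout
                    + _lognormal(rng, *cfg.magazine_params["premature"])
                )
            else:
                t_stim = t_start + cfg.wait_delay
                reaction = _truncated_latency(
                    rng, 0.6, 0.3, 0.9 * cfg.limited_hold
                )
                t_poke = t_stim + reaction
                t_return = t_poke + _lognormal(rng, *cfg.magazine_params[outcome])
                if outcome == "incorrect":
                    t_return += cfg.timeout

        rows.append(
            {
                "trial_id": len(rows),
                "t_trial_start": t_start,
                "t_wait_start": t_wait,
                "t_stimulus": t_stim,
                "t_nosepoke": t_poke,
                "t_magazine_return": t_return,
                "outcome": outcome,
                "prev_outcome": prev_outcome,
                "prev_rewarded": prev_rewarded,
                "wait_start_latency": t_wait - t_start,
            }
        )
        if outcome != "premature":
            n_counted += 1
        if outcome != "omission":
            prev_outcome = outcome
            prev_rewarded = outcome == "correct"
        t = t_return

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return validate_trials(trials)


def power_law_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float = 1.0
) -> np.ndarray:
    """Unit-variance noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1]  # keep DC finite
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _add_bump(env: np.ndarray, fs: float, te: float, gain: float, t_center: float, sigma: float) -> None:
    n = env.size
    i0 = max(0, int((te + t_center - 4 * sigma) * fs))
    i1 = min(n, int((te + t_center + 4 * sigma) * fs) + 1)
    if i1 <= i0:
        return
    tt = np.arange(i0, i1) / fs
    env[i0:i1] += gain * np.exp(-0.5 * ((tt - te - t_center) / sigma) ** 2)


def _add_plateau(env: np.ndarray, fs: float, te: float, gain: float, t_center: float, duration: float, ramp: float = 0.15) -> None:
    n = env.size
    a, b = te + t_center, te + t_center + duration
    i0 = max(0, int((a - ramp) * fs))
    i1 = min(n, int((b + ramp) * fs) + 1)
    if i1 <= i0:
        return
    tt = np.arange(i0, i1) / fs
    up = np.clip((tt - (a - ramp)) / ramp, 0, 1)
    down = np.clip((b + ramp - tt) / ramp, 0, 1)
    env[i0:i1] += gain * np.minimum(up, down)


def band_envelopes(
    cfg: SimConfig, trials: pd.DataFrame, n_samples: int
) -> dict:
    """Ground-truth multiplicative envelopes per (band, region).

    Returns ``{(band, region): env}`` with ``env`` of length ``n_samples``
    (baseline 1.0); only analysed trials contribute event-locked gains.
    """
    fs = cfg.fs_lfp
    regions = list(cfg.electrodes_per_region)
    envs = {
        (band, region): np.ones(n_samples)
        for band in ("theta", "gamma")
        for region in regions
    }
    for effect in cfg.event_effects:
        for _, tr in trials.iterrows():
            if tr["outcome"] == "omission":
                continue
            te = tr["t_wait_start"] if effect.event == "wait_start" else tr["t_nosepoke"]
            if not np.isfinite(te):
                continue
            prev = bool(tr["prev_rewarded"]) if tr["prev_rewarded"] is not None else True
            for region in regions:
                g = effect.gain_for(region, tr["outcome"], prev)
                env = envs[(effect.band, region)]
                if effect.kind == "bump":
                    _add_bump(env, fs, te, g, effect.t_center, effect.sigma)
                else:
                    _add_plateau(env, fs, te, g, effect.t_center, effect.duration)
    return envs


def make_channel_table(cfg: SimConfig, rat_id: int) -> pd.DataFrame:
    """Channel metadata for one rat: ``electrodes_per_region`` rows per region."""
    rows = []
    cid = 0
    for region, n in cfg.electrodes_per_region.items():
        for k in range(n):
            rows.append(
                {
                    "channel_id": f"r{rat_id}c{cid}",
                    "rat_id": rat_id,
                    "region": region,
                    "shank": k,
                }
            )
            cid += 1
    return pd.DataFrame(rows)


def simulate_lfp(
    cfg: SimConfig,
    trials: pd.DataFrame,
    channel_meta: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[SessionRecording, dict]:
    """Synthesise the multi-electrode LFP for one session.

    Per channel: power-law background noise + delta sinusoid + theta with its
    waiting-period envelope + a gamma carrier whose instantaneous amplitude is
    ``baseline x (1 + m cos(delta phase)) x event envelope``. Delta phase and
    the event envelopes are shared across channels within a rat/region, so
    cross-electrode coupling controls see the same structure; carriers and
    noise are channel-specific.
    """
    n = int(round(cfg.session_duration * cfg.fs_lfp))
    t = np.arange(n) / cfg.fs_lfp
    f_delta, a_delta = cfg.band_params["delta"]
    f_theta, a_theta = cfg.band_params["theta"]
    f_gamma, a_gamma = cfg.band_params["gamma"]
    m = cfg.pac_modulation_depth

    delta_phase = 2 * np.pi * f_delta * t + rng.uniform(0, 2 * np.pi)
    delta = np.cos(delta_phase)
    envs = band_envelopes(cfg, trials, n)

    signals = np.empty((len(channel_meta), n))
    for i, (_, ch) in enumerate(channel_meta.iterrows()):
        region = ch["region"]
        noise = power_law_noise(rng, n, cfg.fs_lfp, cfg.noise_exponent)
        theta = (
            a_theta
            * envs[("theta", region)]
            * np.cos(2 * np.pi * f_theta * t + rng.uniform(0, 2 * np.pi))
        )
        gamma_amp = a_gamma * envs[("gamma", region)] * (1 + m * np.cos(delta_phase))
        gamma = gamma_amp * np.cos(2 * np.pi * f_gamma * t + rng.uniform(0, 2 * np.pi))
        signals[i] = cfg.noise_amplitude * noise + a_delta * delta + theta + gamma

    recording = SessionRecording(signals=signals, fs=cfg.fs_lfp, channels=channel_meta.reset_index(drop=True))
    truth = {
        "delta_phase": delta_phase,
        "envelopes": envs,
        "modulation_depth": m,
        "band_freqs": {"delta": f_delta, "theta": f_theta, "gamma": f_gamma},
    }
    return recording, truth


def simulate_tracking(
    cfg: SimConfig,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    roi: MagazineROI = DEFAULT_ROI,
    stationary: bool = False,
) -> pd.DataFrame:
    """25 Hz head-position trace consistent with the trial table.

    The head sits inside the magazine rectangle from each trial start until
    that trial's wait-start, exits on the first frame at or after the
    wait-start time (with a velocity bump as it moves to the scanning
    position), and returns at the magazine-return time. With
    ``stationary=True`` the head never leaves the rectangle (a degenerate
    trace for detector fault tests).
    """
    n = int(round(cfg.session_duration * cfg.fs_tracking))
    tt = np.arange(n) / cfg.fs_tracking
    inside = np.ones(n, dtype=bool)
    if not stationary:
        for _, tr in trials.iterrows():
            t_exit = tr["t_wait_start"]
            if not np.isfinite(t_exit):
                continue
            t_back = tr["t_magazine_return"]
            inside[(tt >= t_exit) & (tt < t_back)] = False

    cx, cy = _MAG_CENTRE
    sx, sy = _SCAN_POS
    half_w = min(roi.x_max - roi.x_min, roi.y_max - roi.y_min) / 2.0
    jitter_in = np.clip(rng.normal(0, 0.4, (n, 2)), -0.8 * half_w, 0.8 * half_w)
    jitter_out = rng.normal(0, 0.6, (n, 2))

    x = np.where(inside, cx + jitter_in[:, 0], sx + jitter_out[:, 0])
    y = np.where(inside, cy + jitter_in[:, 1], sy + jitter_out[:, 1])
    # short outward transit after each exit so velocity shows a bump
    if not stationary:
        exits = np.flatnonzero(inside[:-1] & ~inside[1:]) + 1
        ramp_len = 8  # frames (~0.3 s)
        for e in exits:
            j = np.arange(e, min(e + ramp_len, n))
            if not inside[j].any():
                frac = (j - e + 1) / ramp_len
                # exit point just outside the rectangle, then on to scanning
                ex, ey = roi.x_max + 0.5, roi.y_max + 0.5
                x[j] = ex + frac * (sx - ex) + jitter_out[j, 0] * frac
                y[j] = ey + frac * (sy - ey) + jitter_out[j, 1] * frac
    # jittered outside positions must stay outside the rectangle
    out = ~inside
    x[out] = np.maximum(x[out], roi.x_max + 0.2)
    return pd.DataFrame({"t": tt, "x": x, "y": y})


def simulate_session(
    cfg: SimConfig, rat_id: int = 0, rng: np.random.Generator | None = None
) -> SimulatedSession:
    """Generate one complete session for ``rat_id`` (seeded from the config)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(rat_id + 1)[rat_id]
        )
    trials = simulate_trial_sequence(cfg, rng)
    channels = make_channel_table(cfg, rat_id)
    recording, truth = simulate_lfp(cfg, trials, channels, rng)
    tracking = simulate_tracking(cfg, trials, rng)
    return SimulatedSession(
        rat_id=rat_id,
        recording=recording,
        trials=trials,
        tracking=tracking,
        truth=truth,
        config=cfg,
    )


def trait_scaled_effects(effects: list, trait: float) -> list:
    """Scale event-locked gains by a rat's trait-impulsivity level.

    ``trait`` in [0, 1] amplifies the post-nose-poke gamma outcome contrast
    (error signals grow with impulsivity) and attenuates the waiting-theta
    previous-reward contrast (reward-history signals shrink), emulating the
    between-rat structure the trait analysis is designed to recover.
    """
    from dataclasses import replace

    out = []
    for e in effects:
        if e.event == "nose_poke" and e.band == "gamma":
            og = {k: 1.0 + (v - 1.0) * (1.0 + 1.5 * trait) for k, v in e.outcome_gains.items()}
            e = replace(e, outcome_gains=og)
        elif e.event == "wait_start" and e.band == "theta":
            pg = {k: 1.0 + (v - 1.0) * (1.0 - 0.8 * trait) for k, v in e.prev_reward_gains.items()}
            e = replace(e, prev_reward_gains=pg)
        out.append(e)
    return out


def simulate_cohort(cfg: SimConfig) -> list[SimulatedSession]:
    """One session per rat, each independently seeded from ``cfg.seed``."""
    cfg.validate()
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_rats)
    return [
        simulate_session(cfg, rat_id=i, rng=np.random.default_rng(seeds[i]))
        for i in range(cfg.n_rats)
    ]
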