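"""Simulation configuration for synthetic 5-CSRTT sessions.

The defaults encode the task structure (5 s waiting delay, 5 s timeout,
30-minute or 100-non-premature-trial sessions) and the statistical structure
the downstream analyses assume: outcome probabilities conditioned on previous
reward set from the published contingency counts, right-skewed latency
distributions that differ by outcome and reward history, and an LFP model of
1/f background plus delta (2.75 Hz), theta (8.5 Hz) and gamma (57.5 Hz)
components with event-locked envelopes and delta-phase-modulated gamma
amplitude.

Event-locked envelope gains (in multiples of baseline band amplitude) are free
parameters of the generator: the magnitudes of event-related power changes in
z-units are not published, so the defaults below are declared, adjustable
choices rather than measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datatypes import REGIONS

# Conditional outcome probabilities among analysed (non-omission) trials.
# Premature rates are the published contingency-table rates (316/3554 after a
# rewarded trial, 732/3118 after an error); the correct rates are chosen so
# the chain's stationary premature fraction is ~0.157.
P_PREMATURE_AFTER_REWARD = 316 / 3554
P_PREMATURE_AFTER_ERROR = 732 / 3118

DEFAULT_OUTCOME_MARKOV = {
    True: {
        "correct": 0.62,
        "incorrect": 1.0 - 0.62 - P_PREMATURE_AFTER_REWARD,
        "premature": P_PREMATURE_AFTER_REWARD,
    },
    False: {
        "correct": 0.44,
        "incorrect": 1.0 - 0.44 - P_PREMATURE_AFTER_ERROR,
        "premature": P_PREMATURE_AFTER_ERROR,
    },
}

# Log-normal wait-start latency parameters (median seconds, log-scale sigma)
# per (outcome, previously rewarded). Premature trials start waiting fastest,
# incorrect slowest, and previously non-rewarded trials are faster throughout.
DEFAULT_LATENCY_PARAMS = {
    ("correct", True): (1.6, 0.45),
    ("correct", False): (1.2, 0.45),
    ("incorrect", True): (1.9, 0.45),
    ("incorrect", False): (1.5, 0.45),
    ("premature", True): (1.0, 0.50),
    ("premature", False): (0.8, 0.50),
}

# Magazine-return latency (median seconds, sigma) per outcome; errors return
# after the timeout has elapsed.
DEFAULT_MAGAZINE_PARAMS = {
    "correct": (1.2, 0.3),
    "incorrect": (1.5, 0.4),
    "premature": (1.5, 0.4),
    "omission": (1.0, 0.3),
}

DEFAULT_BAND_PARAMS = {
    # name: (centre Hz, baseline amplitude in noise-RMS units)
    "delta": (2.75, 0.8),
    "theta": (8.5, 0.5),
    "gamma": (57.5, 0.35),
}


@dataclass(frozen=True)
class EventEffect:
    """Multiplicative envelope gain locked to a behavioural event.

    The band envelope is multiplied by ``1 + g * shape(t)`` where the peak
    gain ``g = base_gain * region_gain * outcome_gain * prev_reward_gain``
    and ``shape`` is a Gaussian bump (``kind='bump'``, sd ``sigma`` centred at
    ``t_center`` after the event) or a smoothed plateau from ``t_center`` to
    ``t_center + duration`` (``kind='plateau'``).
    """

    event: str  # 'wait_start' | 'nose_poke'
    band: str  # 'theta' | 'gamma'
    base_gain: float
    kind: str = "bump"
    t_center: float = 0.0
    sigma: float = 0.1
    duration: float = 0.0
    region_gains: dict = field(default_factory=dict)
    outcome_gains: dict = field(default_factory=dict)
    prev_reward_gains: dict = field(default_factory=dict)

    def gain_for(self, region: str, outcome: str, prev_rewarded: bool) -> float:
        return (
            self.base_gain
            * self.region_gains.get(region, 1.0)
            * self.outcome_gains.get(outcome, 1.0)
            * self.prev_reward_gains.get(prev_rewarded, 1.0)
        )


def default_event_effects() -> list[EventEffect]:
    """Event-locked gains emulating the qualitative pattern of the recordings:

    - a transient gamma increase at wait-start, largest in NAcbC, larger on
      upcoming-premature and previously non-rewarded trials;
    - a sustained theta elevation during waiting, largest in PFC, smaller
      after errors and before premature responses;
    - a post-nose-poke gamma response larger after error outcomes.
    """
    return [
        EventEffect(
            event="wait_start",
            band="gamma",
            base_gain=1.5,
            kind="bump",
            t_center=0.0,
            sigma=0.10,
            region_gains={"NAcbC": 1.0, "NAcbSh": 0.7, "PRL": 0.45, "IL": 0.45},
            outcome_gains={"premature": 1.5, "correct": 1.0, "incorrect": 1.05},
            prev_reward_gains={False: 1.35, True: 1.0},
        ),
        EventEffect(
            event="wait_start",
            band="theta",
            base_gain=1.2,
            kind="plateau",
            t_center=0.5,
            duration=1.8,
            region_gains={"PRL": 1.0, "IL": 0.9, "NAcbC": 0.5, "NAcbSh": 0.5},
            outcome_gains={"premature": 0.6, "correct": 1.0, "incorrect": 0.95},
            prev_reward_gains={False: 0.6, True: 1.0},
        ),
        EventEffect(
            event="nose_poke",
            band="gamma",
            base_gain=1.2,
            kind="plateau",
            t_center=0.3,
            duration=1.5,
            region_gains={"NAcbC": 1.0, "NAcbSh": 0.8, "PRL": 0.7, "IL": 0.7},
            outcome_gains={"correct": 1.0, "incorrect": 1.6, "premature": 1.5},
            prev_reward_gains={True: 1.0, False: 1.1},
        ),
    ]


@dataclass
class SimConfig:
    """Complete parameterisation of a synthetic cohort."""

    n_rats: int = 2
    electrodes_per_region: dict = field(
        default_factory=lambda: {"PRL": 2, "IL": 2, "NAcbC": 2, "NAcbSh": 2}
    )
    session_duration: float = 1800.0  # seconds
    fs_lfp: float = 250.0
    fs_tracking: float = 25.0
    wait_delay: float = 5.0  # delay from trial start to stimulus
    limited_hold: float = 5.0  # response window after the stimulus
    timeout: float = 5.0  # punishment timeout after errors
    max_trials: int = 100  # non-premature trials ending the session
    omission_rate: float = 0.05
    outcome_markov: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_OUTCOME_MARKOV.items()}
    )
    latency_params: dict = field(
        default_factory=lambda: dict(DEFAULT_LATENCY_PARAMS)
    )
    magazine_params: dict = field(
        default_factory=lambda: dict(DEFAULT_MAGAZINE_PARAMS)
    )
    band_params: dict = field(default_factory=lambda: dict(DEFAULT_BAND_PARAMS))
    pac_modulation_depth: float = 0.5  # m in [0, 1]
    event_effects: list = field(default_factory=default_event_effects)
    noise_exponent: float = 1.0  # 1/f^exponent background power
    noise_amplitude: float = 1.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        for prev, dist in self.outcome_markov.items():
            total = sum(dist.values())
            if any(not 0 <= p <= 1 for p in dist.values()) or abs(total - 1) > 1e-9:
                raise ValueError(
                    f"outcome_markov[{prev}] must be probabilities summing to 1"
                )
        if not 0 <= self.pac_modulation_depth <= 1:
            raise ValueError("pac_modulation_depth must be in [0, 1]")
        if self.fs_lfp % self.fs_tracking != 0:
            raise ValueError("fs_lfp must be a multiple of fs_tracking")
        if not 0 <= self.omission_rate < 1:
            raise ValueError("omission_rate must be in [0, 1)")
        for key, (med, sigma) in self.latency_params.items():
            if med <= 0 or sigma <= 0:
                raise ValueError(f"latency_params[{key}] must be positive")
        for region in self.electrodes_per_region:
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r}")
        return self
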