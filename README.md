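# oscimp

Peri-event analysis of local field potentials (LFP) recorded during an operant
waiting task, with a seeded synthetic data generator for end-to-end testing.

The package models a 5-choice serial reaction time task (5-CSRTT): on each
trial a rat waits about 5 s for a brief light stimulus and nose-pokes the lit
aperture; a nose-poke during the waiting period is a *premature* (impulsive)
response. The library covers the full analysis chain for such experiments:

- **`oscimp.synthetic`** — seeded generator of complete sessions: Markov trial
  sequences (outcome depends on previous reward), 1/f LFP with injected delta,
  theta and gamma oscillations, phase-amplitude coupling, event-locked power
  changes, and a head-tracking trace.
- **`oscimp.behaviour`** — wait-start detection from tracking (first sample
  strictly outside the magazine area), trial-history annotation, Yates
  chi-square contingency test, head velocity.
- **`oscimp.spectral`** — FIR decimation, wavelet-based artifact attenuation,
  common-average re-referencing, multitaper PSD, complex-Morlet band power
  (z-scored over the session), 1/f-normalised spectrogram, peri-event
  extraction onto a 25 Hz grid from −1 to +2 s.
- **`oscimp.pac`** — envelope-to-signal correlation (ESC) phase-amplitude
  coupling: comodulograms over a 1.5–10 Hz × 30–80 Hz grid, a cross-electrode
  control, moving-window PAC and a circular-shift null.
- **`oscimp.perievent_stats`** — pointwise linear-mixed-model scan with the
  0.01/75 threshold and the >0.2 s epoch rule; nine-window factorial models
  with Bonferroni correction and post-hoc all-pair contrasts.
- **`oscimp.prediction`** — mixed logistic model (rat random intercept) for
  trial-by-trial premature-response prediction, leave-one-out
  cross-validation, ROC/AUC with ties counted one half, likelihood-ratio
  tests and a stratified bootstrap AUC comparison.
- **`oscimp.impulsivity`** — screening scores and the high-impulsivity (HI)
  criterion (≥50 prematures on each of three sessions), per-rat LFP feature
  extraction, correlation-matrix PCA with oblimin rotation, and the
  component-on-score regression.
- **`oscimp.pipeline` / `oscimp.io`** — session-to-tensor plumbing and
  session-bundle persistence.

## Worked example

```python
import numpy as np
from oscimp import SimConfig, behaviour, pipeline, synthetic

cfg = SimConfig(n_rats=3, seed=42)
sessions = synthetic.simulate_cohort(cfg)
trials = pipeline.cohort_trials(sessions)

analysed = trials[trials["outcome"] != "omission"]
frac = (analysed["outcome"] == "premature").mean()
print(f"premature fraction: {100 * frac:.2f}% of {len(analysed)} analysed trials")

table = behaviour.premature_contingency(trials)
stat, df, p = behaviour.contingency_chi_square(table)
print(f"Yates chi-square = {stat:.3f}, df = {df}, p = {p:.3g}")

s = sessions[0]
detected = behaviour.detect_wait_starts(s.trials, s.tracking, synthetic.DEFAULT_ROI)
err = (detected["t_wait_start"] - s.trials["t_wait_start"]).abs()
print(f"wait-start detection: max |error| = {np.nanmax(err) * 1000:.1f} ms")
```

Output:

```text
premature fraction: 16.81% of 345 analysed trials
Yates chi-square = 10.510, df = 1, p = 0.00119
wait-start detection: max |error| = 40.0 ms
```

The `examples/` directory walks through every capability as a narrative
script (`01_simulate_and_behaviour.py` through `06_impulsivity_pca.py`); each
prints its results when run directly.

## Tests and acceptance

```bash
python -m pytest -q tests/                      # unit + acceptance suites
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` recomputes the headline quantities from scratch —
the worked contingency and threshold numbers, PAC recovery, peri-event scan
epochs, LOOCV AUCs and the PCA trait recovery — and writes them as JSON.

See `docs/methods.md` for the statistical methods, model assumptions and the
rationale behind the default parameters.
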