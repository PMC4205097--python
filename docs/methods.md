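# Methods

This note documents the statistical and numerical methods implemented in
`oscimp`, the assumptions behind them, and the rationale for the default
parameters. Problem sizes quoted here (grid lengths, window sets, feature
counts) are the package's own declared defaults; all of them are plain
function arguments and can be overridden.

## Task model

A session consists of sequential trials of a 5-choice serial reaction time
task: a ~5 s waiting delay, a 0.5 s light stimulus, a 5 s limited hold, and a
5 s timeout after errors. A session ends after 100 non-premature trials or
30 min. Outcomes are `correct`, `incorrect`, `premature` (a nose-poke during
the waiting delay) and `omission`. The *wait start* of a trial is the first
tracking sample at which the head is strictly outside a rectangle around the
food magazine; samples on the boundary count as inside.

## Synthetic generator (`oscimp.synthetic`)

The generator exists so that every downstream method can be validated against
known ground truth. Its components:

- **Trial sequence.** Outcomes follow a two-state Markov structure: the
  outcome distribution depends on whether the previous analysed trial was
  rewarded. Defaults set the conditional premature probabilities to 316/3554
  (after reward) and 732/3118 (after non-reward) — the two rates implied by
  the published pooled contingency table — and the correct rates to 0.62 and
  0.44, chosen so the stationary premature fraction is ≈0.157 (the published
  15.71%). Omissions are drawn independently at rate 0.05 and do not advance
  the history state. Latencies are lognormal per (outcome, previous-reward)
  cell, truncated so that non-premature nose-pokes cannot precede the
  stimulus.
- **LFP.** Background noise is spectrally shaped to 1/f (exponent 1 by
  default). On top of it ride a 2.75 Hz delta oscillation (phase shared
  across a rat's electrodes), a 7.5–9.5 Hz theta oscillation, and a 55–60 Hz
  gamma carrier whose amplitude is `base · envelope · (1 + m · cos φ_delta)`,
  giving controllable phase-amplitude coupling of depth `m`.
- **Event-locked gains.** Declared `EventEffect` entries multiply the band
  envelopes around events: a transient gamma bump at wait start (largest in
  the accumbens core, larger before premature responses and after
  non-rewarded trials), a sustained waiting-theta plateau (largest in
  prefrontal cortex, smaller before premature responses), and a post-nose-poke
  gamma response that is larger after errors. `trait_scaled_effects` scales
  two of these contrasts by a per-rat trait to create recoverable between-rat
  structure.
- **Tracking.** 25 Hz head positions inside the magazine rectangle until the
  scheduled wait start, then an 8-frame outward ramp to a scanning position;
  the first strictly-outside sample lands within one frame of the scheduled
  event.

All randomness flows from `numpy.random.SeedSequence(seed)`, so cohorts are
bit-reproducible.

## Preprocessing (`oscimp.spectral`)

- **Decimation** uses a zero-phase FIR low-pass of order `85 × factor`. This
  is deliberately much longer than SciPy's default so that a 1500→250 Hz
  decimation passes 120 Hz with <1 % amplitude loss while leaving <1 %
  residual at 130 Hz.
- **Artifact attenuation** runs a stationary wavelet transform (norm-preserving,
  up to 5 levels, edge-padded to a power of two) and clips detail
  coefficients beyond 5 robust standard deviations (MAD/0.6745), then
  reconstructs. Large transients shrink; in-band oscillations are essentially
  untouched.
- **Re-referencing** subtracts the within-region common average (≥2
  channels), removing volume-conducted common-mode components.
- **Multitaper PSD** uses DPSS tapers with time-bandwidth 2.5 and 4 tapers on
  5 s mean-subtracted segments, averaged over the session, reported on
  1–90 Hz.
- **Band power** is the squared magnitude of a complex Morlet (`cmor1-3`)
  continuous wavelet transform, averaged over ≥2 voices spanning the band and
  z-scored over the whole session, so event-locked values are in units of
  session standard deviations.
- **1/f-normalised spectrogram:** a power law `a·f^b` is fitted to the
  time-averaged spectrum in log-log coordinates; each frequency row is then
  centred and scaled by the fit, removing the background slope.
- **Peri-event extraction** linearly interpolates each series onto a fixed
  76-point 25 Hz grid from −1 to +2 s around each event; events whose window
  leaves the recording are dropped and counted.

## Phase-amplitude coupling (`oscimp.pac`)

The estimator is the envelope-to-signal correlation (ESC): the Pearson
correlation between the low-frequency band-passed signal and the amplitude
envelope (Hilbert magnitude) of the high-frequency band-passed signal. It is
signed: coupling at the slow-wave peak is positive, at the trough negative.
Defaults: phase bands of ±1 Hz, amplitude bands of ±2.5 Hz, order-4 zero-phase
Butterworth filters, and a minimum of 10 phase-frequency cycles.
Comodulograms cover 1.5–10 Hz (step 0.25 Hz) × 30–80 Hz (step 2.5 Hz). The
cross-electrode control recomputes the matrix with phase and amplitude taken
from different electrodes of a region (all ordered pairs, averaged);
within-electrode artefacts cannot survive it. Moving-window PAC filters the
full signal once and evaluates windowed correlations (1 s windows, 20 ms
steps) via cumulative sums. Significance is assessed against a circular-shift
null that rotates the envelope by at least 5 s.

## Peri-event statistics (`oscimp.perievent_stats`)

- **Pointwise scan.** At each of the 76 grid points the measure is modelled
  with fixed effects velocity, outcome, previous reward and region; random
  velocity slope and intercept by rat; and a random intercept for channel
  within rat (variance-component formulation). Per-term Wald chi-square tests
  use sum-to-zero (type-3) coding. The significance threshold is
  0.01/75 ≈ 0.00013 (Bonferroni over the 3 s of 25 Hz comparisons), and only
  contiguous sub-threshold runs lasting *strictly longer* than 0.2 s are
  reported — on the 25 Hz grid the shortest reportable epoch is 7 points
  (0.24 s).
- **Fallback ladder.** When the full random structure cannot be estimated
  (few rats, few channels, degenerate variance), the model degrades in order:
  drop the velocity slope, drop the channel component, and finally fit OLS.
  The applied rung is reported with every result.
- **Windowed models.** Nine declared analysis windows (three measures × the
  two events, split pre/post where relevant) are analysed with the full
  factorial outcome × previous-reward × region model plus velocity;
  interaction terms are dropped with a warning if any factorial cell is
  empty. P-values are Bonferroni-corrected by the number of windows (9).
  Post-hoc all-pair contrasts recover level effects from the sum coding
  (omitted level = −sum of the coded ones) and use Wald t statistics with
  residual degrees of freedom, Bonferroni-corrected over pairs.

## Premature-response prediction (`oscimp.prediction`)

The premature/non-premature label is modelled with a logistic GLMM with a
random intercept per rat. The marginal likelihood is computed by adaptive
Gauss-Hermite quadrature (15 nodes; per-cluster Newton mode finding) and
maximised with BFGS over the fixed effects and log random-effect SD. Complete
separation (|β| > 30) triggers a ridge-penalised refit with a warning. At
zero estimated variance the model collapses exactly to ordinary logistic
regression (verified against `statsmodels.Logit`). Prediction adds each
cluster's posterior-mode intercept for rats seen in fitting.

Evaluation is by leave-one-out cross-validation (each trial predicted by a
model refitted without it, warm-started from the full fit). AUC is computed
in the rank (Mann-Whitney) form with ties counted one half; the ROC sweep
also reports accuracy `(TP+TN)/n` at every threshold. Nested models are
compared with likelihood-ratio chi-square tests. Two cross-validated score
vectors are compared by a class-stratified bootstrap:
`D = (AUC₁ − AUC₂)/sd(ΔAUC draws)`, referred to the standard normal.

The feature table averages each window measure over a region's electrodes
per trial, so each physical trial contributes one row (no electrode-level
pseudoreplication).

## Trait impulsivity (`oscimp.impulsivity`)

Screening scores are the mean premature count over exactly three screening
sessions; the HI (highly impulsive) criterion requires ≥50 prematures on
every one of the three. The per-rat feature matrix uses ten declared
variables — five window/contrast combinations (wait-start gamma by previous
reward, post-poke gamma and theta by outcome, waiting theta by previous
reward, post-poke PAC by outcome) in each of the accumbens core and the
prelimbic cortex. PCA is an eigendecomposition of the feature correlation
matrix (loadings = eigenvectors × √eigenvalues); the leading four components
are rotated with direct quartimin (oblimin, γ = 0), and per-rat scores are
least-squares regression scores against the rotated loadings. Component
scores are regressed on screening scores by OLS, optionally within the HI
subgroup.

## Numerical and design choices

- All statistical entry points accept either one tensor or a per-rat list;
  electrode sets differ between rats, so cross-rat data are concatenated in
  long format with globally unique `rat:trial` identifiers.
- Component signs from eigendecompositions and rotations are arbitrary;
  analyses that depend on direction align signs through a reference feature's
  correlation with the quantity of interest.
- Mixed models are fitted by maximum likelihood (not REML) so that
  likelihood-ratio comparisons are valid.
- The scan threshold, epoch rule, window count and HI criterion are module
  constants, not tunables; they encode the published analysis conventions.

## Limitations of the generator

The synthetic sessions are a test harness, not a biophysical model: noise is
stationary 1/f, oscillations are narrow-band with deterministic envelopes,
event effects are multiplicative gains with fixed shapes, and tracking is a
schematic ramp. Effect sizes were chosen to be comfortably detectable at
small cohort sizes; real recordings will have smaller effects, non-stationary
artifacts and missing data patterns the generator does not emulate.
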