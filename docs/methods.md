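# Methods

`pepkit` implements an analysis pipeline for perturbation-evoked potentials
(PEPs): cortical/subcortical EEG deflections elicited within ~90–150 ms of a
standing-balance perturbation. The pipeline runs from synchronized multi-rate
raw data (EEG at 1,000 Hz, platform accelerometer at 150 Hz) to a 3-way
split-plot ANOVA on epoch RMS magnitudes, and ships a synthetic cohort
generator that emulates the study protocol so every stage is testable without
external data. This note documents the model, the parameters that matter, the
numerical choices, and what the synthetic data do and do not establish.

## Protocol

The perturbation protocol is a fixed sequence of 34 support-surface
translations: posterior translations throughout, with anterior "catch"
trials at positions 16, 22, 28, 29 and 34. Analysis labels partition the
sequence:

* **unpredictable** (6): trial 1 — delivered unannounced, mid-conversation —
  plus the five anterior catch trials;
* **excluded** (4): trials 2–5, dropped so the predictable set reflects
  habituated responses rather than early adaptation;
* **predictable** (24): the remaining posterior trials.

Protocols are data (`ProtocolDefinition`), serializable as a plain-text
table, so alternative sequences can be loaded from a run config.

## Platform kinematics

Each translation is modeled with a trapezoidal-velocity profile honouring the
nominal peak acceleration (0.2 g = 1.962 m/s²) and displacement (0.20 m). The
nominal triple (0.2 g, 1.0 m/s, 0.20 m) is kinematically infeasible — reaching
1 m/s at 0.2 g alone covers more than 25 cm — so peak velocity is capped at
√(a·d) ≈ 0.63 m/s (triangular profile) and a warning is issued. Velocity is
not used downstream; onset detection depends on acceleration and epochs are
locked to displacement onset.

The discrete trace is sample-and-hold acceleration whose rectangle-rule
integral reproduces the sampled velocity exactly; a single global rescale
(< 1%, absorbing the corner clipping of the discretized triangle) makes the
documented quadrature (`integrate_platform_motion`: cumulative rectangle rule
to velocity, trapezoid to displacement) recover the target displacement to
well below 1 µm. Sign convention: posterior negative, anterior positive.

## Synthetic cohort

40 subjects (young/elder × male/female, 10 per cell) each receive the full
34-trial protocol with onsets a fixed 8 s apart (the platform returns within
7 s). Per channel (Fz, Cz, L5–L7, R5–R7):

```
eeg(t) = 1/f background + 60 Hz line + Σ_trials gain_k · PEP(t − onset_k)
```

* **Background**: Gaussian 1/f^α noise (α = 1, flat below 0.5 Hz),
  synthesized in the frequency domain and scaled so its 2.5–30 Hz component
  has a per-channel RMS of 2.2 µV (Fz), 2.6 µV (Cz), 1.1 µV per mastoid
  channel — noise is independent across channels, so the combined mastoid
  series (mean of per-ear means) has ~√6 lower noise. A 2 µV 60 Hz sinusoid
  (common across channels) exercises the notch filter.
* **PEP waveform**: a biphasic atom — a short, sharp negative half-sine lobe
  (~30% of the duration, 0.9 relative depth) followed by a broader positive
  half-sine lobe — starting at a latency drawn uniformly from 90–130 ms,
  spanning 130 ms, with the maximum positive excursion exactly equal to the
  amplitude parameter. Lobe proportions jitter mildly trial-to-trial. The
  sharp leading lobe is what makes response onsets detectable at a 3-SD
  threshold within 150 ms of the perturbation, the latency envelope the
  generator is required to emulate.
* **Amplitudes**: per-channel base (6 / 7 / 3.6 µV for Fz / Cz / mastoid)
  multiplied by a per-subject gain (lognormal, σ = 0.25), a per-trial arousal
  jitter (lognormal, σ = 0.25, shared across channels), and group gains:
  condition gain on unpredictable trials (calibrated; below), an elder gain
  at Cz and mastoid (1.25), and an extra elderly-male mastoid gain (1.8).
  Both lognormals are truncated at ±1σ: evoked responses vary but never
  vanish, so single-trial detectability is bounded away from zero. The
  resulting single-trial evoked-to-background RMS ratio on predictable trials
  is ~1.2–1.4 per channel — a low-SNR regime in which baseline correction,
  normalization and RMS averaging genuinely matter.
* **Trial 1** is modeled as a startle ceiling response: amplitude = base ×
  subject gain × `first_trial_gain` (2.0), without the group modulators. This
  matters: the analysis normalizes every subject's epochs to trial 1, so any
  gain shared between trial 1 and later trials cancels exactly. Treating the
  first, maximally startling perturbation as a ceiling response lets
  first-trial normalization do what it is meant to do — remove individual
  amplitude scale (impedance, anatomy) while preserving group effects on
  subsequent trials.
* **Dropout**: 40 analyzable (subject, trial) slots per cohort, chosen
  uniformly at random, are flagged incomplete ("technical issues"),
  missing-at-random at the whole-event level; excluded trials never drop.
* **Determinism**: one integer seed drives subject gains, dropout and
  per-subject streams through spawned `SeedSequence`s; identical
  (config, protocol, seed) give bit-identical arrays and manifests.

### Calibration of the condition gains

The default condition gains are calibrated by simulation so that the **full
pipeline** recovers a within-subject condition Cohen's d of ≈ 0.5 at the
combined mastoid, ≈ 0.3 at Fz and ≈ 0.2 at Cz. Recovered d is close to linear
in the gain over the relevant range; the calibrated values are
`{Cz: 1.03, Fz: 1.04, mastoid: 1.27}`, recorded in
`src/pepkit/data/default_config.yaml`. Verification over 15 independent
cohorts gave d = 0.23 / 0.31 / 0.52 (SE ≈ 0.02–0.03). The mastoid gain is the
largest because the stronger elderly-male mastoid effect inflates
between-subject spread there, and d is standardized by that spread.

### What the generator does not emulate

No body-sway biomechanics, EMG or synergy structure; no ocular/muscle
artifacts; no habituation dynamics across trials 2–5 (excluded from analysis
anyway); no group differences in PEP latency (a config hook, not a default);
noise is stationary and independent across channels (real cEEGrid channels
are strongly laterally correlated, which would reduce the benefit of mastoid
averaging relative to this simulation). Passing tests therefore demonstrate
that the pipeline recovers known effect structure from realistic SNR, not
that it is robust to artifacts or correlated-noise montages.

## Preprocessing

EEG is filtered as continuous data (before epoching, so 300 ms epochs carry
no edge transients) with a 2nd-order Butterworth bandpass (2.5–30 Hz) cascaded
with a 2nd-order IIR notch (60 Hz, Q = 30), applied forward–backward. The
analysis is offline, and zero-phase application keeps latency readouts free of
group delay; the effective magnitude order doubles. Since filtering and
channel averaging are linear, the combined mastoid series is formed first and
filtered once — mathematically identical to filtering all six mastoid
channels and averaging.

Perturbation onsets are read from the accelerometer: per event marker, noise
statistics come from 1 s before the marker, and onset is the earliest time in
a 1 s search window where |a − baseline mean| exceeds 5 baseline SDs for ≥ 3
consecutive samples. Events with no crossing are flagged undetected, never
silently dropped. A zero-SD baseline (idealized noiseless traces) falls back
to an absolute threshold of 5% of the window's peak |acceleration|. All
threshold parameters are config-exposed. Onset times map to the EEG clock by
nearest-sample rounding.

## Epoching

Per analyzable event: epoch = [onset, onset + 300 ms) (300 samples at 1 kHz),
baseline window = [onset − 300 ms, onset − 100 ms), both half-open with the
onset sample belonging to the epoch. Epochs move through a strict state
machine (raw → corrected → normalized; re-running a stage raises).

Correction removes the epoch's least-squares linear slope **keeping the epoch
mean**, then transforms samples to (x − baseline mean) / baseline SD. The
slope-only detrend is deliberate: removing the full fitted line would also
remove the epoch's DC level, and subsequently subtracting the baseline mean
would re-introduce an offset that depends on the recording's absolute DC —
breaking invariance to a constant shift of the whole recording. With the
slope-only convention a DC offset added to the entire recording cancels
exactly (verified to 1e-9). Division by the baseline SD expresses samples in
baseline-noise units; a mean-only variant is available as a config switch.
Baseline SD ≤ 1e-12 invalidates the epoch (degenerate baseline).

Normalization: per subject × channel, the reference scale is the maximum
absolute value of the first (trial 1) valid corrected epoch; all epochs are
divided by it, making the first epoch's peak magnitude exactly 1. If trial 1
is missing for a subject × channel, the earliest valid epoch substitutes and
the substitution is logged. Normalization of corrected (baseline-z) epochs is
the only option consistent with the processing order; normalizing raw-unit
epochs is not offered.

QC accounting is event-level: planned = subjects × 30 analyzable trials;
missing = dropout + undetected onsets + invalid epochs; analyzed = planned −
missing (1,200 / 40 / 1,160 for the default cohort).

## Statistics

Per epoch: RMS = √(mean(x²)) and peak magnitude = maximum signed sample (an
all-negative epoch is flagged as having no positive peak). Per subject ×
channel × condition: the mean RMS over valid epochs (trial 1 included among
unpredictable events) forms the tidy RMS table.

The design is a split plot: age and sex between subjects, perturbation type
within. With a 2-level within factor the univariate split-plot ANOVA
decomposes exactly into two ordinary linear models — subject condition-means
for the between stratum, subject condition-differences for the within stratum
(the intercept of the difference model tests the condition main effect). Both
strata use Type III sums of squares with sum-to-zero contrasts, so the
mildly unbalanced tables left by listwise deletion (subjects missing a whole
condition cell at a channel) are handled; in the balanced 40-subject default
every effect is F(1, 36). The decomposition is verified in the test suite
against a hand-rolled textbook sums-of-squares oracle and against base-R
`aov(y ~ age*sex*cond + Error(subject/cond))`. Channels (Cz, Fz, combined
mastoid) are analyzed separately, with no cross-channel multiplicity
correction — the analysis reports per-channel inferences.

Post-hoc: Tukey HSD over the four age × sex cells of subject condition-mean
RMS, using the between-subject error mean square; q = |Δ| / √(MSE/n_h) with
the harmonic cell size, p from the studentized-range distribution (for k = 2
this reduces to the pooled two-sample t-test, an identity the tests check).

Effect sizes are classical pooled-SD Cohen's d. The within-subject condition
effect uses mean(u − p) divided by the pooled SD of the two condition columns
(d, not d_z — the difference-SD variant would inflate the value); sign
conventions are condition = unpredictable − predictable, age = elder − young,
sex = male − female, recorded with every output.

Degenerate inputs: a zero-variation stratum (noise-free synthetic data with a
null effect) reports F = 0, p = 1 rather than NaN; zero pooled SDs and zero
MSE raise explicit degenerate-data errors.

## Reproducibility and problem sizes

A `RunConfig` (YAML-serializable, hashed into every output) plus a seed
reproduces a run bit-for-bit; the pipeline streams subjects one at a time, so
a 40-subject cohort needs well under 1 GB. Monte-Carlo checks use sizes chosen
to make their statistical claims meaningful while keeping a laptop-scale run:
type-I calibration of the ANOVA uses 500 null RMS tables (binomial 3-SD band
around 0.05) plus a reduced end-to-end null (40 replicates of 12-subject
unit-gain cohorts, wide band); effect-size recovery averages 100 seeded
40-subject cohorts; gain monotonicity uses 3 gain levels × 6 replicates of
20-subject cohorts.

## Known limitations

* Real-data ingest (EDF / BrainVision via MNE) maps EEG and markers into the
  internal model, but platform acceleration must be supplied separately (the
  study recorded it on a separate device); EDF export of synthetic sessions
  is not provided — datasets are written as `.npy` arrays + JSON sidecars.
* The split-plot decomposition is exact only for a 2-level within factor;
  protocols with more than two analysis conditions would need a general
  mixed-model backend.
* Reported effect sizes for between-subject contrasts vary widely across
  conventions (pooled-SD, difference-SD, F-derived approximations) and are
  easy to misread across studies; the package therefore records the exact
  definition tag next to every d it outputs, and only the condition-effect d
  values serve as calibration targets for the generator defaults.
* The accelerometer model is single-axis; real-data ingest should use the
  Euclidean norm of available axes before onset detection.
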