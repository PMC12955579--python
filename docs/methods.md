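# Methods

`crossmodal_eeg` implements, as a reusable and fully tested pipeline, the
EEG analysis of a reciprocal audiovisual spatial-attention experiment,
together with a synthetic-data generator that emulates the statistical
structure those analyses assume.  This note documents the models, the
defaults and the design choices; nothing here reports an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The experiment being modelled

Participants covertly attend to sounds on one side (constant within a
block) and press a key for occasional white-noise targets on that side,
ignoring the other side and a task-irrelevant central grating.  Stimuli are
visual-only (V, central), auditory-only (A, lateralized) or synchronous
audiovisual (AV, lateralized sound + central grating).  The design is 12
blocks of 100 trials (1200 total; half the blocks left-attended), with
16% V / 42% A / 42% AV and 10% targets; targets occur only on
auditory-bearing trials at the attended side.  The inter-trial interval is
drawn uniformly from 950–1050 ms after a 100 ms stimulus.  The design
generator allocates all of these counts exactly (by counting, not
sampling) and shuffles order within block; allocation therefore requires a
block size that makes every percentage integral — any multiple of 50.
Counts that cannot be exactly balanced within one block (e.g. 21 A trials
cannot split 50/50 left/right) alternate their remainder across blocks so
the design-level balance is exact.

Recording geometry: 32 channels of the 10–20 system at 500 Hz, left-earlobe
reference, Fp1/Fp2 doubling as the EOG derivation (30 non-EOG channels
enter connectivity analyses).

## Forward model (synthetic data)

The generator is deliberately phenomenological: scalp topographies are gain
maps, not lead-field solutions, because the analyses under test operate on
scalp ROI means and are agnostic to the true source configuration.

Each trial adds a set of **component templates**: channel gain map ×
temporal envelope × signed amplitude (µV), modulated by modality, attention
state (stimulus at vs. opposite the attended side) and stimulus laterality.
Envelopes are exactly 1 over the component's nominal measurement window
with 10 ms raised-cosine ramps outside it, so every ROI × window mean
recovers its injected amplitude exactly in noiseless runs (the linearity
and exact-recovery tests rely on this).  A consequence is a known leakage
of amplitude × 0.05 into the 100-ms windows adjacent to a flat region.
Lateralized templates are written for left-side stimuli and mirrored
through the homologous electrode pairs for right-side stimuli.

Default components (amplitudes chosen to match the magnitude and topology
of effects this class of experiment reports; they are the package's study
conditions, not free dials):

| name | ROI | window (ms) | amplitude | modulators |
|---|---|---|---|---|
| AEP_N1 | fronto-central | 90–150 | −2.0 µV | A, AV |
| AEP_P2 | fronto-central | 220–320 | +3.0 µV | A, AV |
| SN | fronto-central | 220–320 | −0.7 µV | A, AV; attended only |
| SN_CONTRA_BIAS | contralateral fronto-central | 220–320 | −0.5 µV | A only; lateralized |
| ACOP | contralateral P3/P4–P7/P8 | 300–500 | +1.2 µV | ×0.5 in AV; lateralized |
| V_EVOKED | occipital | 120–250 | +2.5 µV | V, AV |
| SPREAD_OCC | occipital | 300–600 | −0.8 µV | AV attended only |
| SPREAD_CP | centro-parietal | 500–600 | −0.8 µV | AV attended only |

Because the V template enters both V and AV trials and the auditory
templates enter both A and AV trials with equal gain, the crossmodal
spreading contrast [(AV − A) − V] isolates exactly the attended-only
SPREAD terms; the ACOP modality asymmetry shifts both attention states
equally and cancels in the attended−unattended comparison.

**Oscillatory coupling.**  Every lateral A/AV trial carries a 10 Hz,
Hann-windowed burst (150–450 ms) at the seed channel T8 with a uniformly
random base phase; FC1 and Cz receive copies lagged by π/4 plus von Mises
jitter.  The concentration is κ = 20 for attended and κ = 0 (uniform lag,
i.e. no coupling) for unattended trials; burst amplitude is 12 µV in A and
6 µV in AV.  One lag is drawn per trial and shared by both partner
channels, so FC1–Cz is mutually zero-lag and contributes nothing to wPLI —
significance stays confined to the two injected pairs.  The random base
phase makes the bursts average out of every evoked measure.  The SNR
analysis behind the amplitude: with pink noise σ = 10 µV the per-trial
cross-term mean a²·sin(π/4) ≈ 100 µV² against noise cross-terms of
comparable scale yields attended wPLI ≈ 0.6–0.8 versus a small-sample null
of ≈ 0.1 at ~100 trials, giving the attended-vs-unattended contrast a
paired-t power well above 0.9 at 25 participants.

**Noise and artifacts.**  Background noise is spatially independent 1/f
("pink") noise, σ = 10 µV per channel, plus 2 µV white noise.  Blinks occur
with probability 0.08 per trial: a 300 ms biphasic (one-cycle sine)
deflection of 120 µV at Fp1/Fp2 decaying over frontal sites, timed to fall
inside the epoch.  120 µV reliably crosses the ±80 µV rejection threshold
while the bounded Gaussian background (max ≈ 5.5 σ ≈ 55 µV over a
recording) essentially never does, which is what makes the
rejection-bookkeeping check exact.  The 0.08 rate puts per-condition
retention near 91%, the order reported for experiments of this kind.
Per-participant heterogeneity is a multiplicative Normal(1, 0.1) random
effect on each component amplitude.

**Behavior.**  Attended targets are hit with probability 1 − lapse
(lapse = 0.02); RTs are shifted-gamma, 300 + Γ(4, 55) ms (mean 520 ms,
right-skewed); non-targets draw false alarms at 1%.  Scoring accepts
responses 100–1000 ms post-stimulus; later responses count as misses.

What the generator does **not** emulate: volume conduction (channel noise
is independent, so spatial correlation structure is absent), ongoing
band-limited oscillations, drifts and line noise, eye movements beyond the
threshold-crossing blink, latency jitter of components, and any
non-stationarity across blocks.  Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery* under the assumed
statistical structure, not robustness to every pathology of real EEG.

## Preprocessing

Continuous data are band-passed 0.1–30 Hz with 4th-order Butterworth
high- and low-pass sections (24 dB/octave one-pass) applied
forward-backward (`sosfiltfilt`), which doubles the effective attenuation
and zeroes the phase — the standard ERP choice.  Padding is three high-pass
time constants (30 s at 0.1 Hz) because the high-pass transient far
outlives scipy's default pad; recordings shorter than one time constant are
rejected.  Epochs are [−200, +800) ms around sound onset (half-open
windows throughout the package, so consecutive windows tile exactly), with
the −200–0 ms mean subtracted per channel.  The stated 800 ms epoch with a
200 ms baseline cannot contain the 200–700 ms analysis windows, so the
window extends to +800 ms.  Trials exceeding |80| µV (strict) on any
channel — EEG and EOG alike — are flagged `amplitude`; trials too close to
a recording edge are flagged `edge`.  Rejected trials are kept in place
with their reason, so designed = retained + rejected per condition by
construction.  Filtering happens only on continuous data, never per epoch.

## Component measures

All measures are ROI × window means of condition-averaged waveforms and
hence linear in the data.  Trials with incorrect responses (false alarms)
are excluded from averaging; target trials are scored behaviorally only.

- **Selection negativity (SN):** 220–320 ms mean over the fronto-central
  ROI, split into left (FC1/FC5/F3/C3) and right (FC2/FC6/F4/C4)
  hemisphere values, per attention side × stimulus side cell, separately
  for A and AV.  Electrodes are averaged before participant averaging
  (identical for means either way).
- **ACOP:** waveforms are collapsed contralateral/ipsilateral to the sound
  across stimulus side and the electrode pairs P3/P4 and P7/P8, then
  averaged in 300–400, 400–500 and 300–500 ms windows.
- **Crossmodal spreading:** S = (AV − A) − V per attention state, with the
  single attention-unspecific V evoked subtracted from both; ROI means
  (centro-parietal Pz/P3/P4/CP1/CP2 and occipital PO7/PO8/Oz/O1/O2) in
  five 100-ms windows, 200–700 ms.

## Connectivity

The trial-locked, time-domain wPLI between channels i and j over an
analysis window: from the analytic signal (per-trial demeaned, Hilbert
transform, no padding), with cross-terms X_k(t) = z_i,k(t)·conj(z_j,k(t))
across trials k,

    wpli(t) = |Σ_k Im X_k(t)| / Σ_k |Im X_k(t)|,

averaged over the window; 0 where the denominator vanishes (with a 1e−12
relative floor so numerically zero-lag signals report 0).  This is the
amplitude-weighted form; only the imaginary cross-term enters, so zero-lag
(volume-conduction-like) coupling contributes nothing and the measure is
invariant to positive rescaling of either channel.  The broadband
0.1–30 Hz signal is used as-is — this is deliberately a stimulus-locked,
time-domain measure, not band-specific synchrony.  The analysis window
defaults to 220–320 ms (aligned with the attention-selection window) and
is a configuration parameter.  Contrasts: per participant
D_A = wPLI(A att) − wPLI(A unatt) and D_AV likewise; D_A vs D_AV is
compared per channel pair with paired t-tests, BH-FDR corrected over all
435 non-EOG pairs.

## Inference

Repeated-measures ANOVAs (up to three two-level within factors) are
computed via statsmodels' `AnovaRM`; a single factor with more than two
levels goes through pingouin with Greenhouse–Geisser correction.  Partial
eta squared is recovered as F·df1/(F·df1 + df2).  Degenerate inputs
(constant response, 0/0 mean squares) report F = 0, p = 1.  Paired t-tests
report Cohen's d = mean(diff)/sd(diff), with deterministic conventions for
zero-variance differences.  All tests are two-tailed at α = 0.05.

FDR families mirror the reporting structure: (a) the 7 terms of each
3-way component ANOVA (the two ACOP windows pooled into one 14-test
family), (b) the 10 spreading window tests pooled across both ROIs,
(c) all 435 connectivity pairs.  Family layout is a documented convention
of this package, configurable by calling the test functions directly.

The within-subject power operation finds the smallest N with
noncentral-F power ≥ target, using λ = f²·N·m·ε/(1−ρ), df1 = (m−1)ε,
df2 = (N−1)(m−1)ε.  ρ (default 0.5) and ε (default 1) are exposed because
published power analyses routinely omit them; with f = 0.40, α = 0.05,
power = 0.90 and m = 2 the defaults give N = 19 — assumption-dependent,
as the acceptance output notes.

## Problem sizes and numerical choices

The packaged cohort presets are `paper` (25 participants × 1200 trials)
and `tiny` (3 × 600, the smallest design with exact allocation).  The test
suite runs parameter recovery at 25 participants × 600 trials and the null
false-positive control over 50 cohorts of 6 participants — sizes chosen so
the whole suite completes in minutes while keeping every check at its
stated tolerance.  The recovery check evaluates six effect estimates
jointly against Bonferroni-adjusted confidence intervals (joint coverage
95%), the statistically correct form of "every injected value inside its
interval".  Exact-recovery assertions (1e−9) apply to unfiltered noiseless
data; through the zero-phase band-pass the same quantities reproduce to
~0.5%, which the pipeline-level tests assert at 1% tolerance.

Two staged-execution caveats: continuous recordings are stored as 32-bit
floats (BrainVision), so disk-based stage replay matches in-memory runs to
~1e−4 µV rather than exactly; and report files embed a configuration hash
but no timestamps, making equal-seed runs byte-identical.

## Known limitations

- Phenomenological topographies and independent channel noise: no test
  here validates source-level claims or volume-conduction robustness
  (wPLI's zero-lag insensitivity is checked algebraically, not against a
  conducting head model).
- The wPLI analysis window and the FDR family boundaries are conventions
  of this package; both are configurable.
- Greenhouse–Geisser correction is available only on the single-factor
  path; the factorial path restricts to two-level factors, where sphericity
  is not at issue.
- The behavioral model has no speed–accuracy structure; it exists to
  exercise the scoring and exclusion logic.
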