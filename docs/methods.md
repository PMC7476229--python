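# Methods

This note documents the models, parameter choices and numerical conventions
behind `erptrack`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic validation does
and does not establish.

## Study design emulated

Two visits per infant (early and late infancy), passive viewing of 48 face
and 48 house trials per visit in 4 blocks of 24 (every stimulus identity
once per block, shuffled), 1000 ms stimulus duration, 700–1000 ms uniformly
jittered ISI. EEG: 32 channels on 10-20 positions (28 lateral + 4 midline),
2048 Hz acquisition. All of these are `CohortConfig` defaults and can be
changed, subject to the config invariants (trial count divisible by blocks,
sample rate a multiple of 512).

## Preprocessing conventions

- **"24 dB/oct" filters** are realized as 4th-order Butterworth designs and
  applied forward-backward (zero phase). Zero-phase filtering doubles the
  effective magnitude roll-off; we accept that because component *latencies*
  must not be phase-shifted, and latency fidelity outranks an exact match of
  the roll-off figure.
- **Cascade order.** The 30 Hz low-pass runs at the acquisition rate and is
  also the anti-aliasing filter; decimation to 512 Hz follows; the 0.1 Hz
  high-pass and the 50 Hz notch (2nd-order IIR, quality factor 35 — the
  notch design is a package choice) run on the decimated trace. For a
  signal band-limited by the low-pass this is exactly equivalent to
  filtering everything first and decimating last, at a quarter of the cost.
- **Epoch grid.** Epochs span −200…1000 ms. Windows are closed intervals on
  the 512 Hz grid: a sample at t = n/512 s belongs to [lo, hi] iff
  lo ≤ t ≤ hi. The first epoch sample is therefore −199.2 ms (sample −102)
  and the last exactly 1000 ms (sample 512); the baseline mean uses samples
  −76…0 (−148.4…0 ms).
- **Artifact criteria** are evaluated strictly and only within 0–600 ms
  post-stimulus: amplitude |v| > 200 μV (exactly ±200 passes); flatline =
  any 103-sample window (the largest window spanning ≤ 200 ms) with
  max−min < 3 μV; gradient |Δv| > 50 μV between consecutive samples. The
  first criterion that fires (amplitude, flatline, gradient) is the recorded
  reason.
- **Rejection order.** Look-away trials go first (whole trial). Then trials
  with flagged electrodes exceeding 16 % of the *full montage* (≥ 6 of 32)
  are removed, and only then are electrodes with < 5 artifact-free surviving
  trials (pooled over conditions) rejected. Doing trial removal first means
  a single globally bad trial cannot push electrodes below the count
  threshold. Pooled (not per-condition) electrode counting is a documented
  assumption.
- **Average reference** is computed per trial over that trial's usable
  (unflagged, unrejected) electrodes, so a flagged electrode never leaks
  into the reference. Trials with fewer than two usable electrodes are
  excluded with a log entry.
- **Inclusion.** A subject-visit enters a component family's analyses only
  if every critical electrode of the family retains ≥ 10 trials in both
  conditions. Exclusion propagates as an absent score, never as a crash.

## Component scoring

Mean amplitude = arithmetic mean over the window samples, then over the
critical electrodes. Peak latency = per-electrode extreme sample (max for
positive, min for negative components; earliest sample on ties, flagged
low-confidence when the whole window is flat), averaged across electrodes,
reported on the 512 Hz grid (≈1.95 ms resolution, no sub-sample
interpolation). The N290 has no detectable house-condition peak; requesting
it is an explicit error.

Peak-to-trough corrections: P1 subtracts the *mean* over the 70–90 ms N80
window (on the P1 electrodes); N290 subtracts the most positive P1-window
sample; P400 subtracts the most negative N290-window sample. The preceding
peak is evaluated on the *current* component's electrode set so the
subtraction compares like with like (the P1 and N290 electrode sets differ);
this is an interpretation, and the natural alternative (preceding
component's own electrodes) would be a one-line change in
`scoring._preceding_peak_value`.

## Trajectory model

The three states use the ±1.5 μV threshold; boundary values (exactly
±1.5 μV) are classified "none", and the threshold is a parameter everywhere
(it is an indicative, not an absolute, cut). The transition table is purely
descriptive — counts and row-normalized probabilities; no likelihood,
stationarity assumption or test on transitions. Summary percentages are
rounded half-up to integers, except the both-visit share which keeps two
decimals when not integral (matching how such tables are conventionally
printed). Subjects missing a component at either visit drop out of that
component's table only. Rows with a zero visit-1 marginal have undefined
probabilities and are flagged, not NaN-propagated into summaries.

## Inferential layer

The 2×2 fully-within ANOVA uses the standard decomposition: each effect is
tested against its subject-by-effect interaction, F(1, n−1), partial
η² = SS_effect/(SS_effect + SS_error). With 2-level factors sphericity is
trivially satisfied, so no correction is applied. Zero error variance
yields an explicit "undefined" result object. For every 2-level within
factor, F equals the square of the corresponding paired t — this identity
is asserted in the tests at 1e−10 relative tolerance, alongside agreement
with an independent ANOVA implementation. Cohen's d = mean(diff)/SD(diff).
The Brown–Forsythe test is a one-way ANOVA on |x − group median|; groups
with zero spread are valid input (F = 0 when all deviations vanish).

## The synthetic cohort generator

**Signal model.** Each component is a Gaussian bump in time (centre/SD in
ms: N80 80/10, P1 135/18, N290 235/28, P400 400/45, Nc 450/70), constant
across its electrode set and zero elsewhere. Per subject-visit-condition the
five bump amplitudes are solved jointly from a 5×5 linear system so that the
*pipeline-measured* windowed means — after common-average referencing, which
mixes a fraction |E_k|/32 of every component into every channel — equal the
subject's true targets. Overlap between neighbouring windows (e.g. the P1
tail inside the N290 window) is part of the same system. With zero noise
the full pipeline recovers the targets to ≈0.02 μV (filter distortion of the
bumps accounts for most of it); the widths above were chosen so this
residual stays within 0.05 μV while keeping the bumps inside their windows.

**Population model.** Per component, a subject's face−house differences at
the two visits are bivariate normal with per-visit mean/SD and between-visit
correlation (default 0.3); a per-subject-visit level offset (SD 5 μV)
shifts both conditions equally, so it moves condition means but never
difference scores. Defaults reproduce the published group-level condition
means per visit; the difference SDs (P1 7, N290 6, P400 7, Nc 5.5 μV)
approximate the spread implied by the published subgroup summaries. The
published study reports no trial-level noise figures, so the noise defaults
are stated assumptions: 30 μV per channel, half the variance 1/f ("pink"),
half white, independent across channels.

**Common-mode background.** Every channel additionally carries an identical
4 μV, 20 Hz sinusoid. It represents ongoing oscillatory background, keeps
signal-free channels from being literally flat (without it, a zero-noise
configuration trips the flatline criterion on every signal-free channel and
the 16 % rule removes every trial), and is cancelled exactly by the
common-average reference, leaving all windowed means untouched.

**Artifacts.** Injected per trial-electrode at `artifact_rate` (default
0.05), kind uniform among: Gaussian spike (±400 μV peak, 15 ms SD), flatline
(400 ms pinned to 0 μV) and step (±300 μV boxcar, 250–550 ms). Magnitudes
and durations are chosen so each kind is still unambiguously flagged *after*
the zero-phase filter chain: a narrow raw spike or a 60 μV step would be
smoothed below the amplitude and gradient thresholds by the 30 Hz low-pass,
and filter edge transients eat into a flat segment from both ends. The
per-sample gradient criterion consequently fires mainly on unfiltered epoch
data (it is tested at that level); in the filtered pipeline, step artifacts
are caught by the amplitude criterion. Look-aways are Bernoulli per trial
(default 0.25); with the default rates an included subject-visit retains
roughly 30–35 trials per condition, matching the published inclusion range.

**What the generator does not model:** head geometry / volume conduction,
spatially correlated noise, latency development (component centres are fixed
across visits and subjects, so latency contrasts are null in expectation),
topographic gradients within an electrode set, and ocular artifacts as a
distinct class. Passing recovery tests therefore shows that the pipeline's
arithmetic and rejection logic are correct under a controlled signal model —
not that the pipeline is robust to every pathology of real infant EEG.

**Determinism.** One master seed drives everything through
`numpy.random.SeedSequence` spawning: per-subject-visit children generate
trial plans, noise and artifacts, so any single recording can be regenerated
bit-identically on demand (`CohortRecordings` holds seeds, not traces — an
80-subject cohort never keeps more than one ~90 MB trace in memory). Traces
are rendered in float32 (noise synthesis and low-pass at 2048 Hz) and cast
to float64 at decimation, so epoch-level invariants (baseline and reference
residuals at 1e−9 μV) are exact while a full 160-recording cohort run takes
a few minutes on one CPU.

## Validation scales

The test suite exercises the end-to-end pipeline at reduced scale (3–12
subjects, 512 Hz direct emission, 16–48 trials per condition) to keep the
suite fast; the acceptance script runs the full default design (80 subjects,
two visits, 2048 Hz, 48+48 trials). Statistical calibration uses 2000 null
replicates at n = 80 (type-I error within the 99 % binomial interval of
α = 0.05) and 200 effect-pattern replicates for power (> 0.9 for both main
effects; interaction rejection near α).

## Known limitations

- EDF(+) input/export is not implemented; recordings are exchanged in the
  documented TSV layout.
- The published cohort's exact F statistics are functions of the real infant
  data and are not reproduction targets; only their form and the printed
  group means/counts are.
- No ICA/regression ocular correction, no electrode interpolation, no
  reference schemes beyond the common average (the emulated recording has no
  mastoids).
- The 16 %-rule denominator is the full montage and electrode rejection
  runs after trial removal; the original analysis software's order is not
  documented, so these are explicit package conventions.
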