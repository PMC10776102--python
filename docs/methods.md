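# Methods

## The measurement model

A subject stands quietly (feet together — Romberg — or heel-to-toe —
tandem Romberg), eyes open or closed, for 30 s per condition. Tri-axial
accelerometers at four sites (head, pelvis, left and right ankle) record
linear acceleration at 128 Hz. A trial may be terminated early if the
subject becomes unstable; truncated trials are analysed at their actual
length, which is safe because all four summary metrics are per-sample
averages or maxima.

Each sensor reads, in its own (possibly tilted) frame,

    s(t) = R · (a_AP(t), a_ML(t), a_CC(t) + g) + offset-scale errors,

where `a` is body sway acceleration on the anatomical axes, `g = 9.81 m/s²`
is the gravity reaction along the true vertical, and `R` is a fixed
mounting rotation (strap placement is never perfectly aligned). The
analysis never sees `R`; it must be undone from the data.

## Preprocessing

1. **Smoothing.** A centred 5-point moving average per channel suppresses
   muscle-vibration and sensor noise. Centring avoids the phase lag of a
   trailing window, which would bias the integrated-velocity metric; at the
   edges the window shrinks symmetrically so output length equals input
   length and a linear trend is preserved in the interior.
2. **Verticalized frame.** The mean acceleration vector over the whole
   trial estimates the gravity-reaction direction (sway is zero-mean, so
   the mean is gravity plus O(noise/√n)). That direction is the
   cranio-caudal axis CC (pointing cranially). The shortest-arc rotation
   carrying the nominal vertical onto the measured one maps the sensor's
   nominal forward axis (declared per site in a placement table; default:
   sensor x is forward everywhere) onto AP, and ML = CC × AP completes a
   right-handed triad. For a mounting tilt about any horizontal axis the
   shortest-arc rotation recovers the tilt exactly, so downstream metrics
   are insensitive to tilt (measured: < 10⁻³ % change over ±15°). The
   anatomical azimuth itself is unobservable from gravity alone; since all
   four metrics are magnitude-based per axis, the residual 180° ambiguity
   and any fixed azimuth offset are immaterial. Gravity estimation must
   precede mean subtraction — a pre-centred signal carries no vertical
   information and is rejected. A mean-vector norm outside [7, 13] m/s²
   flags the trial as unit-suspect.
3. **Baseline removal.** The whole-trial mean is subtracted per anatomical
   axis *after* rotation, removing the projected gravity constant and any
   static sensor offset in one step. The subtraction is iterated until the
   residual mean falls below numerical resolution, which makes the
   operation idempotent in floating point.

## Kinematic parameters

On each baseline-removed axis series a(t): maximum ACC = max |a|, mean
ACC = mean |a| (rectified mean — the plain mean is identically ~0 after
baseline removal, so the magnitude mean is the only informative reading),
RMS of ACC = √(mean a²) (the population SD of the zero-mean signal), and
MV = mean |v| where v is the cumulative trapezoidal integral of a with
v(0) = 0. Baseline removal keeps the integrand zero-mean, which bounds the
velocity drift; no further detrending of v is applied. The two ankles are
summarised at the metric level (their metric values are averaged), giving
three body parts × three axes × four metrics = 36 parameters per condition
and 144 per subject. All metrics are exactly scale-equivariant and satisfy
max ≥ RMS ≥ rectified mean ≥ 0.

## Statistics

Two designs mirror the clinical questions. VH (UVH and BVH pooled) vs HC:
independent two-sample pooled-variance Student *t* per parameter with
Cohen's d = Δmean / pooled SD. Subgroups HC/UVH/BVH: one-way ANOVA with
η² = SS_between/SS_total, then Scheffé pairwise tests — p = Pr[F(k−1, N−k)
≥ t²/(k−1)] with t on the ANOVA-pooled within-MS — only for parameters
whose corrected ANOVA p is significant. Raw p-values are Bonferroni
corrected with factor 12, the size of the hypothesis family sharing one
sensor placement and balance test (3 axes × 4 metrics); significance is
α = 0.05 on the corrected p. At k = 2 the scheme degenerates cleanly:
F = t² and the Scheffé p equals the t-test p. Pooled variance (not Welch)
matches the convention of standard clinical statistics packages; tests are
two-sided. Zero-variance cells produce explicit errors or flagged
degenerate results, never silent NaNs.

## The synthetic cohort generator

No recordings are distributed with the protocol, so cohorts are simulated.
Per axis, sway acceleration is zero-mean Gaussian noise restricted to
0.1–2 Hz (quiet-standing sway is low-frequency; a band-limited process
gives exactly controllable RMS — the track is rescaled so its sample RMS
equals the target) with base RMS 0.04/0.03/0.02 m/s² on AP/ML/CC,
plausible for trunk-level quiet standing. Group and condition enter as
amplitude multipliers on those bases: eyes-closed Romberg and eyes-open
tandem inflate ML sway strongly in BVH (3.0× and 4.0× vs 1.3× and 1.8× in
HC) and only negligibly in UVH (+5% over HC), while eyes-closed tandem
inflates every group equally (no group difference survives there). Each
subject draws one lognormal amplitude factor (σ = 0.3) shared across all
their trials — between-subject variability that makes group tests
realistically powered rather than trivially significant — and one mounting
tilt per sensor (uniform within ±5° by default about a random horizontal
axis), held fixed across conditions. High-frequency noise (RMS 0.01 m/s²,
white) models muscle vibration; being body-generated it is added in the
anatomical frame and tilted together with the sway. Gravity is added on CC
before the tilt rotation. Every sample is a deterministic function of
(config, seed) via per-subject and per-trial seed-sequence streams.
Clinical VNG labels (caloric weakness ≥ 25% → UVH, summed slow-phase
velocity < 6°/s → BVH) are attached to the subject table as metadata only.

What the generator does **not** emulate: inverted-pendulum biomechanics,
postural control feedback (sway spectra are flat in-band rather than
resonant), inter-axis and inter-segment coupling, non-stationarity within
a trial, gyroscope/magnetometer channels, or realistic clinical
heterogeneity beyond a single amplitude factor. Passing tests therefore
demonstrate that the pipeline recovers group structure of this form — not
that the default amplitudes are physiological; no published sway
amplitudes or spectra were available to calibrate them.

## Verification conditions and problem sizes

The test suite and `scripts/acceptance.py` check, besides unit-level
oracles (brute-force metric loops at 10⁻¹² relative; scipy/pingouin
cross-checks of t, F, η², d at 10⁻⁹):

- familywise calibration: on 50 replicate no-effect cohorts (two groups of
  31, identical multipliers) the corrected significance rate stays ≤ 5%
  (observed ≈ 0%; Bonferroni at factor 12 is conservative);
- effect recovery: on 50 replicate default-effect cohorts (HC/UVH/BVH,
  31 per group) head-ML maximum and RMS ACC separate BVH from HC
  (corrected ANOVA + Scheffé) in ≥ 90% of replicates (observed 100%), and
  no parameter separates UVH from HC in more than 10% (observed worst 2%);
- tilt invariance: all 12 per-axis metrics change < 1% as the simulated
  mounting tilt sweeps ±15° (observed < 10⁻³ %).

Replicate counts of 50 with full-length 30 s × 128 Hz trials keep each
suite within a few minutes on one CPU.

## Known limitations

- The anatomical azimuth is set by a declared placement convention, not
  estimated; a grossly mis-declared forward axis rotates sway between AP
  and ML silently (only the exactly-degenerate vertical case is caught).
- Mounting tilt is modelled (and corrected) as a rotation about a
  horizontal axis; an additional azimuthal mounting twist is absorbed into
  the placement convention rather than estimated.
- MV inherits low-frequency drift sensitivity from integration; with
  band-limited synthetic sway this is negligible, but real recordings with
  slow drifts may need the high-pass filtering this pipeline deliberately
  does not apply.
- The factor-12 Bonferroni family treats the 12 parameters of one sensor ×
  test × condition as the inference unit; findings across body parts or
  conditions are not jointly corrected.
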