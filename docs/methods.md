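# Methods

This note documents the models and procedures implemented in
`scratchkit`, the parameters that matter, the numerical choices made
where the design was genuinely open, and the limits of what the bundled
synthetic validation demonstrates.

## Signal model and conditioning

The accelerometer measures specific force in g: at rest it reads the unit
gravity vector rotated into the sensor frame, plus device noise; the
gyroscope measures body angular velocity in deg/s (converted to rad/s at
ingest).  Timestamps are float seconds UTC; intervals are half-open
`[start, end)`.

**Autocalibration.** Per-axis gain/offset (`a' = gain⊙a + offset`) are
fit by iterative least squares so that 10-s rest epochs (per-axis SD
< 0.013 g) lie on the unit sphere: each iteration regresses the closest
sphere point onto the raw values per axis.  The fit needs ≥ 10 min of
rest spanning ≥ 20° of orientation spread; otherwise identity parameters
are returned with a warning, and fits outside gain ∈ [0.8, 1.2],
|offset| ≤ 0.5 g are rejected as implausible.

**Resampling.** Linear interpolation onto a uniform 20 Hz grid,
`floor(duration · 20)` samples; only downsampling is allowed.

**Gravity removal.**
*Accelerometer-only:* first-order Butterworth high-pass, 0.25 Hz cutoff,
applied forward–backward (zero-phase) per axis, so that event timing is
preserved against millisecond-resolution labels.  The −3 dB point of the
single pass is at the cutoff; the zero-phase response is its square.
*Fused:* the sensor→world quaternion is integrated with
`q_{k+1} = q_k ⊗ δq(ω̄ Δt)` (midpoint angular velocity, renormalized each
step).  During stationary seconds (movement mask false) the orientation
is rotated toward the accelerometer-measured gravity direction by a
fraction α = 0.02 per sample — a complementary filter that bounds
gyro-bias drift.  Linear acceleration is `a − q⁻¹(0,0,1)q`.  α, like the
integration scheme, is a declared constant of this implementation: small
enough not to corrupt orientation during brief unflagged motion, large
enough to absorb a 0.5 deg/s bias within minutes.

## Movement filter

On the 20 Hz calibrated accelerometer (gravity still present):
VM = √(X²+Y²+Z²) is low-passed (6th-order Butterworth, 3 Hz) and
high-passed (1st-order, 0.25 Hz).  Two statistics drive the per-second
rule:

* rolling 1-s **coefficient of variation** of the band-passed VM,
  `SD / max(|mean|, 1e-6)`, one value per sample (centered window);
* per-second **maximum axis SD** of the band-passed axes, seconds tiled
  as non-overlapping `[k, k+1)`.

A second is movement iff strictly more than half (> 10 of 20) of its CoV
samples exceed θ_cov = 0.41 **and** the max axis SD exceeds
θ_sd = 0.013 g.  `fit_thresholds` recomputes both as the 8 % quantiles
of the pooled distributions of a cohort.

Two numerical choices deserve note.  First, the CoV operand: computing
CoV on a signal whose constant has *not* been removed makes the statistic
mean-dominated (≈ SD/1 g) and a 0.5 g scratch bout never reaches 0.41;
computing it on the band-passed VM gives the statistic its
discriminating shape — scratch-band oscillation averages to ~0 over 1 s
(CoV large) while slow postural drift stays mean-dominated (CoV small) —
and makes the printed thresholds live quantiles of the distribution.
Second, the filters here are **single-pass** (causal, seeded at steady
state): a forward–backward pass would square the 6th-order low-pass
magnitude response and suppress a 4.5 Hz scratch ~120-fold, below the SD
criterion.  Group delay (~0.1 s) is negligible at 1-s resolution.
Movement detection uses the accelerometer only.

**Non-wear.** Contiguous runs that are simultaneously non-movement and
colder than 25 °C for more than 10 min are off-wrist.

## Sleep window (TSO)

With a bed sensor or annotations the TSO is taken as given.  Otherwise a
z-angle heuristic: arm elevation `atan2(az, √(ax²+ay²))` on the 0.5 Hz
low-passed signal, averaged into 5-s epochs, 5-min rolling median;
epochs whose median changes < 5° form sustained-inactivity bouts; bouts
≥ 30 min inside the night gate (18:00–12:00), after excising non-wear,
and the TSO spans the first to the last such bout.  Two valid
overlapping hands are combined by **union** (intending to sleep is a
subject state; a quieter wrist should not truncate it); disjoint windows
keep the longer with a discordance warning; one valid hand stands alone.

## Windows and features

Movement runs are segmented into 3-s windows at 1.5-s hops (training) or
3-s tiles (deployment); a window is kept when ≥ 1 s of it is movement
and labeled scratch when annotated scratch strictly exceeds 1 s.  Edge
windows (partially outside movement) are kept and flagged.

Per sensor, 12 channels: x, y, z, their two leading principal-component
projections (per 3-s window covariance), VM, and central-difference
derivatives of all six.  The PC sign is fixed so the largest-magnitude
*sample of the projection* is positive — a convention that is a function
of the projected series only and therefore invariant under rotations of
the raw axes (a loading-based convention would not be).  Zero-variance
windows project to zeros.

Each channel yields 27 features: 16 time/frequency statistics (mean, SD,
min, max, range, RMS, IQR, median absolute deviation, skewness,
kurtosis, zero-crossing rate, lag-1 autocorrelation, dominant frequency
in (0, 10] Hz, its power, spectral entropy, spectral centroid — spectra
via mean-removed, Hann-windowed magnitude-squared FFT, DC excluded) and
11 topological features.  14 cross-channel features (6 axis/derivative
correlations, 3 axis–VM correlations, 2 PC explained-variance ratios,
signal-magnitude area, tilt mean and SD) complete 12×27 + 14 = **338**
columns per sensor; both sensors give 676.  Non-finite values are
imputed to 0.  The catalog is frozen and versioned; the printed totals
(338/676 interpretable, 348/686 with the 10 learned features) are
structural invariants of the bank.

### Topological features

The 0-dim sublevel-set persistence diagram of a 1-D window is computed
by a union-find sweep in value order: components are born at local
minima; at a merge the younger component dies (elder rule, ties to the
earlier index); plateau-induced zero-persistence pairs are merged away;
the essential class is closed at the global maximum, so `(min, max)` is
always present.  Features: mean, SD, skewness, kurtosis, and Shannon
entropy (base e, of the sum-normalized vector) of the lifespans
`d−b` and of the midlives `(b+d)/2` (midlives are shifted by their
minimum for the entropy term; sets smaller than two get zero
spread/shape terms; an empty diagram gives ten zeros), plus the L2 norm
of the Gaussian persistence curve
`G(t) = Σ ℓ_i · N(t; μ=m_i, σ=0.5 ℓ_i)` evaluated on a 256-point grid
spanning the window's value range.

## Classifier

Two small numpy networks are trained on the raw window tensors
(channels × 60 samples, per-channel standardized) with class-weighted
binary cross-entropy and Adam, then decapitated:

* conv: two blocks of (1-D conv k=5 → batch norm → ReLU → max-pool 2)
  with widths 16, 32, then dense 16 → 5 → 1;
* recurrent: bidirectional LSTM (hidden 32, concatenated final states)
  then dense 16 → 5 → 1 (learning rate 5e-3; BPTT over 60 steps
  converges slowly at the conv rate of 1e-3).

The 5-unit penultimate activations of each provide 10 learned features.
All layer gradients are verified against numerical differentiation in
the test suite.

The top layer is a LightGBM binary classifier on the selected features.
Recursive feature elimination drops the lowest-gain 25 % per round
(never past the target; a smaller 60-tree forest is used during
selection, since the ranking, not the classifier, is the product) down
to 16 features (accel) or 18 (both sensors), recording a validation-AUC
elbow curve.  The final model trains with `scale_pos_weight` set to the
training-set imbalance and early stopping (20 rounds) on a random 8–2
train/validation split of the training windows.  Evaluation is
leave-one-subject-out: extractors, feature selection, and trees are all
refit per fold; metrics (prevalence, AUC, accuracy, recall, specificity,
F1, PPV, NPV) are reported per fold at the held-out subject's original
prevalence and summarized as mean ± SD.

## Endpoints and agreement statistics

Deployment (after conditioning): movement filter → non-wear → TSO →
non-overlapping 3-s tiles with ≥ 1 s movement → classify at threshold
0.5 → pool hands by union (a tile is scratch if either hand calls it).
Total scratch seconds = 3 × positive tiles; hourly duration = total /
TSO hours; intensity = mean dominant frequency of the leading
principal-component projection of the positive tiles (orientation
invariant like the VM, but signed: the norm of a zero-mean oscillation
is rectified and would read twice the scratch frequency, whereas the
signed projection reads the programmed tone exactly).
With non-overlapping tiles, per-hour seconds sum exactly to the total.

Agreement: Bland–Altman mean difference with 95 % limits
`mean ± 1.96·SD`; one-way random-effects single-measure ICC(1,1) =
`(MSB − MSW)/(MSB + (k−1)MSW)` with k the mean group size (no rater
structure — nights are exchangeable repeats; subjects with one night are
excluded with a warning); Pearson and Spearman correlations both
reported (subject-level means against once-per-subject severity scores,
night-level against nightly sleep-scale items).

## Synthetic data: what it emulates and what it does not

`simulate_night` generates both hands of an annotated night at 50 Hz:
piecewise-constant orientation with 3-s smooth turns (gyroscope derived
from the same orientation path), gravity plus Gaussian noise
(SD 0.01 g), scratch bouts as amplitude-modulated sinusoids with ±10 %
frequency jitter mixed onto 1–2 random axes (plus a small, analytically
consistent wrist-rotation wobble), non-scratch movements as ≤ 1.5 Hz
band-limited motion with a posture turn, out-of-bed walking at ~1.8 Hz,
and non-wear as a frozen signal with temperature decaying exponentially
(τ = 3 min) toward 22 °C from a worn baseline of ~32 °C.  Annotations
are written at 1-ms resolution and tile the TSO exactly.  Defaults:
scratch frequency drawn uniformly in 2–5 Hz, hand-scratch amplitude
0.3–1.0 g, finger-scratch 0.02–0.08 g.  `simulate_cohort` draws one
frequency/amplitude style per subject, held across nights, so
leave-one-subject-out faces genuinely unseen styles; `severity` sets the
expected bout rate per sleep hour.

The validation study (`run_validation_study`, also driven by
`scripts/acceptance.py`) uses 10 subjects × 3 nights of 0.5 h each with
hand-style scratches at 10 bouts/h — problem sizes chosen so the full
LOSO study runs at desk scale while every stage still operates on
realistic signal.  Extractors train 5 epochs per fold in the study (10
in unit tests); these are scale choices, not tuned values.

What passing does **not** show: synthetic scratches are narrowband and
well separated from the other event classes, so near-perfect
classification here says nothing about performance on real patients,
where scratch morphology overlaps other hand movements; video-annotation
label noise, free-living confounders (typing, tremor), inter-device
variation, and real finger-scratch morphology are absent.  The study validates the
*machinery* — rule arithmetic, leakage-free evaluation, endpoint
conservation, statistical identities — not clinical performance.

## Known limitations

* Scratches expressed without wrist motion (rubbing, non-hand scratch)
  are invisible by construction.
* The movement filter attenuates the upper scratch band (the 3 Hz
  low-pass sits inside the 2–5 Hz scratch range even single-pass);
  low-amplitude bouts near 5 Hz can be lost — the synthetic cohort
  reproduces this amplitude/frequency sensitivity.
* The TSO heuristic assumes a night-time gate (18:00–12:00) and
  sustained stillness; shift workers or highly fragmented sleep would
  need a different gate.
* ICC of per-night durations on the default synthetic cohort is low by
  design: subjects share the same severity parameter, so between-subject
  variance is small; planted-severity cohorts recover high ICC.
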