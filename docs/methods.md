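# Methods

This note records the generative model, the signal-processing and modelling
choices, and the limits of what the synthetic experiments can show.

## Generative model of a session

A session is 884 s at 50 Hz: a 2 min rest baseline and four tasks of
nominally 2 min separated by 2 min rests, truncated at 884 s (the final task
is cut to 44 s and the closing rest dropped). 884 s is the session length
that a 3 s window with 1 s step segments into exactly 882 windows, the
standard per-user sample count for this protocol. Each segment carries a
latent stress state: rest = 0, tasks 1–2 = 1 (mild), tasks 3–4 = 2 (strong),
matching the observation that the Stroop task is a weaker stressor than
arithmetic under time pressure or memory recall. Self-reported Likert
ratings (0–4) are derived deterministically from the state (0 → 0, 1 → 2,
2 → 4); rating noise — a participant whose report contradicts their
physiology — is *not* modelled, so label noise in real data is understood to
lower all reported accuracies.

**Blinks.** Inter-blink intervals follow a Gamma(shape 2) renewal process:
blinks have a refractory period, and the gamma shape suppresses the
near-zero intervals a Poisson process would produce. Consecutive apices are
additionally kept at least the sum of half-durations apart so waveforms
never overlap. Rest-state parameters: 15 blinks/min, 0.28 s mean duration,
150 µV mean amplitude — typical values for relaxed adults recorded with
eyewear EOG. Stress modulation (relative to rest): state 1 multiplies rate
×1.4, duration ×1.2, amplitude ×0.85; state 2: ×1.8, ×1.4, ×0.7 — the
directions established for cognitive load (shorter inter-blink intervals,
longer and smaller blinks), with magnitudes chosen to be detectable yet
overlapping. Between-subject variability is log-normal on all three
parameters (sd 0.15/0.10/0.15 in log space); per-blink jitter is log-normal
(sd 0.15 duration, 0.20 amplitude). Each blink is rendered as a unit-peak
raised-cosine (Hann) pulse scaled to its amplitude.

**Other signal components.** Saccades: a piecewise-constant gaze level
renewed at Poisson events (12/min, steps up to ±50 µV) — full amplitude on
the horizontal channel, ×0.3 on the vertical; a bounded level process rather
than a random walk, since gaze position is bounded. Drift: a 30 µV, 60 s
sinusoid with random phase, standing in for slow electrode-skin potential
wander. White measurement noise: sd 10 µV. Acceleration: 1 g gravity on the
z axis plus sensor noise (sd 0.02 g). Motion artifacts (1/min, Poisson):
a 0.3 s, 300 µV spike on the vertical EOG with a coincident 0.6 g burst
along the gravity axis (±0.3 g on x/y), so every EOG artifact has an
accelerometer signature — the premise of accelerometer-coupled rejection.

Determinism: each subject draws from
`SeedSequence((config_seed, subject_index))`; identical configurations give
bit-identical cohorts.

## Preprocessing

The EOG bandpass is a Butterworth of overall order 6 (three conjugate pole
pairs), 0.25–7.5 Hz, applied forward–backward in second-order sections:
zero-phase filtering keeps blink apices aligned with ground-truth times
(the pipeline is offline, so causality is not required), at the cost of
squaring the magnitude response. The acceleration filter is an order-8
windowed-sinc FIR (Hamming), 10 Hz cutoff, also applied zero-phase. Signals
are reflection-padded before filtering to suppress startup transients on
short inputs.

Artifact masking thresholds the *low-passed* acceleration magnitude at
mean + 3 sd with a strict inequality (so a constant magnitude masks
nothing). Masked samples, dilated by a 0.5 s guard on each side (covering a
blink-scale transient around the super-threshold apex), are replaced by
linear interpolation between the nearest clean samples — interpolation
rather than deletion preserves the uniform time base that fixed-length
windows require.

## Blink detection

Candidates are local maxima of the filtered vertical channel with prominence
≥ 3× a MAD-based robust noise sd, separated by ≥ 0.2 s (blink refractory).
Each candidate is scored by fitting the canonical raised-cosine template,
duration-rescaled to the pulse's measured half-amplitude width (for a Hann
pulse the half-amplitude width is exactly half the duration) and refined
over a small multiplicative duration grid. Three details matter in practice:

- the template is passed through the same zero-phase bandpass as the signal,
  so the score measures waveform shape, not filter distortion (which grows
  with blink duration);
- the least-squares fit includes a linear baseline nuisance term, because
  blinks ride on the slow undershoot the 0.25 Hz high-pass edge leaves
  behind;
- after an initial pass, each event is rescored with its fitted neighbours
  subtracted, removing the mutual interference of blinks in rapid bursts.

The score is the normalized RMSE (residual RMSE divided by fitted
amplitude), which is invariant to rescaling the signal. Acceptance is
adaptive per session: rmse_norm ≤ min(0.5, Q3 + 1.5·IQR) — a Tukey upper
fence with an absolute cap. The composite detector also requires the fitted
amplitude to clear the same 3σ floor as the raw peak prominence; this
suppresses small noise bumps whose smooth shape would otherwise fit the
template well. On noise-free sessions the detector recovers the ground
truth exactly; at the default noise level its F1 against ground truth is
≈ 0.94 (pooled over 12 subjects).

## Features and selection

Nine statistics per 3 s window (1 s step), with fixed conventions:
population (divide-by-n) variance/sd throughout; "total" signal =
vertical + horizontal, element-wise; the covariance feature is
cov(vertical, total) within the window; the RMS feature is taken about zero
(the bandpassed signal is ≈ zero-mean); blink-dependent features are 0 in
blink-free windows (keeping the matrix dense); windows crossing a segment
boundary are dropped before labelling, since a window spanning rest→task has
no single true label. Task windows are labelled from the Likert rating:
two-class stress at rating ≥ 2; three-class no-stress ≤ 1 / level 1 at 2–3 /
level 2 at 4.

Lasso selection standardizes features with training-split statistics,
encodes the class labels as consecutive integers, and removes features with
exactly-zero coefficients. When no penalty is supplied it is chosen by
5-fold cross-validation with the **one-standard-error rule** (the largest
penalty whose CV error is within one SE of the minimum): the CV-minimum
penalty systematically retains small spurious coefficients, while the 1-SE
rule recovers the true support in ≥ 90% of replicates on a
2-informative + 7-noise design. Selection is refitted inside every training
fold to avoid leakage. Constant feature columns cannot be standardized and
are dropped with a log entry.

## Classifiers and evaluation

Random forest, logistic regression (newton-cg, multinomial), linear SVM
(one-vs-one), decision tree, and distance-weighted KNN (Euclidean), with the
tuned optima as per-scheme defaults (e.g. two-class RF: max_depth 12,
8 estimators) and grid search over brackets of those optima using a
stratified 10% validation split of the training rows (ties broken by grid
order). Grid search evaluates grid points on the full feature set, so
hyperparameter choice is not conflated with selection. The linear models'
bracket extends the iteration caps to converged settings: an iteration cap
tuned on one dataset can leave the solver far from the optimum on another —
at ~10⁴ windows the two-class cap of 80 libsvm iterations (vs ~9,000 needed)
yields near-chance output.

Protocols: stratified, seeded 10-fold CV (each window tested exactly once)
and LOSO CV (one fold per subject; every fold is audited for disjoint
train/test subject sets). Metrics from the pooled one-vs-rest confusion
counts: accuracy, precision, recall, F1 = 2TP/(2TP+FP+FN), specificity;
multi-class summaries are macro averages (the convention that also yields
per-class tables); zero-denominator cells are reported as 0 and flagged.
Per-task accuracy restricts each task's test windows plus all rest windows,
using the globally trained model.

## What the synthetic experiments do and do not show

The generator produces the *structure* of the real measurement problem —
state-modulated renewal blink trains, filter-distorted pulse shapes,
coupled motion artifacts, subject heterogeneity — so it validates the
pipeline's mechanics end to end: artifact recall, blink F1, window
bookkeeping, leakage-free cross-validation. It does not reproduce real blink
morphology variation (partial blinks, flurries), EMG/mains interference,
electrode displacement, or self-report noise, so absolute accuracies on
synthetic cohorts do not predict accuracies on human data.

One structural finding is robust and worth stating: with the prescribed
stress modulation (rate *up*, amplitude *down*) and zero-filled blink-free
windows, the class boundary is substantially non-linear. Tree-based and
neighbour models clear the majority-class baseline by 17–21 percentage
points on the default cohort, while fully converged linear models (logistic
regression at any C; linear SVM without iteration cap) plateau ~7 points
above baseline. This is a property of the feature geometry, not of solver
settings.

## Problem sizes and numerical details

Default experiments use 12 subjects × 884 s (≈ 10,400 labelled windows),
the cohort size the protocol prescribes; the bundled examples use 1–4
subjects. Filter-response checks use 60 s tones and compare measured
steady-state amplitudes against the designed (squared, zero-phase) response.
Floating-point window counting uses a 1e-9 slack before flooring. Blink
matching uses greedy nearest-apex assignment within ±0.1 s. CSVs are written
with 9 significant digits; round-trips reproduce samples to 1e-9 relative.
The pipeline manifest records a SHA-256 hash per output file, and a single
global seed fans out to stage seeds via `SeedSequence((seed, stage_index))`.
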