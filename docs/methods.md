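# Methods

This note documents the models, parameters and numerical choices behind
minisleep, and what the synthetic benchmark does and does not establish.

## The mini-epoch framework

A hypnogram is a sequence of stage labels over {W, N1, N2, N3, REM} plus an
ART token for unscorable mini-epochs. Labels live on a fixed grid: label *i*
covers the half-open interval [t₀ + i·τ, t₀ + (i+1)·τ) with τ = 5 s for
mini-epochs and τ = 30 s for conventional epochs (six mini-epochs per epoch).
Each N1/N2/REM label carries a boolean *characteristic flag*: False means the
mini-epoch was staged from context because no stage-defining graphoelement
was visible. W and N3 cannot be scored without characteristics, so their flag
is always True; this invariant is enforced in the container itself.

## Synthetic PSG generator (`synth`)

The generator exists so every downstream component is testable without
clinical data. It emulates the structure of a mini-epoch scoring study —
100 recordings, two randomly placed 20-min segments per recording (240
mini-epochs per segment, 48 000 total), an NT1/sibling cohort with partial
family pairing — not the physiology of full nights (no sleep cycles,
ultradian rhythm, EMG or respiration; see Limitations).

**Stage sequence.** A first-order semi-Markov chain on the 5-s grid. At each
boundary the stage switches with probability p = rate·τ/60, giving geometric
dwell times and an expected transition rate exactly equal to the group
target; the entering stage is drawn from the occupancy prior (W .08, N1 .07,
N2 .52, N3 .16, REM .17) restricted to the other stages. Defaults: NT1 2.0
and siblings 1.5 transitions/min — free parameters chosen to plant a
recoverable fragmentation contrast whose population mean (0.38·2.0 +
0.62·1.5 ≈ 1.7/min) matches a realistic mini-epoch transition rate. Rates
above 12/min are rejected (one switch opportunity per 5-s boundary).
Artifact labels are injected i.i.d. with p = 0.0046; the characteristic flag
is drawn False with p = 0.308 for N1/N2/REM labels only.

**Signals.** Background is 1/f^β-coloured Gaussian noise per channel,
generated per maximal stage run, with stage-specific slope and RMS
(W 1.0/10 µV → N3 2.2/20 µV; ART is a 300 µV broadband burst). Each
mini-epoch whose flag is set receives its stage's graphoelement with
AASM-style morphology: W — 10 Hz alpha run covering 60% of the mini-epoch at
40 µV on the occipital channels; N3 — 1 Hz waves at 75 µV amplitude
(150 µV peak-to-peak) covering 70% on the frontal channels; N2 — a 13 Hz,
1.0-s, 35 µV spindle (central) or a 0.8-s, ~180 µV peak-to-peak K-complex
(frontal); N1 — a 1.2-s, 60 µV slow eye movement (anti-phase on the two EOG
derivations) or a 0.3-s vertex wave (central); REM — a 0.25-s, 80 µV rapid
eye movement (anti-phase EOG). Channel assignment is deliberately disjoint
(alpha occipital, spindle/vertex central, K-complex/delta frontal, eye
movements EOG) so detector cross-talk cannot occur by construction. The
planted event list is returned as ground truth. `noise_scale=0` produces a
clean render used for detector validation.

**Segment placement.** Uniform over mini-epoch grid positions inside the
lights-off/lights-on window; the two segments are constrained to be
non-overlapping (a design choice — overlap would double-count labels),
via rejection sampling.

**Determinism.** All randomness descends from one `SeedSequence`; label
sequences are bit-identical across runs of the same seed.

## Rule-based scorer (`rules`)

The scorer turns visual staging criteria into signal tests. Per mini-epoch it
computes: the fraction of samples where the occipital 8–12 Hz Hilbert
envelope exceeds 20 µV (alpha fraction); the fraction where the frontal
0.5–2 Hz envelope exceeds 37.5 µV — half the 75 µV peak-to-peak convention —
(slow-wave fraction); band-limited envelope detections for spindles
(11–16 Hz, 0.4–2 s), K-complexes (0.5–3 Hz, 0.4–1.2 s, suppressed when slow
waves dominate the mini-epoch, since that is delta activity rather than an
isolated K-complex), and vertex waves (2–8 Hz, <0.5 s); and EOG deflections
on the low-passed difference signal, anti-phase across the two derivations
(correlation < −0.3), classified slow vs rapid by peak slope (threshold
400 µV/s). An optional artifact detector flags mini-epochs whose broadband
RMS exceeds 150 µV.

Decision order: artifact → alpha >50% → W; slow waves >50% → N3; otherwise
stages with event evidence compete and the *predominant* stage (largest total
evidence duration; ties N2 > REM > N1) wins with flag True. Mini-epochs with
no evidence are resolved in a second pass against the first-pass labels: the
nearest N1/N2/REM label wins (preceding preferred at equal distance, window
configurable, default whole segment), flag False. If no context exists, the
mini-epoch's Welch log-band-power profile (δ/θ/α/σ/β) is matched to stage
templates — in-segment means of first-pass N1/N2/REM mini-epochs when
available, otherwise canonical profiles derived from the generator's stage
colours. The two-pass design replaces a human's free scrolling with a
deterministic, order-independent procedure. EMG is ignored throughout: low
muscle tone is deliberately not a REM criterion, mirroring mini-epoch scoring
practice in populations where REM atonia is unreliable.

On clean renders the detectors recover the planted event list with recall
and precision 1.0, W/N3 are exact, and overall weighted F1 with 30.8%
suppression stays above 0.9 (measured ≈0.95–0.99); at full noise it remains
≈0.92–0.95, though only the clean-render figures are pinned by tests.

## Segmentation network (`netmodel`)

A U-shaped fully-convolutional network over one EEG×EOG pair, implemented in
NumPy with explicit backprop (gradients pinned by finite-difference tests to
~1e-8 relative error). Encoder blocks are conv(k=9) → ELU → batch-norm →
2× max-pool; the decoder mirrors them with nearest-neighbour upsampling and
skip concatenation; a per-sample feature map is mean-pooled over the output
period (30 s or 5 s at 128 Hz) and a 1×1 convolution maps pooled features to
stage logits. Only the pooling width depends on the output period, so the
parameter vector is identical at both resolutions — the precondition for
transfer, asserted by shape comparison. Checkpoints store parameters plus
batch-norm running statistics (restoring one without the other silently
corrupts inference).

Preprocessing: polyphase resampling to 128 Hz, per-channel robust scaling
(median/IQR, std fallback for zero-IQR channels, all-constant rejected) and
clipping at ±20 scaled units as the outlier rule (the bound is a config
value). Segments are processed whole, tiled into non-overlapping input
windows (default 30 s). Majority voting over the 12 EEG×EOG pairs breaks
ties by highest mean probability, then by the fixed stage order W < N1 < N2
< N3 < REM; missing montage channels shrink the vote with a logged warning.

The default desk-scale configuration (depth 2, 4 base filters, ~2k
parameters) is sized for CPU minutes, not clinical accuracy; depth, width,
kernel and window are all exposed in `ModelConfig`.

## Transfer harness (`transfer`)

Splits are recording-level (both segments of a PSG share one assignment) and
stratified on group × sex by largest-remainder allocation; 80/10/10 by
default, surplus recordings joining the training set. Fivefold CV partitions
the cohort into 5 disjoint test sets of n/5 with 10 validation recordings
drawn per fold.

Training samples minibatches of (segment, channel pair, window) uniformly,
optimizes masked cross-entropy (ART positions excluded from the loss) with
Adam, and evaluates prevalence-weighted validation F1 every `eval_interval`
steps on voted predictions. The patience counter (default 500) counts
*evaluation rounds* without improvement — the natural reading of a
convergence criterion whose unit the protocol leaves ambiguous; the interval
is configurable, so patience-in-steps is recoverable. The returned model is
the best-validation checkpoint, never the last step, and a zero learning
rate is an exact no-op. The canonical fine-tuning learning rate for a
full-scale model is 1e-7; the desk-scale experiments use 1e-3/3e-4 because a
~2k-parameter model trained from scratch needs usable step sizes —
`transfer_experiment` (12 recordings, 5-min segments, 150 + 300 steps)
reproduces the qualitative transfer result in about 40 s per seed.

## Evaluation statistics (`evalstats`)

One confusion matrix per recording with segments combined; mini-epochs where
either scorer says ART are excluded and counted. Per stage: TP = diagonal,
FP = column − TP, FN = row − TP, precision, recall and F1 by the standard
formulas. A stage is *present* when either scorer used it (row+column > 0);
absent stages are undefined (None), representing missing agreement rather
than disagreement, and are excluded from stage-wise averages with the
contributing n reported. The overall F1 weights present stages by
reference-scorer support within the recording (a "pooled" option exists;
per-recording reference weights were chosen because all analyses are at the
recording level). Means and 95% CIs use the seeded percentile bootstrap
(n = 1000, resampling recordings).

Transitions are adjacent label changes within a segment, never across
segment boundaries; ART labels are deleted and their flanking labels treated
as non-adjacent, while the denominator keeps full segment minutes.
Sleep–wake transitions are changes where exactly one side is W. The 30-s
comparison view majority-collapses mini-epochs per epoch (ties to the
earlier stage in canonical order) and expands back; expansion→collapse is an
exact round trip for any epoch hypnogram.

Paired comparisons use the two-sided Wilcoxon signed-rank (normal
approximation with tie correction, no continuity correction, no
multiple-testing correction) with effect size r = Z/√n; all-tied inputs
return the null convention p = 1, r = 0. Group comparisons fit
√(outcome) ~ group + age + sex with a family random intercept (REML);
Cohen's d is the group coefficient over the residual SD on the transformed
scale. Without family replication, or on a singular fit, an
independent-errors linear model is used with a logged warning — in the
no-clustering limit this coincides with OLS exactly.

Calibration checks pinned by the test suite: weighted and per-stage F1 match
scikit-learn to 1e-12 on random matrices; Wilcoxon type-I error at α = 0.05
lies in [0.04, 0.06] over 10 000 null replicates; bootstrap CI coverage of
the mean is ≈95% (asserted 92–98% over 1000 replicates at n = 50); the mixed
model recovers a planted d = δ/σ within 3 standard errors over 200
simulations.

## Problem sizes

The default test and acceptance runs use: full label-level geometry (100
recordings, 48 000 mini-epochs) wherever signals are not needed; 20-min
rendered segments for the rule-scorer checks; and the desk-scale
`transfer_experiment` preset (12 recordings × 5-min segments, ~450 optimizer
steps, 5 seeds) for the transfer property. These sizes were chosen so the
whole suite runs in minutes on one CPU while keeping every check at the
label-geometry scale of the full design.

## Limitations

Passing tests on synthetic data show that the *machinery* is correct —
detectors recover what the generator plants, the statistics match
independent references, transfer improves a model trained at the wrong
resolution — not that any component reaches clinical performance. The
generator omits real-data features that matter in practice: continuous
background dynamics and arousals, graphoelement variability and co-occurrence
across channels, EMG/atonia, respiratory and movement artifacts, inter-scorer
disagreement, and full-night architecture. Detector thresholds are tuned to
the generator's amplitude conventions and would need re-tuning for real PSG.
The desk-scale network is orders of magnitude smaller than a clinical
segmentation model; only the directional transfer effect, not its magnitude,
is meaningful here.
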