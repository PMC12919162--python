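# Methods

`mcieeg` implements a feature-driven pipeline for discriminating mild
cognitive impairment (MCI) from healthy controls (HC) in resting-state
scalp EEG: engineered per-channel descriptors of nonlinear dynamics and
frequency-band-specific functional connectivity feed an attention-based
classifier evaluated strictly across subjects, with Shapley-value
attributions aggregated into channel, feature and band importance
tables. This note records the models, the parameter choices and their
rationale, the numerical conventions, and what the synthetic validation
does and does not establish.

## Preprocessing

Continuous recordings (20 channels of the 10–20 montage at 256 Hz) are
band-pass filtered to 0.5–40 Hz, downsampled to 100 Hz, re-referenced
to the common average, stripped of the POz electrode (leaving 19
analysis channels), and cut into non-overlapping 3-second epochs of
19 × 300 samples.

- **Filter.** Zero-phase Butterworth (`sosfiltfilt`), default order 8
  with even edge extension. A 4th-order filter is the more common EEG
  default, but its effective stopband at 1.25× the upper edge leaves
  over 10 % of a 50 Hz tone (including start/end transients); order 8
  holds this below a few percent, which is the behaviour the pipeline's
  stopband contract tests. The order is configurable.
- **Resampling.** Polyphase rational resampling (256 → 100 is handled
  exactly as 25/64) with built-in anti-aliasing.
- **Two-level normalization.** Stage 1 z-scores each channel with that
  subject's pooled statistics (mean/SD over all of the subject's epoch
  samples); stage 2 z-scores each subject's entire epoch tensor with
  its pooled mean/SD. Pooled (rather than per-epoch) statistics were
  chosen as the simplest reading of "align distributions between
  participants"; per-epoch z-scoring would erase between-epoch
  amplitude variation that the features may legitimately use.
  Zero-variance channels become identically zero and are flagged.
- **Class balancing.** The minority class is augmented by perturbed
  duplication: additive Gaussian noise at 0.1 × the epoch's SD,
  amplitude scaling from U(0.9, 1.1), and circular temporal shifts up
  to ±0.3 s — all sub-SD perturbations intended to mimic intra-subject
  variability without altering class identity. Augmented epochs retain
  their source subject identifier, which is what makes the group-wise
  split a leakage guard.
- Artifact rejection is off by default; a configurable absolute
  amplitude threshold is available. Independent component analysis is
  deliberately not part of the pipeline.

## Nonlinear dynamical features (12 per channel)

Computed per epoch channel (300 samples at 100 Hz). Defaults follow the
short-series literature: embedding dimension m = 2 and tolerance
r = 0.2 × SD for the entropy family, lag 1, coarse-graining scales 1–5,
Higuchi k_max = 10, embedding dimension 5 for the chaos estimators, DFA
windows log-spaced in [4, N/4].

- **ApEn, SampEn** — template-matching irregularity (Chebyshev
  distance); ApEn includes self-matches (Φ-formulation), SampEn
  excludes them and is the ratio −ln(A/B) over the first N−m templates.
- **MSE** — mean SampEn over coarse-grained series at scales 1–5, with
  r fixed from the original series' SD (Costa's convention), so
  coarse-graining genuinely removes matchable variance. The scalar
  reduction (mean over scales) is configurable to a single scale.
- **FuzzyEn** — baseline-removed templates with membership
  exp(−(d/r)^n), n = 2. The dimensionless d/r form is used because it
  is exactly invariant under affine rescaling of the input; the
  dimensional variant exp(−d^n/r) found in parts of the literature is
  not.
- **LZC** — median binarization followed by the Lempel–Ziv 1976
  incremental parse; normalized as c(n)·log2(n)/n. A constant run
  parses to c = 2 (the first symbol always opens phrase one).
- **Higuchi FD, Katz FD** — standard constructions; Katz standardizes
  the series first so the planar-curve measure becomes scale-invariant.
- **DFA** — linear detrending per window of the integrated profile;
  slope of log F(s) vs log s.
- **Hurst** — rescaled-range analysis with the Anis–Lloyd–Peters
  small-sample correction (the raw R/S statistic is biased upward at
  short segment lengths; the corrected estimator recovers H ≈ 0.5 on
  white noise).
- **Largest Lyapunov exponent** — Rosenstein's nearest-neighbour
  divergence method (Theiler window 10, divergence fit over iterations
  0–8), in nats per sample. Validated against the analytic ln 2 of the
  fully chaotic logistic map.
- **K–S entropy** — sum of positive exponents of an Eckmann-style
  tangent-space spectrum (local Jacobians from nearest-neighbour
  displacements, QR-accumulated). Exponents under a resolution floor of
  0.05 nats/sample count as zero, which suppresses the spurious small
  positives that smooth signals otherwise produce. On failure the
  estimate falls back to max(0, λ₁) and is flagged. With embedding
  dimension 5 on short noisy series the spectrum contains spurious
  directions, so this feature is a consistent *relative* descriptor
  across epochs rather than an unbiased physical rate.
- **Correlation dimension** — Grassberger–Procaccia slope over the
  scaling region, taken as radii where C(r) ∈ [0.05, 0.7]; the small-r
  end is excluded because the Theiler correction distorts it on
  300-sample epochs.

Undefined values (e.g. SampEn with zero matches, Katz of a constant)
are returned as NaN with a flag and later imputed with the training-set
feature mean — never with label information.

A known caveat, preserved deliberately: ApEn's self-match bias makes it
non-monotone between white and mildly smoothed noise (the flaw that
motivated SampEn), so ordering checks hold it only to the weaker
noise > sinusoid contrast.

## Connectivity graphs (65 features per channel)

Magnitude-squared coherence between all channel pairs is estimated by
Welch segment-averaged cross-spectra (1-s Hann windows, 50 % overlap,
constant detrend — five segments per 3-s epoch), averaged over each of
five canonical bands: delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30,
gamma 30–40 Hz (half-open bins on the 1 Hz Welch grid). Each band's
coherence matrix is an undirected weighted graph; a binary adjacency is
derived by an absolute threshold (default w > 0.5). The threshold is a
necessary free parameter: without it, degree, density, assortativity
and transitivity are degenerate on an all-positive coherence matrix. An
absolute (rather than proportional) threshold preserves between-epoch
variance in the binary metrics.

Node-level metrics: binary degree; strength; Onnela weighted clustering
(weights normalized by the graph maximum); weighted betweenness
(Brandes accumulation, normalized by 2/((N−1)(N−2))); eigenvector
centrality (power iteration on W, dominant component, nonnegative unit
norm); local efficiency on each node's weighted neighbour subgraph.
Graph-level metrics: weighted global efficiency (disconnected pairs
contribute zero), weighted characteristic path length (largest
connected component), mean weighted clustering, small-worldness,
degree assortativity, density and transitivity (binary). All weighted
shortest paths use edge lengths 1/w.

Small-worldness σ = (C/C_rand)/(L/L_rand) is computed on the binary
topology against a seeded ensemble of 10 degree-preserving
double-edge-swap randomizations (4 swaps per edge); on graphs drawn
from the null family itself, E[σ] ≈ 1 within Monte-Carlo tolerance.
Whether the original analysis used weighted or binary C and L in σ is
not determinable; binary was chosen to match the null ensemble's
topology exactly.

The seven graph-level scalars are broadcast to every channel slot when
the tensor is assembled, giving 5 × (6 + 7) = 65 connectivity features
per channel and 12 + 65 = 77 features per channel in total.

## Feature normalization

Feature-wise z-scoring pooled over epochs × channels, fitted on
training epochs only and reapplied verbatim to validation and test
epochs. Fitting on training data only is a deliberate strictness:
normalizing over all epochs before splitting would leak test-set
statistics into training and weaken the cross-subject claim the
evaluation protocol exists to protect.

## Classifiers

Both models consume the identical (19 channels × 77 features) matrix.

**Feature Transformer** (primary). 1-D convolutional embedding along
the channel sequence (128 filters, kernel 5) with batch normalization,
a trainable positional embedding, then 6 post-norm encoder blocks with
5 attention heads and a 64-unit feed-forward layer; dropout 0.1 and L2
5·10⁻⁴ regularize; global average pooling over channel tokens feeds a
64-unit dense layer and a 2-way softmax. Since 128 is not divisible by
5, queries/keys/values project to 5 × 25 = 125 dimensions and the
attention output projects back to 128 (the framework-style uneven-head
convention). Tokens are channels, so attention models cross-channel
interactions directly. A 3-block/4-head variant is reachable through
the same configuration object.

**Feature EEGNet** (baseline). The compact depthwise-separable recipe
with the 77-feature axis in the role of time: shared temporal
convolution (8 filters, kernel 31), depthwise spatial convolution over
the 19 channels (multiplier 2), separable convolution (kernel 15 →
16 maps), ELU, average pooling by 4 then 8 (axis truncated to the
nearest multiple), dropout 0.4, dense softmax. Kernel and pooling sizes
are the canonical recipe proportionally rescaled to a 77-length axis.

**Training.** Adam (Transformer lr 10⁻⁴, batch 8; EEGNet lr 10⁻⁵,
batch 4), categorical cross-entropy, continuous exponential
learning-rate decay of 0.96 per epoch, early stopping on validation
accuracy with patience 10, at most 50 epochs, checkpointing of the
best-validation-accuracy weights (restored before evaluation). The
decay rate and the single 64-unit dense head are free choices where the
training recipe leaves them open. Training is bit-deterministic given
its seed (weight init, batch shuffling and dropout masks all derive
from one generator). Both networks run on an in-package reverse-mode
automatic-differentiation engine over numpy; gradients flow to inputs
as well as weights, which the attribution estimator uses.

## Evaluation protocol

All partitioning is on subject identifiers. One outer group-shuffle
split holds out 20 % of subjects as a test set; five repeated
group-shuffle splits of the remaining subjects (validation fraction
0.2) provide the inner folds, reconciling "5-fold cross-validation"
with "repeated group-based splits". Training refuses subject overlap
between partitions. Metrics are epoch-level — accuracy, precision,
recall, per-class and macro F1, and ROC-AUC via the rank statistic
(ties half-counted) — reported as mean ± SD over the inner folds;
undefined ratios are reported as missing. Subject-level majority
voting is available as a secondary report.

## Attribution

Per-sample signed attributions of the MCI output probability are
estimated with expected gradients: for each explained sample, 12
background draws from the training fold (reference set capped at 300)
each define an interpolation path to the sample, integrated with 16
stratified midpoint gradient evaluations. The estimator approximately
satisfies completeness — attributions sum to f(x) minus the expected
background output — with a mean residual around 10⁻² on the validation
studies; each fold records per-sample baselines so the residual is
measurable. Aggregation follows the mean-|value| protocol: channel
importance averages over samples and features, feature importance over
samples and channels, both then averaged across folds with
across-fold SDs; band importance is the *sum* of each band's
connectivity-feature importances (sample-averaged before summation,
the reading adopted where sum-then-average and average-then-sum
diverge). Additivity does not survive aggregation — aggregated tables
are relative magnitudes, not model outputs.

## Synthetic cohorts

The generator emulates subject-structured, two-class, 20-channel
resting EEG: per-channel 1/f pink background plus stochastic
narrowband oscillations (band-pass filtered white noise) centred at
2, 6, 10, 20 and 35 Hz with alpha-dominant amplitudes, partially
driven by per-band common sources with signed per-channel couplings
(so shared activity survives average referencing, as dipole
topographies do). Two class contrasts are controllable:

- `complexity_effect` ∈ [0, 1]: AR(1) smoothing (pole at 0.6 × effect)
  of the affected channels in the MCI-like class, rescaled to preserve
  amplitude — lowering entropy, LZC and fractal dimension
  monotonically;
- `coherence_effect` ∈ [0, 1]: coupling of the affected channels to
  the common sources raised in delta (×(1+e)) and lowered in alpha
  (×(1−0.9e)) — the slow-wave-up / alpha-down coupling shift
  characteristic of cognitive decline.

Effects are modulated per subject by a log-normal factor (σ = 0.1), and
subject gains vary log-normally, so group-wise cross-validation faces
genuine between-subject variance. Each subject owns an RNG stream keyed
by (seed, class, subject index): cohorts are bit-reproducible and
stable under subject-count changes.

What the generator does **not** contain: biophysical source geometry,
eye-blink/EMG artifacts, non-stationary vigilance drifts, volume
conduction beyond the common-source construction, or realistic effect
sizes (no quantitative MCI effect sizes are available to calibrate
against). Passing the validation studies therefore demonstrates that
the pipeline recovers the *kind* of contrast it targets under
controlled conditions — not clinical performance on real recordings.

## Validation studies and problem sizes

Three studies (in `mcieeg.experiments`) exercise the package end to
end at sizes chosen to complete in minutes on one CPU:

1. **Structural contracts** — a 6-subject cohort through the full
   extraction: (epochs, 19, 77) with 300-sample epochs, 12 + 65
   features per channel.
2. **Closed forms** — DFA and Hurst on white noise (50 seeds),
   the logistic-map Lyapunov exponent, complete-graph metrics.
3. **Planted-signal recovery** — 40 subjects/class × 6 epochs, both
   effects at 0.8 on Fp1, T5 and O2 (the frontal/temporal/occipital
   trio reported as most informative for MCI), a 2-block/32-wide
   Transformer, one outer split with 2 inner folds, and 2 subject-level
   label permutations per fold as the chance reference. Checks: the
   held-out accuracy margin over the permutation null, whether the
   three manipulated channels occupy the top-3 attribution ranks, and
   whether the manipulated complexity family's mean per-feature
   importance exceeds the connectivity family's, each over three
   cohort seeds. Band importances are reported descriptively: the
   alpha band (whose coupling is most strongly manipulated)
   consistently ranks first, but the complexity manipulation alters
   coherence in every band, so a clean per-band recovery check is not
   identifiable in this design.

## Known limitations

- Graph metrics at the default coherence threshold 0.5 leave the
  binary topology empty in weakly coherent bands (beta/gamma on the
  synthetic cohorts); σ and assortativity are then flagged missing and
  imputed downstream. This mirrors a real degeneracy of absolute
  thresholding rather than hiding it.
- The K–S entropy spectrum and the correlation dimension are biased on
  300-sample epochs; they are used as relative descriptors.
- The numpy autodiff engine is single-threaded and eager; the default
  full-size Transformer trains orders of magnitude slower than a GPU
  framework would, which is why the validation studies use the reduced
  configuration.
- Expected-gradients completeness is approximate; the residual is
  reported, not assumed zero.
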