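# Methods

This note documents the models, algorithms and design choices behind
`pseudosorter`, the assumptions they rest on, and what the synthetic tests
do and do not demonstrate about real recordings.

## Signal model and preprocessing

A single-channel extracellular trace is modeled as spikes superimposed on
zero-mean background noise, sampled at 20 kHz. Preprocessing follows the
standard chain for somatic spikes:

- **Bandpass 300–3000 Hz**, 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`) so the filter adds no phase shift and spike times are
  preserved. The order is a conventional choice; only the band is part of
  the method's definition.
- **Robust noise estimate** σ_m = median(|x|)/0.6745 on the filtered trace.
  The denominator is median(|N(0,1)|), so σ_m is unbiased for pure Gaussian
  noise. On spike-laden traces at ~100 Hz aggregate firing, σ_m
  overestimates the pure-noise σ by a few tens of percent; this inflation is intrinsic to the estimator and is treated as
  part of the method (the detection threshold and SNR are both defined in
  σ_m units).
- **Threshold detection** at −5σ_m, negative-going crossings (extracellular
  somatic spikes are negative deflections; positive-going detection is
  available behind a flag). Events closer than the dead time to the
  previous accepted event are suppressed. The dead time defaults to
  20 samples (1.0 ms): longer than the discriminative waveform core,
  shorter than the 2 ms refractory period, and short enough that distinct
  spikes from different neurons 1–1.6 ms apart are not merged (at ~100 Hz
  aggregate firing, a 1.6 ms dead time measurably suppresses genuine
  spikes).
- **Extraction**: 64-sample windows, 20 samples before and 44 after the
  event. With trough alignment (the default), the trough is searched within
  16 samples of the crossing — a 5σ crossing precedes the trough by less
  than ~0.5 ms for spikes of FWHM ≤ 0.6 ms — and located as the argmin of a
  3-sample moving average, refined to the raw minimum among the smoothed
  minimum's direct neighbors. The smoothing stabilizes alignment on wide,
  flat troughs where single-sample noise would otherwise jitter the argmin
  by several samples.
- **Features**: per-spike min–max normalization to [0, 1] followed by the
  first difference divided by the sampling step (Δt = 50 µs), yielding 63
  gradient features. Flat (constant) waveforms produce all-zero feature
  rows and are flagged rather than dropped, keeping row indices stable.
  The normalized gradient is invariant to affine transforms of the
  waveform, so amplitude information is deliberately discarded; sorting
  rests on shape alone.

## Encoder and contrastive pretraining

The encoder is a fully connected network [63, 500, 500, 2000, 10] with ReLU
activations; a projection head (Dense → BatchNorm → ReLU → Dense →
BatchNorm without affine, width 10) sits on the bottleneck during
pretraining only. Two implementation details matter:

- **Input scaling.** Gradient features carry the 1/Δt scale (≈2×10⁴).
  The encoder stores a scaler fitted on the pretraining features:
  per-dimension centering plus one global standard deviation. Translation
  and isotropic scaling preserve the feature geometry — per-dimension
  standardization would instead equalize signal- and noise-dominated
  dimensions and demonstrably degrades clustering.
- **BatchNorm in the projection head.** An all-ReLU stack maps every input
  into the same activation orthant, so raw embeddings start with cosine
  similarities near 1; contrastive training from that state collapses to a
  single point (observed: loss → log N with all embeddings identical). The
  batch-mean subtraction inside the head removes this common direction.
  The head is only ever run on training batches, so no running statistics
  are kept.

Training follows the nearest-neighbor contrastive scheme: each batch is
augmented twice with Gaussian noise whose per-row standard deviation is
u·0.075·(row peak-to-peak range), u ~ U(0, 1); the positive for each
anchor is its nearest neighbor (cosine) in a FIFO memory queue of past
embeddings (queue size 8192, clipped to n, prefilled with initial-encoder
embeddings so the contrast set is constant from the first step); the
InfoNCE denominator runs over the batch's second views; the loss is
symmetrized over the two views, and gradients flow through the anchor view
only. Optimizer: Adam, learning rate 10⁻³, batch 256, 25 epochs by
default. With this formulation the epoch loss decreases over training (asserted
by the test suite on a two-class set). An earlier variant
with the whole queue in the denominator and the argmax-selected neighbor
as the positive starts at an artificially low loss and *rises* as clusters
form; it was replaced for that reason.

## Pseudolabeling

Density, sampling and clustering operate on the L2-normalized bottleneck
embeddings — the contrastive loss shapes the latent space on the unit
sphere, so Euclidean operations are applied in that geometry.

- **KNN density**: inverse mean distance to the K nearest neighbors,
  K = max(1, round(0.005·n)), self excluded, with an ε = 10⁻¹² guard for
  coincident points.
- **Densest sampling** takes the top ⌈fraction·n⌉ indices (ties broken by
  ascending index).
- **Weighted sampling** draws without replacement with weight
  exp(−λ·rank/n), rank 0 = densest. Rank-based weights are invariant to
  the density scale. λ defaults to 2 (≈7.4:1 densest-to-sparsest odds per
  draw): at λ = 5 the sample concentrates so strongly on the densest
  regions that classes with tighter latent clusters crowd out the rest of
  a balanced population, and K-means++ then fragments the
  over-represented class. The draw uses
  the exponential-race construction (keys Exp(1)/w_i, take the m
  smallest), which is equivalent to successive weighted draws without
  replacement and fully seeded.
- **Cluster count**: K-means++ inertia over k = 2…20 (3 restarts per k) on
  the densest 50 % of the latent space; the elbow is the point of maximum
  perpendicular distance to the chord joining the normalized curve's
  endpoints (Kneedle-style). The result is always clamped to [2, 20].
- **Pseudolabels**: K-means++ (10 restarts) on the sampled points only;
  if a class comes out empty the clustering is restarted with a shifted
  seed up to 5 times.

## Iterative fine-tuning

A zero-initialized linear head maps the bottleneck to k class scores
(zero initialization keeps early logits small, so the first updates do
not destroy pretrained features through large error signals).
Each iteration: compute densities, sample the scheduled fraction
(weighted by default), assign K-means++ pseudolabels, train the full
network (encoder + head) with cross-entropy on the pseudolabeled subset
(50 epochs, batch 128, augmentation level 0.1, Adam 10⁻³), then recompute
the latent space. Because each iteration re-clusters from scratch, class
ids are an arbitrary permutation; pseudolabels are renamed by a
maximum-agreement one-to-one (Hungarian) matching against the current
head's predictions before training — semantically neutral, but it stops
the head from relearning the naming every iteration. k is estimated once
after pretraining and held fixed (re-estimation per iteration available
behind a flag). Final labels are the head's argmax over the whole dataset;
pseudoclass identity is not tracked across iterations.

## Synthetic data generator

The generator emulates single-electrode benchmark recordings without a
compartmental simulator:

- **Templates**: sums of Gaussian lobes — an asymmetric negative trough
  (repolarization 1–2.5× slower than depolarization), a trailing positive
  lobe with widely varying latency and amplitude ratio, an optional
  positive pre-lobe and an optional slow after-hyperpolarization dip.
  Trough FWHM is stratified across neurons over 0.1–0.6 ms (the realistic
  span for cortical/hippocampal units), so a population always spans the
  width range. Templates are normalized to trough −1 at sample 20,
  matching the extraction window.
- **Spike trains**: homogeneous Poisson with an absolute refractory dead
  time of 2 ms per neuron, rates drawn uniformly from 15–35 Hz; the
  exponential rate is corrected so the mean rate equals the drawn rate
  despite the dead time. Overlaps across neurons are allowed and not
  resolved.
- **Amplitudes**: each neuron gets a normalized distance to the electrode,
  drawn uniformly from [0, 1]; SNR follows the inverse-distance law
  s(d) = s_hi/(1 + αd) with α = s_hi/s_lo − 1, mapping distance 0 → the
  top of the target range (default 12) and 1 → the bottom (default 4).
- **Raw traces** carry white Gaussian background noise (σ in µV), so the
  documented noise-estimate calibration holds on the raw trace; per-spike
  SNR is defined against σ_m of the *final bandpassed* trace (where
  detection operates), and insertion scales are solved by a short
  fixed-point iteration because σ_m itself depends on the inserted spikes.
  Ground-truth spike times are the troughs of the filtered spikes, located
  with the same estimator the detector uses.
- **Waveform datasets** (the detection-bypass path) add band-limited
  (300–3000 Hz) Gaussian noise: isolated-spike benchmark files are
  extracted from filtered recordings, and white noise would make the
  gradient representation unrealistically dominated by sample-to-sample
  noise.

What the generator does *not* reproduce: background-population activity
(thousands of distant neurons contributing non-Gaussian "biological"
noise), electrode drift, bursting and amplitude adaptation, overlapping
spike resolution, and multichannel geometry. Tests passing on this
generator demonstrate the pipeline's mechanics and calibration, not
performance on tissue data.

## Evaluation

Matched accuracy uses a maximum-weight one-to-one (Hungarian) assignment
between predicted and true classes on the confusion matrix; surplus classes
score zero. Many-to-one matching would inflate scores and is not used.
SNR of a detected spike is |trough|/σ_m, binned into [4, 6), [6, 8) and
[8, ∞) for noise-stratified reports; the class matching is established once
on the full dataset and then scored per bin. The classical reference sorter
is PCA (3 components) followed by a full-covariance Gaussian mixture.
Repeated evaluation runs a sorter five times with distinct seeds and
reports per-run and mean accuracy — the protocol used for all end-to-end
comparisons, because training-seed variance at reduced budgets is large.

## Unit quality metrics

FWHM is the time between the two half-amplitude crossings flanking the
trough, located by linear interpolation between samples; the baseline is
0 µV (bandpassed waveforms are zero-mean) and the peak amplitude is
measured trough-to-zero. Waveforms that never return to half amplitude on
one side get NaN rather than an error. Amplitude is reported as the signed
trough value in µV. The RPV rate is the fraction of spikes whose preceding
inter-spike interval is shorter than the 2 ms refractory period (one
violation per short interval); units with RPV rate ≥ 0.1 % are excluded
from aggregate analyses (strictly below threshold is kept). Pre/post
firing-rate change is (post − pre)/pre, undefined (NaN) for units silent
before treatment. For pre/post analyses the model trained on the combined
spikes is applied to both epochs, so a unit's identity is the classifier
class.

## Problem sizes and reduced budgets

The examples and end-to-end tests run at desk scale: datasets of 10⁴
spikes, 5 pretraining epochs and three fine-tuning iterations of 10 epochs
over fractions (0.05, 0.2, 0.4) — about 900 optimizer steps in total,
roughly 50× fewer than the full defaults on a 10⁵-spike dataset. At this
budget the contrastive latent has not caught up with the raw gradient
features (latent k-means ≈ 0.53 vs 0.66 directly on features on the
5-neuron example), so the classical PCA-GMM baseline is a strong
competitor and multi-seed mean accuracy of the full loop can fall below
it; with favorable training seeds the loop exceeds the baseline (up to
0.68). At the full default budget the latent improves monotonically
(k-means 0.41 → 0.60 from 0 to 25 epochs). Detection round-trip recall of
SNR ≥ 6 spikes within ±2 samples averages ≈ 0.93–0.96 over recordings:
spikes barely above SNR 6 face 5σ-threshold physics (per-spike crossing
probability ≈ 0.90), wide flat troughs add alignment jitter, and ~100 Hz
aggregate firing adds overlap losses. These are properties of the method's
stated operating point, not tunables.

## Numerical choices

Float32 weights and activations; float64 for losses, densities, metrics
and serialization. All randomness flows from integer seeds through
`numpy.random.Generator`; identical seeds give bit-identical results on a
given platform. Degenerate inputs are guarded explicitly: empty traces and
zero-norm embeddings raise, flat waveforms and undefined FWHM are flagged,
coincident latent points get an ε floor, empty K-means classes trigger
seeded restarts.
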