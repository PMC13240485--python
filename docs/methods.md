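# Methods

## Problem and model

The classifier assigns sinus-rhythm 12-lead ECG report images to one of
three classes: healthy control (0), concealed accessory pathway (1), and
AV-nodal reentry tachycardia (2). The architecture is a residual bottleneck
CNN whose blocks carry a channel-and-spatial parallel attention (CSPA)
operator.

Every attention operator in the package follows one contract —
extraction (pooled descriptors `E = e(X; w_e)`), transformation (factors
`T = t(E; w_t)` squashed by a sigmoid) and fusion (`X̄ = T ⊙ X`, here
always multiplicative). CSPA's two branches both read the *original* block
output:

* **Channel branch.** Global max pooling and global average pooling give
  two `C`-vectors; one shared 1D convolution of odd size `k` slides along
  the channel axis of each (zero padding `(k−1)/2` keeps length `C`); the
  responses are summed and squashed: `Wc = σ(C1D(GMP X) + C1D(GAP X))`.
  There is no bottleneck/dimensionality reduction.
* **Spatial branch.** Per-location max and mean over channels give two
  `H×W` planes; the 2-channel stack goes through *parallel* 1×1 and 3×3
  convolutions (2→1 channel each, "same" zero padding); their outputs are
  restacked and a final 7×7 convolution (2→1) plus sigmoid yields
  `Ws ∈ (0,1)^{H×W}`.
* **Fusion.** `out[h,w,c] = X[h,w,c]·Wc[c]·Ws[h,w]` — a single elementwise
  product (the factor order is immaterial), unlike CBAM's sequential
  channel-then-spatial refinement, which recomputes its spatial gate from
  the already-recalibrated map.

Design points the source description left open, resolved here as package
conventions:

* **Channel kernel size `k`.** Not fixed upstream; default "auto" sizes it
  from the channel count as the nearest odd integer ≥ 1 to
  `|log2(C)/γ + b/γ|` with `γ = 2, b = 1` (the efficient-channel-attention
  policy), ties resolved toward the smaller kernel. Overridable per config.
* **Shared vs. separate channel convolutions.** The channel formula writes
  one `C1D` operator for both pooled paths, so a single shared kernel is
  the default; a flag provides separate kernels.
* **Bias terms** in all attention convolutions are off by default, which
  makes the zero-weight analytic case exact (all factors 0.5) and matches
  common attention implementations.
* **Bracketing of the spatial formula.** Read per the prose order: the 7×7
  convolution consumes the re-stacked pair of 1×1-path and 3×3-path
  outputs, each path mapping the 2-channel pooled stack to 1 channel.
* **Final spatial convolution has one output channel**, since a spatial map
  must be single-channel to broadcast in the fusion product.

## Network

Stem: three convolutions with kernels 7×7, 5×5, 3×3 ("inverted triangle"),
each followed by batch normalization and ReLU. Widths default to
(32, 48, 64) with strides (2, 2, 2); neither is printed upstream, so they
are package conventions chosen to give a standard ×8 entry downsampling.
With the stem disabled (ablation arm) a single 7×7 convolution with the
same output width and the combined stride takes its place, keeping all
downstream shapes unchanged.

Six bottleneck blocks: 1×1 reduce → 3×3 (stride 1 or 2) → 1×1 expand, each
convolution with batch norm, ReLU after the first two; the attention
operator applies to the expanded main path *before* the residual addition;
identity shortcut when shapes match, 1×1-projection (with batch norm)
otherwise; ReLU after the addition. Default output widths
(256, 256, 512, 512, 1024, 1024) with mid = out/4 (expansion 4) and stride
2 at the first block of each two-block stage — consistent with a 22-layer
count (3 stem + 18 block + 1 head) and standard residual staging, declared
as a convention rather than a claim about the original model. The head is
global average pooling plus one dense layer (resolution-robust and
parameter-lean; the original head is undescribed). Argmax ties resolve to
the lowest class index. Inputs are single-channel (grayscale printouts);
a 3-channel mode exists for color scans.

The **desk preset** divides all widths by 4 and uses a 256×128 input; it
exists so that training, ablation and the test suite run in minutes on one
CPU. Its training preset uses Adam at 1e-3 (the customary Adam default,
appropriate for a small network on a 20-epoch schedule); the full-scale
protocol defaults remain batch 8, Adam 1e-4, cosine annealing
`lr(t) = lr_min + (lr_max − lr_min)(1 + cos(πt/T))/2` with `lr_min = 0`,
updated once per epoch, 100 epochs, natural-log cross-entropy. Adam moment
parameters are library defaults (0.9, 0.999, eps 1e-8) and are recorded in
every run record. No augmentation, weight decay or early stopping. The
test split is evaluated after every epoch; the final epoch is the headline
number (a declared convention — the original model-selection policy is
unstated).

Everything runs on a small reverse-mode autodiff engine written for this
package (im2col + GEMM convolutions, batch normalization with running
statistics, fused softmax cross-entropy). Single-threaded runs are
bitwise reproducible given the seeds; gradient correctness is enforced by
central-difference checks and a scipy cross-correlation oracle in the test
suite.

## Metrics

Rows of the confusion matrix are true classes, columns predictions (a
declared orientation). Accuracy is the trace over the total. Sensitivity,
specificity and precision are macro-averaged: the unweighted mean over the
three one-vs-rest ratios `TP/(TP+FN)`, `TN/(TN+FP)`, `TP/(TP+FP)`. A class
with a zero denominator (no true or no predicted members) is excluded from
the macro mean with a warning by default ("count-as-zero" is available);
the original data never encounters this case, and exclusion avoids silently
penalizing empty classes. Cross-entropy uses the natural logarithm with the
true-class probability clamped at 1e-12 (warning, not an exception). ROC is
one-vs-rest over a class's probability column with trapezoidal AUC, which
equals the tie-corrected Mann–Whitney ranking probability; the macro AUC is
the unweighted three-class mean, matching the macro convention of the other
metrics.

## Synthetic data: what it emulates and what it does not

Each record is 12 leads × 5000 samples (10 s at 500 Hz). A beat is a sum of
Gaussian bumps (P, Q, R, S, T) placed on an exactly regular R-R lattice;
"width" means the full width at 5 % of bump amplitude
(σ = width / (2√(2 ln 20))), so wave onsets are recoverable by a 5 %
threshold crossing and the PR interval (P onset to QRS onset) equals the
configured value by construction. One fixed per-lead amplitude factor
(negative for aVR) projects the template to the 12 leads. Baseline wander
is a low-frequency sinusoid with random frequency and phase; white noise is
added per lead. Per-patient parameters are drawn once per patient and
shared across that patient's recordings; values are clipped to
physiological ranges with a warning.

Class structure enters as parameter offsets: CAP shifts the PR interval by
−12 ms and widens the P wave by +8 ms; AVNRT scales P amplitude by 0.8 and
slows the heart rate by 3 bpm (the heart-rate direction mirrors the
reported resting-rate difference between AVNRT patients and controls).
The per-patient standard deviations (heart rate 1.0 bpm, PR 2.5 ms,
P amplitude 0.010 mV, P width 2.5 ms) are deliberately narrow — several
times narrower than real population spreads — so that the class offsets are
a 3–5 σ signal. This is a design requirement, not a fit to data: after
rendering at 1600×800 and bilinear downscaling to the 256×128 desk input, a
12 ms PR shift spans well under one pixel and survives only through
anti-aliased gray levels; with clinically realistic spreads the desk-scale
task is unlearnable outright. The generator therefore makes **no claim of
reproducing CAP/AVNRT electrophysiology** (real concealed pathways are, by
definition, invisible in sinus rhythm); it exists to verify that the
pipeline can extract a subtle, known signal end to end. Passing tests
demonstrate mechanism correctness and trainability, not clinical
performance.

Rendering uses the standard 4-column × 3-row report layout (columns are
consecutive 2.5-s windows, column-major lead order), white background,
dark traces drawn by per-pixel-column min/max filling with bridged
adjacent columns, fixed gain 100 px/mV, stroke thickness 3 px, optional
light grid (off by default — the published preprocessing crops to "relevant
waveform segments", and a grid adds nuisance structure without aiding the
tested properties). Rendering is deterministic given record and config.

Preprocessing crops to the bounding box of non-background pixels
(threshold 0.95 on a unit white scale), expands it by a 2 % margin, and
rescales by separable bilinear interpolation with **half-pixel-center
alignment** (stated so the 2×2 → 4×4 closed-form test case is well
defined); aspect ratio is not preserved (the protocol forces a fixed input
resolution). With a zero margin the operation is idempotent; the default
2 % margin trades exact idempotence for a small whitespace buffer.

Splitting is by patient, stratified by class: patients are shuffled with a
seeded generator and the train side receives round(0.7 · n) patients per
class; all of a patient's records follow the patient. A patient appearing
in two classes is an error.

## Problem sizes and numerical choices

The default synthetic study is 100 patients per class, one recording each
(300 images, 210/90 split) — large enough for the quarter-width model to
reach ≥ 0.9 test accuracy in 20 epochs, small enough to train in about a
minute on one CPU. The ablation-trend check in the test suite uses a
shortened 10-epoch schedule, identical across arms, since it compares arms
rather than absolute performance. Weights are float32; He-style uniform
initialization (a "zeros" scheme exists for analytic tests); max-pool
gradients split equally among ties; batch-norm eps 1e-5, momentum 0.1.
Attention factors are strictly inside (0, 1) mathematically; in floating
point, extreme pre-activations can round the sigmoid to 0 or 1, so the
range property is asserted at initialization-scale weights.

## Known limitations

* The waveform model is far simpler than real electrophysiology: no beat-
  to-beat variability, no lead-specific morphology beyond a scalar gain, no
  pathology other than the injected parameter offsets.
* The desk preset's accuracy says nothing about clinical data; the original
  headline numbers come from GPU-scale training on a private single-center
  cohort and are not reproducible here.
* Training is single-process CPU; no mixed precision, no multi-device.
* CA and SK attention baselines are not implemented (registry extension
  points exist); the nine classical CNN baselines of the original
  comparison are out of scope.
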