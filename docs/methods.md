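# Methods

This note documents the models, defaults, and numerical choices behind
`motionsentry` — what the pipeline computes, why its parameters are set the
way they are, and what the synthetic test substrate does and does not show.

## Data model

A motion record is a uniformly sampled tensor `X ∈ R^{T×J×D}` of joint
positions (meters) with strictly increasing times at a fixed Δt. The default
frame rate for the simulator and all window arithmetic is 25 Hz (Δt = 40 ms),
so a 2 s reference window is 50 frames. Kinematics use backward finite
differences, `v_t = (x_t − x_{t−1})/Δt`, iterated for acceleration and jerk;
the leading frame of each derivative order is undefined and zero-filled so
all tensors keep length T. This keeps downstream shapes uniform at the cost
of a transient at t = 0, which never enters the baseline statistics in
practice because the reference window mean absorbs it.

The skeleton is an undirected anatomical graph. Its operator is the
symmetric degree-normalized adjacency `Â = D^{−1/2} A D^{−1/2}`. By default
normalization is applied to `A + I` (the renormalization that keeps a node's
own features in every aggregation and leaves all degrees positive); the
bare form without self-loops is available by flag and is used in the oracle
tests. Joint masses are never observable from motion data, so the default is
a uniform split of a 70 kg body over the joints, overridable per joint in
the skeleton JSON (anthropometric tables can be supplied by the user).

Per-joint mechanical energy is `E_t^j = ½ m_j ‖v_t^j‖² + m_j g h_t^j` with
g = 9.81 m/s². Heights are referenced so the lowest vertical coordinate
over the leading baseline window sits at 0 — this guarantees nonnegative
energy during normal motion while remaining per-sequence; a fixed ground
plane can be pinned instead. The vertical axis defaults to the last
coordinate and is configurable, since capture conventions vary.

## Anomaly scoring

Two reference quantities are computed and both are reported:

* **Window baseline** — the per-joint mean energy over a short reference
  window of normal motion (default 50 frames ≈ 2 s). The anomaly score is
  the absolute deviation `S_t^j = |E_t^j − baseline_j|`; it localizes
  *where and when* energy departs from the subject's own recent behavior.
* **Population statistics** — per-joint mean μ_E and standard deviation σ_E
  estimated from a corpus of normal motion, giving the z-score
  `z = (E − μ_E)/σ_E`. This is the calibrated signal: under a Gaussian
  assumption the two-sided mass inside |z| ≤ 2.5 is 98.76%, i.e. 98.8% to
  one decimal, so flagging |z| ≥ 2.5 (inclusive) has a ~1.2% false-positive
  rate per cell. σ_E is floored at 10⁻⁶ J: a corpus whose energies are
  constant below that scale is degenerate and rejected rather than divided
  by.

z statistics are per joint by default (pooling across joints is a config
option); per-joint calibration matters because distal joints move far more
than the trunk in normal gait. Flagged cells are reported sorted by |z|
descending, ties broken by (frame, joint) ascending. No multiple-testing
correction is applied across the T×J cells; users comparing flag counts
across conditions should account for that.

The confidence weight `β = sigmoid(z)` maps deviations into (0, 1), 0.5 at
typical behavior, and rescales fused features joint-wise. Literally applied,
a perfectly typical joint is scaled by 0.5; downstream linear layers absorb
this constant, and a `neutral_rescale` flag (2β, identity at z = 0) is
available when the refinement is used standalone.

## Encoders

**Graph convolution** stacks `H^{(l+1)} = σ(Â H^{(l)} W^{(l)})` (default two
layers, ReLU) applied frame-wise. **Spatial attention** restricts the
softmax of the bilinear scores `φ(F_i)ᵀψ(F_j)` to the neighborhood
N_i = {graph neighbors of i} ∪ {i}; including the node itself is required so
a joint can retain its own features, and makes empty neighborhoods
impossible. Logits are unscaled (temperature 1 by default). Exactly zero
feature vectors give uniform weights — the smooth limit of equal logits —
so no tie-breaking is needed.

**Temporal attention** is single-head scaled dot-product attention
`A = softmax(QKᵀ/√d′)`, `Z = AV` over the per-frame embeddings, which are
the joint-mean of the graph-encoder output (mean pooling is the neutral
collapse of J node vectors to one frame vector). Sinusoidal positional
encodings (base 10⁴) are added first. d′ defaults to 64. The optional
feed-forward refinement block is behind a flag and off by default. Two
representation losses operate on Z as produced: the frame-to-frame
smoothness penalty Σ‖Z_t − Z_{t+1}‖² and the lag-k cosine contrastive term
Σ(1 − cos(Z_t, Z_{t+k})) (default k = 5 ≈ 0.2 s). The cosine is undefined
for zero-norm rows: the strict path rejects them naming the frame, the
training path may regularize norms with a small ε.

## Adaptive fusion

Vision (T×J×3 positions), IMU (T×J×3 accelerations, mapped onto joints),
and plantar pressure (T×J×1 vertical-force proxy, broadcast to joints by
body side via the skeleton's sensor map) are projected into a shared d_s = 16
space. Per frame, each modality's joint-mean embedding is scored by
`s_i = w_sᵀ tanh(W_s x̃_i + b_s)` and the softmax weights mix the
joint-resolved embeddings. The equations are written per frame with shared
parameters — the only reading consistent with time-indexed scores — so
fusion is applied independently at each frame.

Score conditioning on a temporal-context vector (trailing mean of the last
W_c = 10 fused frame vectors, zero-initialized — the simplest causal summary
with no hidden state) is implemented and tested but off by default: the
context-free scoring factorizes over frames and vectorizes, and on the
synthetic corpus the conditioning did not change the learned behavior. A
missing modality is an explicit absence in the bundle; its score is simply
excluded, which renormalizes the softmax over the present modalities. The
fixed-coefficient mix Σλ_i X^(i) is kept as a baseline; the adaptive path is
the default.

## Classifier and losses

The refined, encoded sequence Z is concatenated per frame with the J-vector
of anomaly scores — divided by the per-joint σ_E so the concatenated block
is dimensionless and commensurate with the learned features — and passed
through a two-layer perceptron with sigmoid output, giving per-frame injury
probabilities P_t. The sequence probability is the temporal mean (not max),
thresholded at 0.5; mean pooling matches the smoothing intent of the
consistency losses.

The objective is
`L = L_cls + λ₁·Σ(P_t − P_{t+1})² + λ₂·Σ|P_t − P_{t−1}| + λ₃·Σ(P_t − P_{t+k})²`
with defaults λ₁ = 0.2, λ₂ = 0.05, λ₃ = 0.05, k = 5 — small enough that
classification dominates, large enough that the consistency terms measurably
reduce prediction jitter (verified in the acceptance suite). The weighted
consistency variant multiplies each term by `α_t = 1 + γ|P_t − P_{t+1}|`
(γ = 1 default), reducing exactly to the unweighted form at γ = 0. An
energy-deviation regularizer `λ·ΣS_t^j` can be added to the classification
term (λ = 0 by default: on synthetic data the S-sum is label-correlated but
parameter-independent, so it shifts the loss without shaping gradients).
A static baseline detector — `sigmoid(Σ_j w_j‖A_j‖)` with ‖A_j‖ the
time-mean acceleration norm of joint j — is provided for comparison.

All learnable blocks run on an in-package reverse-mode autodiff core over
numpy arrays (dense float64, scalar-terminal backward, numpy broadcasting
semantics with gradients summed back to operand shapes). Training uses Adam
(lr 10⁻³, halved after 3 epochs without validation improvement), global
gradient-norm clipping at 10, batch size 16 (the reference batch of 128
scaled to desk-size corpora), 30 epochs, a stratified 75/25 split, and
Glorot-uniform initialization — every stochastic step drawn from a single
seeded generator, so identical seed and config reproduce training logs
byte for byte.

## Synthetic study conditions

The generator emulates treadmill walking: per-joint rest pose plus a 1 Hz
forward swing (amplitude 2–15 cm, distal joints largest, left/right in
phase opposition) plus a 3 cm second-harmonic vertical bob, with 5 mm iid
Gaussian capture noise — typical of marker-less pose estimation. An injury
is a raised-cosine vertical displacement excursion at one joint whose peak
velocity is the injury magnitude (default 2.5 m/s over 8 frames ≈ 0.32 s,
an impact-scale transient); the raised cosine returns smoothly to zero, so
it excites the energy signal through both kinetic and potential terms
without the spectral leakage a step discontinuity would inject into the
smoothness losses. Sensors add modality-specific degradations: vision noise
and occlusion dropouts (held poses, mask recorded), IMU noise and a linear
bias drift, pressure noise and box smoothing. Corpora (default n = 200,
injury rate 0.5) derive every sequence's seed from one corpus seed via
`SeedSequence.spawn`.

What passing tests show: the energy/z-score mechanism recovers exactly the
kind of transient the generator injects, and the learned pipeline separates
such sequences from normal gait. What they do not show: performance on real
capture data — the generator has no biomechanically validated dynamics
(no OpenSim-class model), no inter-subject variability, no soft-tissue or
marker artifacts, and its injuries are idealized single-joint events.
Statistical structure, not physiological fidelity, is the target.

## Numerical choices and limitations

* Softmax is shift-stabilized everywhere; neighborhood masking adds −10³⁰
  to excluded logits rather than slicing, keeping shapes static.
* Non-finite attention inputs and non-uniform sampling are rejected with
  diagnostics naming the offending frame.
* Missing samples at ingestion: interior gaps ≤ 5 frames are linearly
  interpolated; longer or boundary gaps reject the sequence.
* Positions are assumed to be in meters throughout; no unit inference is
  attempted.
* Problem sizes in the test and acceptance suites (n = 200, T = 50, J = 15;
  smaller corpora for the multi-run comparisons) are the package's desk-scale
  study conditions; the library itself has no hard size limits.
* The learned weights of the static baseline detector are never trained by
  the main pipeline; the component exists as a reference point.
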