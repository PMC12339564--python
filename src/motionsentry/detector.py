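"""Injury classification: model head, loss family, training, evaluation.

The full pipeline per sequence:

    sensors --adaptive fusion--> fused joint features
            --confidence refinement (beta from energy z-scores)-->
            --graph convolution + spatial attention--> per-frame embeddings
            --positional encoding + temporal attention--> Z (T x d')
            --concat normalized anomaly scores--> classifier head --> P_t

The training objective combines sequence-level cross-entropy with the
temporal-consistency family: a squared frame-to-frame consistency term
(optionally deviation-weighted), an l1 smoothing term, and a lag-k
regularizer, each with its own weight. An optional energy-deviation
regularizer adds lambda * sum S_t^j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, recall_score, roc_auc_score

from . import _ops as am
from . import autodiff as ad
from . import biomech
from .fusion import FusionParams, ModalityBundle, fuse_sequence
from .graph_encoder import (
    GCNStack,
    SpatialAttentionParams,
    gcn_forward,
    glorot_uniform,
    spatial_attention,
)
from .motion import MotionSequence, SkeletonGraph, compute_kinematics, total_energy
from .synthetic import LabeledCorpus
from .temporal_attention import (
    TemporalAttentionParams,
    add_positional_encoding,
    temporal_attention,
)

_EPS = 1e-12


# --------------------------------------------------------------------- types
@dataclass
class Predictions:
    """Per-frame injury probabilities and the pooled sequence decision."""

    frame_probs: np.ndarray  # (T,) in [0, 1]
    threshold: float = 0.5

    @property
    def sequence_prob(self) -> float:
        return float(np.mean(self.frame_probs))

    @property
    def label(self) -> int:
        return int(self.sequence_prob >= self.threshold)


@dataclass
class LossWeights:
    """Weights of the composite objective; all nonnegative.

    ``lambda_energy`` scales the summed anomaly scores; ``lambda1..3`` weight
    the consistency, smoothing, and lag-k regularization terms; ``gap_k`` is
    the lag of the regularizer; ``gamma`` the slope of the dynamic weighting
    factor alpha_t = 1 + gamma * |P_t - P_{t+1}| (gamma = 0 recovers the
    unweighted consistency loss).
    """

    lambda_energy: float = 0.0
    lambda1: float = 0.2
    lambda2: float = 0.05
    lambda3: float = 0.05
    gap_k: int = 5
    gamma: float = 1.0
    weighted: bool = False

    def __post_init__(self):
        for name in ("lambda_energy", "lambda1", "lambda2", "lambda3", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.gap_k < 1:
            raise ValueError("gap_k must be >= 1")


@dataclass
class DetectorConfig:
    """Model sizes, thresholds, and optimization settings."""

    shared_dim: int = 16
    gcn_dims: tuple = (16, 16)
    gcn_activation: str = "relu"
    spatial_attn_dim: int = 8
    temporal_dim: int = 64
    head_hidden: int = 32
    context_window: int = 10
    use_context: bool = False  # temporal-context conditioning of fusion scores
    include_jerk: bool = False
    z_threshold: float = biomech.Z_THRESHOLD
    decision_threshold: float = 0.5
    neutral_rescale: bool = False
    loss_weights: LossWeights = field(default_factory=LossWeights)
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 16
    clip_norm: float = 10.0
    val_fraction: float = 0.25
    lr_patience: int = 3  # epochs of stalled validation loss before halving


# ------------------------------------------------------------------- head
@dataclass
class ClassifierHead:
    """Two-layer perceptron with sigmoid output, applied per frame."""

    W1: "np.ndarray"  # (F_in, hidden)
    b1: "np.ndarray"
    w2: "np.ndarray"  # (hidden,)
    b2: "np.ndarray"  # scalar

    @classmethod
    def init(cls, n_in: int, hidden: int, rng: np.random.Generator):
        return cls(
            W1=glorot_uniform(rng, n_in, hidden),
            b1=np.zeros(hidden),
            w2=glorot_uniform(rng, hidden, 1)[:, 0],
            b2=np.zeros(1),
        )


def classify(features, scores, head: ClassifierHead, threshold: float = 0.5):
    """Per-frame injury probability from [features_t, scores_t].

    ``features`` is (T, d), ``scores`` (T, J) anomaly scores to concatenate.
    Returns the per-frame probabilities (numpy or Tensor); wrap in
    :class:`Predictions` for the pooled decision.
    """
    if am.asdata(features).shape[0] != am.asdata(scores).shape[0]:
        raise ValueError("features and anomaly scores disagree on frame count")
    u = am.concatenate([features, scores], axis=1)
    hidden = am.relu(u @ head.W1 + head.b1)
    logits = hidden @ head.w2 + head.b2
    return am.sigmoid(logits)


def baseline_threshold_detector(acceleration: np.ndarray, weights: np.ndarray) -> float:
    """Static threshold baseline: sigmoid(sum_j w_j ||A_j||).

    ``||A_j||`` is the time-mean of per-frame acceleration norms of joint j.
    """
    acceleration = np.asarray(acceleration, dtype=float)
    if acceleration.ndim != 3:
        raise ValueError("expected a T x J x D acceleration tensor")
    norms = np.linalg.norm(acceleration, axis=2).mean(axis=0)  # (J,)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != norms.shape:
        raise ValueError("one weight per joint required")
    return float(am.sigmoid(float(weights @ norms)))


# ------------------------------------------------------------------- losses
def cross_entropy(p, y):
    """Binary cross-entropy of a single pooled probability against y in {0,1}."""
    return -(y * am.log(p + _EPS) + (1.0 - y) * am.log(1.0 - p + _EPS))


def loss_regularized(p, y, anomaly_scores, lam: float):
    """Cross-entropy + lambda * sum_{j,t} S_t^j (energy-deviation regularizer)."""
    return cross_entropy(p, y) + lam * float(np.sum(anomaly_scores))


def consistency_loss(P):
    """sum_t (P_t - P_{t+1})^2 — penalizes abrupt prediction changes."""
    if am.asdata(P).shape[0] < 2:
        return 0.0
    d = P[1:] - P[:-1]
    return am.summation(d * d)


def weighted_consistency_loss(P, gamma: float):
    """Consistency loss with dynamic weights alpha_t = 1 + gamma |P_t - P_{t+1}|."""
    if am.asdata(P).shape[0] < 2:
        return 0.0
    d = P[1:] - P[:-1]
    return am.summation((1.0 + gamma * am.absolute(d)) * d * d)


def smoothing_loss(P):
    """sum_t |P_t - P_{t-1}| (l1) — a monotone ramp 0 -> 1 costs exactly 1."""
    if am.asdata(P).shape[0] < 2:
        return 0.0
    return am.summation(am.absolute(P[1:] - P[:-1]))


def temporal_reg_loss(P, k: int):
    """sum_{t} (P_t - P_{t+k})^2 — lag-k consistency; empty sum is 0."""
    T = am.asdata(P).shape[0]
    if k >= T:
        warnings.warn(f"lag k={k} >= T={T}: temporal regularizer is an empty sum")
        return 0.0
    d = P[:-k] - P[k:]
    return am.summation(d * d)


def total_loss(P, y, weights: LossWeights, anomaly_scores=None):
    """Composite objective and its per-term breakdown.

    L = L_cls + lambda1 L_consistency + lambda2 L_smoothing + lambda3 L_reg,
    where L_cls is cross-entropy optionally augmented by the energy
    regularizer lambda_energy * sum S.
    """
    p_seq = am.mean(P)
    cls = cross_entropy(p_seq, y)
    if weights.lambda_energy > 0 and anomaly_scores is not None:
        cls = cls + weights.lambda_energy * float(np.sum(anomaly_scores))
    cons = (
        weighted_consistency_loss(P, weights.gamma)
        if weights.weighted
        else consistency_loss(P)
    )
    smooth = smoothing_loss(P)
    reg = temporal_reg_loss(P, weights.gap_k)
    total = cls + weights.lambda1 * cons + weights.lambda2 * smooth + weights.lambda3 * reg
    breakdown = {
        "classification": am.item(cls),
        "consistency": am.item(cons),
        "smoothing": am.item(smooth),
        "temporal_reg": am.item(reg),
        "total": am.item(total),
    }
    return total, breakdown


# -------------------------------------------------------------------- model
class DetectorModel:
    """All learnable parameters of the detection pipeline."""

    def __init__(
        self,
        config: DetectorConfig,
        channel_dims: dict[str, int],
        n_joints: int,
        rng: np.random.Generator,
    ):
        self.config = config
        c = config
        fusion_np = FusionParams.init(
            channel_dims,
            c.shared_dim,
            rng,
            context_window=c.context_window,
            use_context=c.use_context,
        )
        self.fusion = FusionParams(
            projections={
                m: (ad.Tensor(W, requires_grad=True), ad.Tensor(b, requires_grad=True))
                for m, (W, b) in fusion_np.projections.items()
            },
            w_score=ad.Tensor(fusion_np.w_score, requires_grad=True),
            W_score=ad.Tensor(fusion_np.W_score, requires_grad=True),
            b_score=ad.Tensor(fusion_np.b_score, requires_grad=True),
            context_window=c.context_window,
            use_context=c.use_context,
        )
        dims = (c.shared_dim,) + tuple(c.gcn_dims)
        self.gcn = GCNStack(
            weights=[
                ad.Tensor(glorot_uniform(rng, a, b), requires_grad=True)
                for a, b in zip(dims[:-1], dims[1:])
            ],
            activation=c.gcn_activation,
        )
        f_out = dims[-1]
        self.spatial = SpatialAttentionParams(
            phi=ad.Tensor(glorot_uniform(rng, f_out, c.spatial_attn_dim), requires_grad=True),
            psi=ad.Tensor(glorot_uniform(rng, f_out, c.spatial_attn_dim), requires_grad=True),
        )
        self.temporal = TemporalAttentionParams(
            w_q=ad.Tensor(glorot_uniform(rng, f_out, c.temporal_dim), requires_grad=True),
            w_k=ad.Tensor(glorot_uniform(rng, f_out, c.temporal_dim), requires_grad=True),
            w_v=ad.Tensor(glorot_uniform(rng, f_out, c.temporal_dim), requires_grad=True),
        )
        head_np = ClassifierHead.init(c.temporal_dim + n_joints, c.head_hidden, rng)
        self.head = ClassifierHead(
            W1=ad.Tensor(head_np.W1, requires_grad=True),
            b1=ad.Tensor(head_np.b1, requires_grad=True),
            w2=ad.Tensor(head_np.w2, requires_grad=True),
            b2=ad.Tensor(head_np.b2, requires_grad=True),
        )

    def parameters(self) -> list[ad.Tensor]:
        ps: list[ad.Tensor] = []
        for W, b in self.fusion.projections.values():
            ps += [W, b]
        ps += [self.fusion.w_score, self.fusion.W_score, self.fusion.b_score]
        ps += list(self.gcn.weights)
        ps += [self.spatial.phi, self.spatial.psi]
        ps += [self.temporal.w_q, self.temporal.w_k, self.temporal.w_v]
        ps += [self.head.W1, self.head.b1, self.head.w2, self.head.b2]
        return ps

    def forward(self, sample: dict):
        """Frame probabilities for one preprocessed sample.

        ``sample`` carries numpy arrays: modality ``bundle``, the (T, J)
        confidence map ``beta``, normalized anomaly scores ``s_norm``, and
        the skeleton's normalized adjacency / neighborhood mask via ``graph``.
        Returns ``(P, alpha)``: the (T,) probabilities and the (T, M)
        modality attention weights.
        """
        x_fused, alpha = fuse_sequence(sample["bundle"], self.fusion)
        x_ref = biomech.refine_features(
            x_fused, sample["beta"], neutral_rescale=self.config.neutral_rescale
        )
        H = gcn_forward(x_ref, sample["graph"].normalized_adjacency, self.gcn)
        _, H_attn = spatial_attention(H, sample["graph"], self.spatial)
        pooled = am.mean(H_attn, axis=1)  # (T, F)
        x_pe = add_positional_encoding(pooled)
        _, Z = temporal_attention(x_pe, self.temporal)
        P = classify(Z, sample["s_norm"], self.head, self.config.decision_threshold)
        return P, alpha

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = a.copy()


@dataclass
class FittedDetector:
    """A trained model with its preprocessing statistics and training log."""

    model: DetectorModel
    stats: biomech.BaselineStats
    skeleton: SkeletonGraph
    config: DetectorConfig
    log: dict


# ------------------------------------------------------------ preprocessing
def preprocess_sample(
    seq: MotionSequence,
    bundle: ModalityBundle,
    graph: SkeletonGraph,
    stats: biomech.BaselineStats,
    config: DetectorConfig,
) -> dict:
    """Numpy-side features that do not depend on learnable parameters."""
    kin = compute_kinematics(seq)
    profile = total_energy(kin, seq, graph)
    window = (0, min(seq.n_frames, biomech.DEFAULT_WINDOW))
    base = biomech.expected_energy(profile, window)
    S = biomech.anomaly_score(profile, base)
    z = biomech.zscore(profile, stats)
    beta = biomech.confidence_weight(z)
    s_norm = S / np.maximum(np.broadcast_to(stats.sigma, S.shape[1:]), 1e-9)
    return {
        "bundle": bundle,
        "graph": graph,
        "beta": beta,
        "s_norm": s_norm,
        "z": z,
        "S": S,
        "energy": profile,
    }


def stratified_split(labels: np.ndarray, val_fraction: float, rng) -> tuple:
    """Seeded stratified train/validation index split."""
    labels = np.asarray(labels)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx += idx[:n_val].tolist()
        train_idx += idx[n_val:].tolist()
    return sorted(train_idx), sorted(val_idx)


class Adam:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, clip=10.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps, self.clip = beta1, beta2, eps, clip
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.data)
            for p in self.params
        ]
        norm = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
        if self.clip and norm > self.clip:
            grads = [g * (self.clip / norm) for g in grads]
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# ------------------------------------------------------------------- train
def train(
    corpus: LabeledCorpus, config: DetectorConfig | None = None, seed: int = 0
) -> FittedDetector:
    """Fit the detector on a labeled corpus; deterministic for a fixed seed.

    Stratified 75/25 split, Adam with the configured learning rate, global
    gradient clipping, and learning-rate halving after ``lr_patience``
    epochs without validation improvement. The returned log records the
    per-epoch mean loss breakdown on both splits.
    """
    config = config or DetectorConfig()
    rng = np.random.default_rng(seed)
    labels = np.asarray(corpus.labels)
    train_idx, val_idx = stratified_split(labels, config.val_fraction, rng)

    normal_profiles = []
    for i in train_idx:
        if labels[i] == 0:
            kin = compute_kinematics(corpus.sequences[i])
            normal_profiles.append(
                total_energy(kin, corpus.sequences[i], corpus.skeleton)
            )
    if not normal_profiles:
        raise ValueError("training split contains no normal sequences")
    T = corpus.sequences[0].n_frames
    stats = biomech.fit_baseline_stats(
        normal_profiles, window=(0, min(T, biomech.DEFAULT_WINDOW))
    )

    samples = [
        preprocess_sample(s, b, corpus.skeleton, stats, config)
        for s, b in zip(corpus.sequences, corpus.bundles)
    ]
    channel_dims = {
        m: corpus.bundles[0].features[m].shape[2] for m in corpus.bundles[0].names
    }
    model = DetectorModel(config, channel_dims, corpus.skeleton.n_joints, rng)
    opt = Adam(
        model.parameters(), lr=config.learning_rate, clip=config.clip_norm
    )

    log: dict = {"epochs": [], "config": {"seed": seed}}
    best_val = np.inf
    stall = 0
    for epoch in range(config.epochs):
        order = np.array(train_idx)[rng.permutation(len(train_idx))]
        epoch_terms: list[dict] = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            batch_terms = []
            for i in batch:
                P, _ = model.forward(samples[i])
                loss, terms = total_loss(
                    P,
                    float(labels[i]),
                    config.loss_weights,
                    anomaly_scores=samples[i]["S"],
                )
                if not np.isfinite(am.item(loss)):
                    raise RuntimeError(
                        f"non-finite loss in batch starting at index {start} "
                        f"(sequence {i})"
                    )
                (loss * (1.0 / len(batch))).backward()
                batch_terms.append(terms)
            opt.step()
            epoch_terms += batch_terms

        val_terms = []
        for i in val_idx:
            P, _ = model.forward(samples[i])
            _, terms = total_loss(
                P, float(labels[i]), config.loss_weights, samples[i]["S"]
            )
            val_terms.append(terms)
        mean_terms = lambda ts: {
            k: float(np.mean([t[k] for t in ts])) for k in ts[0]
        }
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "train": mean_terms(epoch_terms),
            "val": mean_terms(val_terms),
        }
        log["epochs"].append(entry)
        val_loss = entry["val"]["total"]
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.lr_patience:
                opt.lr *= 0.5
                stall = 0
    log["train_indices"] = list(map(int, train_idx))
    log["val_indices"] = list(map(int, val_idx))
    return FittedDetector(
        model=model, stats=stats, skeleton=corpus.skeleton, config=config, log=log
    )


def predict(
    fitted: FittedDetector,
    sequences: list[MotionSequence],
    bundles: list[ModalityBundle],
) -> list[Predictions]:
    out = []
    for seq, bundle in zip(sequences, bundles):
        sample = preprocess_sample(
            seq, bundle, fitted.skeleton, fitted.stats, fitted.config
        )
        P, _ = fitted.model.forward(sample)
        out.append(
            Predictions(
                frame_probs=am.asdata(P).copy(),
                threshold=fitted.config.decision_threshold,
            )
        )
    return out


def evaluate(scores, labels, threshold: float = 0.5) -> dict:
    """Standard binary metrics from sequence scores and true labels.

    ``scores`` may be probabilities (thresholded for the label metrics) and
    are used directly for the rank-based AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    preds = (scores >= threshold).astype(int)
    metrics = {
        "accuracy": float(accuracy_score(labels, preds)),
        "recall": float(recall_score(labels, preds, zero_division=0)),
        "f1": float(f1_score(labels, preds, zero_division=0)),
    }
    if len(np.unique(labels)) == 2:
        metrics["auc"] = float(roc_auc_score(labels, scores))
    else:
        metrics["auc"] = float("nan")
    return metrics
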