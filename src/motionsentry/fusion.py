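"""Multi-sensor fusion: static mixing and adaptive attention weighting.

Three co-registered streams — vision-based joint positions, IMU-derived
accelerations, and a plantar-pressure proxy — are projected into a shared
embedding space and combined per frame. The adaptive path scores each
modality with a small tanh network, optionally conditioned on a causal
temporal-context vector (trailing mean of recent fused frames), and mixes
the embeddings with softmax weights; a modality degraded by noise or
dropout can thus be down-weighted dynamically, which a static mix cannot do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _ops as am
from .graph_encoder import glorot_uniform

MODALITY_ORDER = ("vision", "imu", "pressure")
DEFAULT_CONTEXT_WINDOW = 10  # frames


@dataclass
class ModalityBundle:
    """Named per-modality feature arrays aligned to a common frame axis.

    Arrays are (T, J, C) once joint-aligned (IMU/pressure channels are mapped
    onto joints via the skeleton's sensor map before they get here). A
    modality that was not recorded is explicitly absent from ``features`` —
    never silently zero-filled. ``masks`` may carry per-frame validity for
    degraded streams (True = observed).
    """

    features: dict[str, np.ndarray]
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    static_coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.features:
            raise ValueError("a modality bundle needs at least one modality")
        lengths = {name: arr.shape[0] for name, arr in self.features.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"modalities disagree on frame count: {lengths}")
        for lam in self.static_coefficients.values():
            if lam < 0:
                raise ValueError("static coefficients must be nonnegative")

    @property
    def n_frames(self) -> int:
        return next(iter(self.features.values())).shape[0]

    @property
    def names(self) -> list[str]:
        ordered = [m for m in MODALITY_ORDER if m in self.features]
        extras = sorted(set(self.features) - set(ordered))
        return ordered + extras


@dataclass
class FusionParams:
    """Per-modality projections into shared dim d_s plus the scoring network."""

    projections: dict[str, tuple]  # name -> (W (C, d_s), b (d_s,))
    w_score: "np.ndarray"  # (h,) scoring read-out
    W_score: "np.ndarray"  # (d_s [+ d_s context], h)
    b_score: "np.ndarray"  # (h,)
    context_window: int = DEFAULT_CONTEXT_WINDOW
    use_context: bool = True

    @property
    def shared_dim(self) -> int:
        return am.asdata(next(iter(self.projections.values()))[0]).shape[1]

    @classmethod
    def init(
        cls,
        channel_dims: dict[str, int],
        shared_dim: int,
        rng: np.random.Generator,
        hidden: int = 16,
        context_window: int = DEFAULT_CONTEXT_WINDOW,
        use_context: bool = True,
    ) -> "FusionParams":
        projections = {
            name: (glorot_uniform(rng, c, shared_dim), np.zeros(shared_dim))
            for name, c in channel_dims.items()
        }
        score_in = shared_dim * (2 if use_context else 1)
        return cls(
            projections=projections,
            w_score=glorot_uniform(rng, hidden, 1)[:, 0],
            W_score=glorot_uniform(rng, score_in, hidden),
            b_score=np.zeros(hidden),
            context_window=context_window,
            use_context=use_context,
        )


def static_mix(bundle: ModalityBundle, coefficients: dict[str, float] | None = None):
    """X_total = sum_i lambda_i X^(i) — the fixed-coefficient baseline."""
    lam = coefficients or bundle.static_coefficients
    missing = [m for m in lam if m not in bundle.features]
    if missing:
        raise KeyError(f"static coefficients name absent modalities: {missing}")
    active = {m: lam.get(m, 0.0) for m in bundle.names}
    if all(v == 0.0 for v in active.values()):
        warnings.warn("all static coefficients are zero; the mix is a zero tensor")
    shapes = {bundle.features[m].shape for m in active}
    if len(shapes) != 1:
        raise ValueError(f"modalities are not dimension-compatible: {sorted(shapes)}")
    out = np.zeros(next(iter(shapes)))
    for m, v in active.items():
        out = out + v * bundle.features[m]
    return out


def project_modalities(features: dict, params: FusionParams) -> dict:
    """X~^(i) = X^(i) W^(i) + b^(i), each into the shared dim d_s."""
    out = {}
    for name, x in features.items():
        if name not in params.projections:
            raise KeyError(f"no projection parameters for modality {name!r}")
        W, b = params.projections[name]
        out[name] = x @ W + b
    return out


def modality_weights(embeddings, params: FusionParams, context=None):
    """Softmax attention weights over modalities for one frame.

    ``embeddings`` is an (M, d_s) array (or Tensor) of per-modality frame
    embeddings; ``context`` an optional (d_s,) temporal-context vector that
    is concatenated to every row before scoring:
    s_i = w_s^T tanh(W_s [x~_i, c_t] + b_s), alpha = softmax(s).
    Rows of absent modalities are handled upstream by masking.
    """
    x = embeddings
    M = am.asdata(x).shape[0]
    if context is not None:
        ctx = context
        if am.is_tensor(ctx) or am.is_tensor(x):
            rows = ctx.reshape(1, -1) if am.is_tensor(ctx) else am.asdata(ctx)[None, :]
            ctx_tiled = am.concatenate([rows] * M, axis=0)
        else:
            ctx_tiled = np.tile(np.asarray(ctx)[None, :], (M, 1))
        x = am.concatenate([x, ctx_tiled], axis=1)
    scores = am.tanh(x @ params.W_score + params.b_score) @ params.w_score
    return am.softmax(scores, axis=-1)


def fuse(embeddings, alpha):
    """X_fused = sum_i alpha_i X~^(i); a convex combination of the embeddings."""
    M = am.asdata(embeddings).shape[0]
    if am.asdata(alpha).shape[0] != M:
        raise ValueError("alpha length must match the number of modalities")
    extra = am.asdata(embeddings).ndim - 1
    a = alpha.reshape((M,) + (1,) * extra) if am.is_tensor(alpha) else np.asarray(
        alpha
    ).reshape((M,) + (1,) * extra)
    return am.summation(a * embeddings, axis=0)


def temporal_context(fused_history, window: int):
    """c_t = mean of the previous min(t, window) fused vectors; zeros at t = 0."""
    n = len(fused_history)
    if n == 0:
        return None
    recent = fused_history[-window:]
    if am.is_tensor(recent[0]):
        total = recent[0]
        for r in recent[1:]:
            total = total + r
        return total * (1.0 / len(recent))
    return np.mean(np.stack(recent, axis=0), axis=0)


def fuse_sequence(bundle: ModalityBundle, params: FusionParams):
    """Adaptive attention fusion of a whole sequence.

    Per frame: project each modality (T, J, C) -> (T, J, d_s), pool joints
    into a frame embedding, score modalities (with the causal context vector
    when enabled), and mix the joint-resolved embeddings with the resulting
    softmax weights. Returns ``(X_fused (T, J, d_s), alpha (T, M))``.
    """
    names = bundle.names
    projected = project_modalities(
        {m: bundle.features[m] for m in names}, params
    )  # each (T, J, d_s)
    frame_emb = {m: am.mean(projected[m], axis=1) for m in names}  # (T, d_s)
    T = bundle.n_frames
    d_s = params.shared_dim

    if not params.use_context:
        # context-free scoring factorizes over frames; do it in one shot
        emb = am.stack([frame_emb[m] for m in names], axis=1)  # (T, M, d_s)
        scores = am.tanh(emb @ params.W_score + params.b_score) @ params.w_score
        alpha = am.softmax(scores, axis=-1)  # (T, M)
        x_fused = None
        for i, m in enumerate(names):
            a_i = alpha[:, i].reshape((T, 1, 1))
            term = a_i * projected[m]
            x_fused = term if x_fused is None else x_fused + term
        return x_fused, alpha

    fused_frames = []
    fused_joint_frames = []
    alphas = []
    history: list = []
    zero_ctx = np.zeros(d_s)
    for t in range(T):
        emb_t = am.stack([frame_emb[m][t] for m in names], axis=0)  # (M, d_s)
        ctx = None
        if params.use_context:
            ctx = temporal_context(history, params.context_window)
            if ctx is None:
                ctx = zero_ctx
        alpha_t = modality_weights(emb_t, params, context=ctx)
        joint_t = am.stack([projected[m][t] for m in names], axis=0)  # (M, J, d_s)
        fused_joint_frames.append(fuse(joint_t, alpha_t))
        frame_vec = fuse(emb_t, alpha_t)
        fused_frames.append(frame_vec)
        history.append(frame_vec)
        alphas.append(alpha_t)
    x_fused = am.stack(fused_joint_frames, axis=0)  # (T, J, d_s)
    alpha = am.stack(alphas, axis=0)  # (T, M)
    return x_fused, alpha
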