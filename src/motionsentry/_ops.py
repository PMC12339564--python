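"""Array math that dispatches between numpy arrays and autodiff Tensors.

Loss functions and attention blocks are written once against this layer:
called with numpy inputs they return plain floats/arrays (the inference and
testing path), called with :class:`~motionsentry.autodiff.Tensor` inputs
they stay differentiable (the training path).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad


def is_tensor(x) -> bool:
    return isinstance(x, ad.Tensor)


def asdata(x) -> np.ndarray:
    return x.data if is_tensor(x) else np.asarray(x)


def exp(x):
    return x.exp() if is_tensor(x) else np.exp(x)


def log(x):
    return x.log() if is_tensor(x) else np.log(x)


def tanh(x):
    return x.tanh() if is_tensor(x) else np.tanh(x)


def relu(x):
    return x.relu() if is_tensor(x) else np.maximum(x, 0.0)


def absolute(x):
    return x.abs() if is_tensor(x) else np.abs(x)


def sqrt(x):
    return x.sqrt() if is_tensor(x) else np.sqrt(x)


def summation(x, axis=None, keepdims=False):
    if is_tensor(x):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def mean(x, axis=None, keepdims=False):
    if is_tensor(x):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)


def sigmoid(x):
    if is_tensor(x):
        return ad.sigmoid(x)
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def softmax(x, axis=-1):
    if is_tensor(x):
        return ad.softmax(x, axis=axis)
    x = np.asarray(x, dtype=float)
    e = np.exp(x - np.max(x, axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def concatenate(parts, axis=0):
    if any(is_tensor(p) for p in parts):
        return ad.concatenate(parts, axis=axis)
    return np.concatenate(parts, axis=axis)


def stack(parts, axis=0):
    if any(is_tensor(p) for p in parts):
        return ad.stack(parts, axis=axis)
    return np.stack(parts, axis=axis)


def swapaxes(x, a, b):
    return x.swapaxes(a, b) if is_tensor(x) else np.swapaxes(x, a, b)


def item(x) -> float:
    return float(x.data) if is_tensor(x) else float(x)
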