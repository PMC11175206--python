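"""Minimal dense/convolutional layer primitives with explicit backprop.

Every layer is a pair of pure functions: ``*_forward`` returns the output and
a cache, ``*_backward`` consumes the upstream gradient and the cache and
returns input/parameter gradients.  All arrays are float64; convolutions are
valid-padding, stride 1, NHWC layout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dense_forward",
    "dense_backward",
    "relu_forward",
    "relu_backward",
    "conv2d_forward",
    "conv2d_backward",
    "softmax",
    "softmax_cross_entropy",
    "sigmoid",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Glorot/Xavier uniform initialization.

    fan_in/fan_out follow the usual convention: for a dense weight
    ``(n_in, n_out)`` they are the two axes; for a conv filter
    ``(kh, kw, c_in, c_out)`` they are ``kh*kw*c_in`` and ``kh*kw*c_out``.
    """
    if len(shape) == 2:
        fan_in, fan_out = shape
    elif len(shape) == 4:
        receptive = shape[0] * shape[1]
        fan_in, fan_out = receptive * shape[2], receptive * shape[3]
    else:  # biases and 1-D parameters start at zero elsewhere
        fan_in = fan_out = int(np.prod(shape))
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    out = x @ w + b
    return out, (x, w)


def dense_backward(dout: np.ndarray, cache):
    x, w = cache
    dx = dout @ w.T
    dw = x.T @ dout
    db = dout.sum(axis=0)
    return dx, dw, db


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, (x > 0.0)


def relu_backward(dout: np.ndarray, cache):
    return dout * cache


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # x: (N, H, W, C) -> (N, Ho, Wo, kh, kw, C)
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    # sliding_window_view yields (N, Ho, Wo, C, kh, kw)
    return np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3))


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid-padding stride-1 convolution. x (N,H,W,Cin), w (kh,kw,Cin,Cout)."""
    n, h, wd, cin = x.shape
    kh, kw, cin_w, cout = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, filter expects {cin_w}")
    if h < kh or wd < kw:
        raise ValueError(f"input {h}x{wd} smaller than kernel {kh}x{kw}")
    ho, wo = h - kh + 1, wd - kw + 1
    cols = _im2col(x, kh, kw).reshape(n * ho * wo, kh * kw * cin)
    wmat = w.reshape(kh * kw * cin, cout)
    out = (cols @ wmat + b).reshape(n, ho, wo, cout)
    return out, (x.shape, cols, wmat, (kh, kw, cin, cout))


def conv2d_backward(dout: np.ndarray, cache):
    x_shape, cols, wmat, (kh, kw, cin, cout) = cache
    n, h, wd, _ = x_shape
    ho, wo = h - kh + 1, wd - kw + 1
    dflat = dout.reshape(n * ho * wo, cout)
    dw = (cols.T @ dflat).reshape(kh, kw, cin, cout)
    db = dflat.sum(axis=0)
    dcols = (dflat @ wmat.T).reshape(n, ho, wo, kh, kw, cin)
    dx = np.zeros(x_shape)
    for i in range(kh):
        for j in range(kw):
            dx[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, i, j, :]
    return dx, dw, db


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean cross-entropy over samples and its gradient w.r.t. logits."""
    n = logits.shape[0]
    probs = softmax(logits)
    # clip only inside the log; the gradient uses the exact probs
    loss = -np.sum(onehot * np.log(np.clip(probs, 1e-300, None))) / n
    dlogits = (probs - onehot) / n
    return loss, dlogits


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
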