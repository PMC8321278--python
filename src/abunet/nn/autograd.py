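"""Minimal reverse-mode autodiff on NumPy arrays.

Only the operations a 2-D segmentation U-Net needs are provided: same-padded
stride-1 convolution, 2x2 max pooling, 2x2/stride-2 transposed convolution,
batch normalization, ReLU, element-wise (inverted) dropout, channel
concatenation and a fused softmax cross-entropy loss.  Tensors carry NCHW
float32 data; gradients are accumulated on a tape and released by
:func:`backward` via a topological sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "backward",
    "conv2d",
    "conv_transpose2d",
    "maxpool2x2",
    "relu",
    "dropout",
    "batchnorm",
    "concat_channels",
    "softmax_cross_entropy",
]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=False)
        else:
            self.grad = self.grad + g


def backward(loss: Tensor):
    """Backpropagate from a scalar loss through the tape."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:  # iterative post-order; graphs can be deep
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(order):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


# ---------------------------------------------------------------- conv ops

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix for stride-1 correlation."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # v: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * k * k
    )


def _corr2d_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Plain stride-1 'same' cross-correlation, no graph."""
    n, _, h, wd = x.shape
    o, c, k, _ = w.shape
    cols = _im2col(x, k, pad)
    out = cols @ w.reshape(o, c * k * k).T
    return out.reshape(n, h, wd, o).transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int) -> Tensor:
    """Stride-1 correlation with same padding (k odd, pad=(k-1)//2)."""
    n, cin, h, wd = x.data.shape
    o, _, k, _ = w.data.shape
    cols = _im2col(x.data, k, pad)
    wmat = w.data.reshape(o, cin * k * k)
    out = (cols @ wmat.T + b.data).reshape(n, h, wd, o).transpose(0, 3, 1, 2)
    res = Tensor(out, parents=(x, w, b))

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * wd, o)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            # dx = correlation of g with the channel-swapped, spatially
            # flipped kernel; exact for stride 1 / same padding.
            wt = w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
            x._accum(_corr2d_raw(g, np.ascontiguousarray(wt), pad))

    res._backward = bwd
    return res


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 kernel, stride-2 transposed convolution (doubles H and W).

    Windows do not overlap, so forward/backward reduce to reshapes.
    w has shape (C_in, C_out, 2, 2).
    """
    n, cin, h, wd = x.data.shape
    _, cout, _, _ = w.data.shape
    out = np.einsum("nchw,coij->nohiwj", x.data, w.data, optimize=True)
    out = out.reshape(n, cout, 2 * h, 2 * wd) + b.data[:, None, None]
    res = Tensor(out, parents=(x, w, b))

    def bwd(g):
        gr = g.reshape(n, cout, h, 2, wd, 2)
        if w.requires_grad:
            w._accum(np.einsum("nchw,nohiwj->coij", x.data, gr, optimize=True))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(np.einsum("nohiwj,coij->nchw", gr, w.data, optimize=True))

    res._backward = bwd
    return res


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max-pool needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    win = np.ascontiguousarray(xr.transpose(0, 1, 2, 4, 3, 5)).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    res = Tensor(out, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gw = np.zeros_like(win)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            gx = gw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5
            ).reshape(n, c, h, w)
            x._accum(gx)

    res._backward = bwd
    return res


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    res = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)

    res._backward = bwd
    return res


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted element-wise dropout: zero with prob p, scale kept by 1/(1-p)."""
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    res = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)

    res._backward = bwd
    return res


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mean: np.ndarray,
    var: np.ndarray,
    training: bool,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel normalization with the given statistics.

    In training mode `mean`/`var` are the current mini-batch statistics and
    the full batch-norm gradient is used; in evaluation mode they are frozen
    running averages and behave as constants.
    """
    n, c, h, w = x.data.shape
    m = mean[:, None, None]
    inv = (1.0 / np.sqrt(var + eps))[:, None, None].astype(x.data.dtype)
    xhat = (x.data - m) * inv
    out = gamma.data[:, None, None] * xhat + beta.data[:, None, None]
    res = Tensor(out, parents=(x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gy = g * gamma.data[:, None, None]
            if training:
                cnt = n * h * w
                sum_gy = gy.sum(axis=(0, 2, 3), keepdims=True)
                sum_gy_xhat = (gy * xhat).sum(axis=(0, 2, 3), keepdims=True)
                gx = (inv / cnt) * (cnt * gy - sum_gy - xhat * sum_gy_xhat)
            else:
                gx = gy * inv
            x._accum(gx)

    res._backward = bwd
    return res


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    res = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g[:, :ca])
        if b.requires_grad:
            b._accum(g[:, ca:])

    res._backward = bwd
    return res


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over all pixels of the batch.

    logits: (N, c, H, W); target: (N, H, W) integer labels.
    """
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n, c, h, w = probs.shape
    t = target.astype(np.int64)
    picked = np.take_along_axis(probs, t[:, None], axis=1)[:, 0]
    loss_val = -np.log(np.maximum(picked, 1e-30)).mean()
    res = Tensor(np.asarray(loss_val, dtype=logits.data.dtype), parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            grad = probs.copy()
            onehot_idx = t[:, None]
            np.put_along_axis(
                grad, onehot_idx, np.take_along_axis(grad, onehot_idx, 1) - 1.0, 1
            )
            logits._accum(grad * (float(g) / (n * h * w)))

    res._backward = bwd
    return res
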