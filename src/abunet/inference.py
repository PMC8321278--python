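"""Deterministic and Monte-Carlo predictive inference.

Two prediction regimes are exposed:

``standard_predict``
    one forward pass with every dropout site disabled and batch norm frozen
    on its running statistics — the deterministic reference prediction
    p(Y|X, Theta).

``mc_predict``
    T forward passes with dropout kept active (fresh Bernoulli masks each
    pass), averaged into the Monte-Carlo posterior predictive
    p(Y|X, D) ~= (1/T) * sum_t p(Y|X, W_t).  The full T-slice stack is
    returned alongside the mean so disagreement statistics (BALD, predictive
    variance) can be computed.

Probability maps are float64 arrays of shape (H, W, c) normalized per pixel.
"""

from __future__ import annotations

import numpy as np
from scipy.special import softmax

from .nn import ForwardContext, Tensor
from .model import UNet

__all__ = [
    "standard_predict",
    "mc_predict",
    "predictive_variance",
    "predict_batch",
    "mc_predict_batch",
]


def _to_nchw(images: np.ndarray, in_channels: int) -> np.ndarray:
    """Accept (H,W), (H,W,C), (N,H,W) or (N,H,W,C); return float32 (N,C,H,W)."""
    a = np.asarray(images, dtype=np.float32)
    if a.ndim == 2:
        a = a[None, :, :, None]
    elif a.ndim == 3:
        if a.shape[-1] == in_channels:
            a = a[None]
        else:
            a = a[..., None]
    if a.ndim != 4:
        raise ValueError(f"cannot interpret image array of shape {images.shape}")
    return np.ascontiguousarray(a.transpose(0, 3, 1, 2))


def _forward_probs(net: UNet, x: np.ndarray, ctx: ForwardContext) -> np.ndarray:
    logits = net.forward(Tensor(x), ctx).data
    # softmax in float64 so per-pixel normalization holds to tight tolerance
    probs = softmax(logits.astype(np.float64), axis=1)
    return probs.transpose(0, 2, 3, 1)  # (N, H, W, c)


def predict_batch(net: UNet, images: np.ndarray) -> np.ndarray:
    """Deterministic probability maps for a batch; (N, H, W, c)."""
    x = _to_nchw(images, net.config.in_channels)
    return _forward_probs(net, x, ForwardContext())


def standard_predict(net: UNet, image: np.ndarray) -> np.ndarray:
    """Deterministic single-image prediction; (H, W, c).

    Dropout off, batch norm on running statistics: repeated calls are
    bit-identical.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValueError("standard_predict expects a single (H,W[,C]) image")
    x = _to_nchw(image, net.config.in_channels)
    return _forward_probs(net, x, ForwardContext())[0]


def mc_predict_batch(
    net: UNet,
    images: np.ndarray,
    T: int,
    seed: int,
    mc_batchnorm: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo prediction for a batch.

    Returns (mean, stack) with shapes (N,H,W,c) and (T,N,H,W,c).
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    x = _to_nchw(images, net.config.in_channels)
    rng = np.random.default_rng(seed)
    ctx = ForwardContext(stochastic=True, mc_batchnorm=mc_batchnorm, rng=rng)
    slices = [_forward_probs(net, x, ctx) for _ in range(T)]
    stack = np.stack(slices, axis=0)
    return stack.mean(axis=0), stack


def mc_predict(
    net: UNet,
    image: np.ndarray,
    T: int,
    seed: int,
    mc_batchnorm: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo prediction for one image.

    Returns (mean, stack) with shapes (H,W,c) and (T,H,W,c).  Fresh dropout
    masks are drawn for each of the T passes from a generator seeded with
    ``seed``, so equal seeds give bit-identical stacks.  On a network without
    dropout sites all passes coincide with the deterministic prediction.
    """
    mean, stack = mc_predict_batch(net, image, T, seed, mc_batchnorm)
    return mean[0], stack[:, 0]


def predictive_variance(stack: np.ndarray) -> np.ndarray:
    """Per-pixel variance across passes of the top-class probability.

    The summary used to shade uncertainty maps: for each pixel take the
    probability of the MC-mean argmax class in every pass and return the
    population variance over the T passes.  stack: (T, H, W, c).
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 4:
        raise ValueError("stack must have shape (T, H, W, c)")
    if stack.shape[0] < 2:
        raise ValueError("predictive variance needs T >= 2 passes")
    mean = stack.mean(axis=0)
    top = mean.argmax(axis=-1)  # (H, W)
    per_pass = np.take_along_axis(
        stack, top[None, :, :, None], axis=-1
    )[..., 0]  # (T, H, W)
    var = per_pass.var(axis=0)
    # exactly zero where the passes literally agree (no roundoff residue)
    var[np.ptp(per_pass, axis=0) == 0] = 0.0
    return var
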