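"""Bayesian U-Net builder.

The network is the classic encoder/decoder U shape: per resolution level two
3x3 same-padded convolutions followed by one batch-normalization layer and a
rectifier; 2x2 max pooling on the way down, 2x2 stride-2 up-convolutions and
skip concatenations on the way up, and a 1x1 softmax head.  Epistemic
uncertainty is injected by Bernoulli dropout whose placement is the
``variant`` knob:

- ``plain``            — no dropout sites at all;
- ``maxpool_dropout``  — one site immediately after each max pool
  (``depth`` sites), the placement that benchmarks best for uncertainty
  quality;
- ``standard_dropout`` — one site after each double-convolution block
  (``2*depth + 1`` sites);
- ``both``             — the union of the two placements.

Monte-Carlo prediction (dropout kept live at inference) then approximates
posterior predictive averaging over network weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import ForwardContext, Tensor
from .nn.autograd import concat_channels

VARIANTS = ("plain", "standard_dropout", "maxpool_dropout", "both")


class ShapeError(ValueError):
    """Input spatial dimensions incompatible with the network."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    depth          number of pooling levels; inputs must be divisible by 2**depth
    base_filters   channel count at the top level, doubled at each level down
    n_classes      number of pixel classes c (softmax width)
    in_channels    1 for greyscale, 3 for RGB
    variant        dropout placement, one of VARIANTS
    dropout_rate   Bernoulli drop probability p
    use_batchnorm  batch-normalize after each convolution pair
    """

    depth: int = 3
    base_filters: int = 16
    n_classes: int = 2
    in_channels: int = 1
    variant: str = "maxpool_dropout"
    dropout_rate: float = 0.5
    use_batchnorm: bool = True

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in (0,1)")


class _DoubleConv(nn.Module):
    """conv3x3 -> conv3x3 -> [batch norm] -> ReLU."""

    def __init__(self, cin, cout, use_bn, rng):
        self.c1 = nn.Conv2d(cin, cout, 3, rng)
        self.c2 = nn.Conv2d(cout, cout, 3, rng)
        self.bn = nn.BatchNorm2d(cout) if use_bn else None
        self.act = nn.ReLU()

    def forward(self, x, ctx):
        x = self.c1.forward(x, ctx)
        x = self.c2.forward(x, ctx)
        if self.bn is not None:
            x = self.bn.forward(x, ctx)
        return self.act.forward(x, ctx)


class UNet(nn.Module):
    """A built network; doubles as the opaque weights handle.

    Use :func:`build_unet` rather than constructing directly.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        d, f = config.depth, config.base_filters
        p = config.dropout_rate
        bn = config.use_batchnorm
        block_drop = config.variant in ("standard_dropout", "both")
        pool_drop = config.variant in ("maxpool_dropout", "both")

        self.enc = []
        cin = config.in_channels
        for lvl in range(d):
            cout = f * 2 ** lvl
            self.enc.append(_DoubleConv(cin, cout, bn, rng))
            cin = cout
        self.enc_drop = [nn.Dropout(p) if block_drop else None for _ in range(d)]
        self.pool = nn.MaxPool2x2()
        self.pool_drop = [nn.Dropout(p) if pool_drop else None for _ in range(d)]

        self.bottleneck = _DoubleConv(cin, f * 2 ** d, bn, rng)
        self.bottleneck_drop = nn.Dropout(p) if block_drop else None

        self.up = []
        self.dec = []
        self.dec_drop = []
        cin = f * 2 ** d
        for lvl in reversed(range(d)):
            cout = f * 2 ** lvl
            self.up.append(nn.ConvTranspose2d(cin, cout, rng))
            self.dec.append(_DoubleConv(2 * cout, cout, bn, rng))
            self.dec_drop.append(nn.Dropout(p) if block_drop else None)
            cin = cout
        self.head = nn.Conv2d(cin, config.n_classes, 1, rng)

    # ------------------------------------------------------------ forward

    def _check_shape(self, x: np.ndarray):
        d = self.config.depth
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ShapeError(
                f"expected {self.config.in_channels} input channel(s), got {c}"
            )
        div = 2 ** d
        if h % div:
            raise ShapeError(f"height {h} not divisible by 2**depth = {div}")
        if w % div:
            raise ShapeError(f"width {w} not divisible by 2**depth = {div}")

    def forward(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        """Return class logits of shape (N, c, H, W)."""
        self._check_shape(x.data)
        skips = []
        for lvl in range(self.config.depth):
            x = self.enc[lvl].forward(x, ctx)
            if self.enc_drop[lvl] is not None:
                x = self.enc_drop[lvl].forward(x, ctx)
            skips.append(x)
            x = self.pool.forward(x, ctx)
            if self.pool_drop[lvl] is not None:
                x = self.pool_drop[lvl].forward(x, ctx)
        x = self.bottleneck.forward(x, ctx)
        if self.bottleneck_drop is not None:
            x = self.bottleneck_drop.forward(x, ctx)
        for i, lvl in enumerate(reversed(range(self.config.depth))):
            x = self.up[i].forward(x, ctx)
            x = concat_channels(skips[lvl], x)
            x = self.dec[i].forward(x, ctx)
            if self.dec_drop[i] is not None:
                x = self.dec_drop[i].forward(x, ctx)
        return self.head.forward(x, ctx)

    # ------------------------------------------------------------ weights

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, mod in enumerate(self.modules()):
            for attr, v in vars(mod).items():
                if isinstance(v, Tensor) and v.requires_grad:
                    state[f"{i}.{attr}"] = v.data.copy()
                elif attr in ("running_mean", "running_var"):
                    state[f"{i}.{attr}"] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for i, mod in enumerate(self.modules()):
            for attr, v in vars(mod).items():
                key = f"{i}.{attr}"
                if isinstance(v, Tensor) and v.requires_grad:
                    v.data = state[key].copy()
                elif attr in ("running_mean", "running_var"):
                    setattr(mod, attr, state[key].copy())

    def save(self, path):
        """Write a single-file checkpoint (npz with embedded config)."""
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **state)

    @classmethod
    def load(cls, path) -> "UNet":
        with np.load(path) as z:
            cfg = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
            net = cls(cfg)
            net.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return net


def build_unet(config: ModelConfig, seed: int = 0) -> UNet:
    """Build a randomly initialized network for the given configuration."""
    return UNet(config, seed=seed)


def count_stochastic_sites(net: UNet) -> int:
    """Number of dropout layers wired into the network."""
    return sum(isinstance(m, nn.Dropout) for m in net.modules())
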