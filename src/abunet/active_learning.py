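"""Pool-based active learning with a simulated oracle.

The loop: train on a small seed set, score every unlabelled image with an
acquisition function, ask the oracle to label the top-k, fold the new pairs
into the training set, warm-start retrain (Adam, lr 1e-3, early stopping on
validation dice), and repeat for a fixed iteration budget or until the pool
is empty.  The oracle is simulated by a held-out label lookup that counts
every label it releases, so the label budget of a run is auditable:
initial_size + iterations * k when the pool is not exhausted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .acquisition import AcquisitionScore, score_stack, select_top_k
from .inference import mc_predict_batch, predict_batch, predictive_variance
from .metrics import dice_multiclass
from .model import ModelConfig, UNet, build_unet
from .nn import ForwardContext, Tensor
from .nn.autograd import backward, softmax_cross_entropy

__all__ = [
    "Oracle",
    "ALState",
    "train_with_early_stopping",
    "run_active_learning",
    "run_variant_benchmark",
    "ACQUISITION_CHOICES",
]

ACQUISITION_CHOICES = ("entropy", "bald", "committee_kl", "committee_jsd", "random")


class Oracle:
    """Simulated annotator: a lookup of held-out ground-truth masks.

    ``query_count`` tallies every label released and never decreases.
    """

    def __init__(self, masks: dict):
        self._masks = dict(masks)
        self.query_count = 0

    def query(self, ids) -> dict:
        out = {}
        for i in ids:
            if i not in self._masks:
                raise KeyError(f"oracle has no label for image id {i!r}")
            out[i] = self._masks[i]
        self.query_count += len(out)
        return out


@dataclass
class ALState:
    """Evolving state of one active-learning run."""

    iteration: int
    labeled_ids: set
    pool_ids: set
    net: UNet
    history: list = field(default_factory=list)
    initial_record: dict | None = None

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


# ------------------------------------------------------------------ training

def _val_dice(net: UNet, val_images, val_masks, n_classes: int) -> np.ndarray:
    probs = predict_batch(net, val_images)
    preds = probs.argmax(axis=-1).astype(val_masks.dtype)
    return np.array(
        [dice_multiclass(p, t, n_classes) for p, t in zip(preds, val_masks)]
    )


def _mc_val_dice(net, val_images, val_masks, n_classes, T, seed):
    mean, _ = mc_predict_batch(net, val_images, T=T, seed=seed)
    preds = mean.argmax(axis=-1).astype(val_masks.dtype)
    return np.array(
        [dice_multiclass(p, t, n_classes) for p, t in zip(preds, val_masks)]
    )


def train_with_early_stopping(
    net: UNet,
    images: np.ndarray,
    masks: np.ndarray,
    val_images: np.ndarray,
    val_masks: np.ndarray,
    max_epochs: int = 60,
    patience: int = 5,
    lr: float = 1e-3,
    batch_size: int = 4,
    seed: int = 0,
) -> tuple[UNet, int]:
    """Train in place from the given weights; return (net, epochs_run).

    Minimizes mean categorical cross-entropy with Adam.  After each epoch the
    deterministic validation dice is measured; training stops once it has not
    improved for ``patience`` consecutive epochs (or at ``max_epochs``) and
    the weights of the best epoch are restored.  ``max_epochs=0`` is an
    explicit no-op returning the given weights untouched.
    """
    if len(images) == 0:
        raise ValueError("cannot train on an empty labelled set")
    if len(val_images) == 0:
        raise ValueError("validation set is empty")
    if max_epochs < 0:
        raise ValueError("max_epochs must be >= 0")
    if max_epochs == 0:
        return net, 0

    rng = np.random.default_rng(seed)
    opt = nn.Adam(net.parameters(), lr=lr)
    n = len(images)
    c = net.config.n_classes
    from .inference import _to_nchw  # shared NCHW conversion

    x_all = _to_nchw(images, net.config.in_channels)
    y_all = np.asarray(masks)

    best_state = net.state_dict()
    best_dice = _val_dice(net, val_images, val_masks, c).mean()
    best_epoch = 0
    epochs_run = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            ctx = ForwardContext(training=True, rng=rng)
            logits = net.forward(Tensor(x_all[idx], requires_grad=True), ctx)
            loss = softmax_cross_entropy(logits, y_all[idx])
            opt.zero_grad()
            backward(loss)
            opt.step()
        epochs_run = epoch
        dice = _val_dice(net, val_images, val_masks, c).mean()
        if dice > best_dice:
            best_dice = dice
            best_state = net.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= patience:
            break
    net.load_state_dict(best_state)
    return net, epochs_run


# ------------------------------------------------------------------ the loop

def _score_pool(net, ids, pool, acquisition, T, seed, rng):
    """Score a list of pool ids with the chosen acquisition function."""
    if acquisition == "random":
        return [
            AcquisitionScore(i, float(rng.random()), "random") for i in ids
        ]
    imgs = np.stack([pool[i] for i in ids])
    mc_mean, stack = mc_predict_batch(net, imgs, T=T, seed=seed)
    if acquisition in ("committee_kl", "committee_jsd"):
        standard = predict_batch(net, imgs)
    else:
        standard = None
    out = []
    for j, i in enumerate(ids):
        s = score_stack(
            acquisition,
            standard=None if standard is None else standard[j],
            mc_mean=mc_mean[j],
            stack=stack[:, j],
        )
        out.append(AcquisitionScore(i, s, acquisition))
    return out


def run_active_learning(
    model_config: ModelConfig,
    pool: dict,
    oracle: Oracle,
    val_images: np.ndarray,
    val_masks: np.ndarray,
    acquisition: str = "committee_jsd",
    k: int = 2,
    iterations: int = 15,
    initial_size: int = 2,
    subsample_size: int | None = None,
    T: int = 20,
    seed: int = 0,
    max_epochs: int = 60,
    patience: int = 5,
    lr: float = 1e-3,
    batch_size: int = 4,
    net: UNet | None = None,
) -> ALState:
    """Run the full interactive loop and return its final state.

    pool: mapping image_id -> image; oracle holds the matching masks.
    Each iteration scores a (sub)sample of the pool, labels the top ``k``
    images, and retrains from the current weights.  The whole run is
    deterministic given ``seed``.
    """
    if acquisition not in ACQUISITION_CHOICES:
        raise ValueError(
            f"unknown acquisition {acquisition!r}; one of {ACQUISITION_CHOICES}"
        )
    if initial_size < 1:
        raise ValueError("initial_size must be >= 1")
    if len(pool) <= initial_size:
        raise ValueError("pool must be larger than initial_size")

    rng = np.random.default_rng(seed)
    pool_ids = sorted(pool.keys())
    init_ids = list(
        np.array(pool_ids, dtype=object)[
            rng.choice(len(pool_ids), size=initial_size, replace=False)
        ]
    )
    labeled: dict = dict(oracle.query(init_ids))
    pool_ids = [i for i in pool_ids if i not in labeled]

    if net is None:
        net = build_unet(model_config, seed=int(rng.integers(2 ** 31)))
    c = model_config.n_classes

    def _train():
        ids = sorted(labeled.keys())
        imgs = np.stack([pool[i] for i in ids])
        msks = np.stack([labeled[i] for i in ids])
        return train_with_early_stopping(
            net, imgs, msks, val_images, val_masks,
            max_epochs=max_epochs, patience=patience, lr=lr,
            batch_size=batch_size, seed=int(rng.integers(2 ** 31)),
        )

    t0 = time.perf_counter()
    _, epochs0 = _train()
    mc0 = _mc_val_dice(net, val_images, val_masks, c, T,
                       int(rng.integers(2 ** 31)))
    state = ALState(
        iteration=0,
        labeled_ids=set(labeled),
        pool_ids=set(pool_ids),
        net=net,
        initial_record={
            "n_labeled": len(labeled),
            "val_dice_mean": float(mc0.mean()),
            "val_dice_sd": float(mc0.std(ddof=1)) if len(mc0) > 1 else 0.0,
            "epochs_run": epochs0,
            "seconds": time.perf_counter() - t0,
        },
    )

    for t in range(1, iterations + 1):
        if not pool_ids:
            break
        t0 = time.perf_counter()
        if subsample_size is not None and subsample_size < len(pool_ids):
            sub = list(
                np.array(pool_ids, dtype=object)[
                    rng.choice(len(pool_ids), size=subsample_size, replace=False)
                ]
            )
        else:
            sub = list(pool_ids)
        scores = _score_pool(
            net, sub, pool, acquisition, T, int(rng.integers(2 ** 31)), rng
        )
        chosen = select_top_k(scores, min(k, len(sub)))
        labeled.update(oracle.query(chosen))
        pool_ids = [i for i in pool_ids if i not in set(chosen)]
        _, epochs_run = _train()
        mc = _mc_val_dice(net, val_images, val_masks, c, T,
                          int(rng.integers(2 ** 31)))
        state.iteration = t
        state.labeled_ids = set(labeled)
        state.pool_ids = set(pool_ids)
        state.history.append(
            {
                "iteration": t,
                "n_labeled": len(labeled),
                "acquisition": acquisition,
                "selected": ",".join(str(i) for i in chosen),
                "val_dice_mean": float(mc.mean()),
                "val_dice_sd": float(mc.std(ddof=1)) if len(mc) > 1 else 0.0,
                "epochs_run": epochs_run,
                "seconds": time.perf_counter() - t0,
            }
        )
    return state


# ------------------------------------------------------------------ benchmark

def run_variant_benchmark(
    variants: list[ModelConfig],
    training_sizes: list[int],
    repeats: int,
    epochs: int,
    T: int,
    seed: int,
    train_images: np.ndarray,
    train_masks: np.ndarray,
    val_images: np.ndarray,
    val_masks: np.ndarray,
    lr: float = 1e-3,
    batch_size: int = 4,
    patience: int = 5,
) -> pd.DataFrame:
    """Train every (variant, training size, repeat) cell and score it.

    Returns a tidy table (variant, size, repeat, metric, value) with three
    metrics per cell: deterministic validation dice, MC validation dice, and
    the mean per-pixel predictive variance over the validation set (exactly
    zero for dropout-free variants).
    """
    for size in training_sizes:
        if size > len(train_images):
            raise ValueError(
                f"training size {size} exceeds available {len(train_images)}"
            )
    rng = np.random.default_rng(seed)
    rows = []
    for cfg in variants:
        for size in training_sizes:
            for rep in range(repeats):
                net = build_unet(cfg, seed=int(rng.integers(2 ** 31)))
                idx = rng.choice(len(train_images), size=size, replace=False)
                train_with_early_stopping(
                    net, train_images[idx], train_masks[idx],
                    val_images, val_masks, max_epochs=epochs,
                    patience=patience, lr=lr, batch_size=batch_size,
                    seed=int(rng.integers(2 ** 31)),
                )
                det = _val_dice(net, val_images, val_masks, cfg.n_classes)
                mc_seed = int(rng.integers(2 ** 31))
                mean, stack = mc_predict_batch(net, val_images, T=T, seed=mc_seed)
                preds = mean.argmax(axis=-1).astype(val_masks.dtype)
                mc = np.mean(
                    [
                        dice_multiclass(p, t, cfg.n_classes)
                        for p, t in zip(preds, val_masks)
                    ]
                )
                pv = np.mean(
                    [predictive_variance(stack[:, j]).mean()
                     for j in range(len(val_images))]
                ) if T >= 2 else 0.0
                for metric, value in (
                    ("val_dice", float(det.mean())),
                    ("mc_val_dice", float(mc)),
                    ("predictive_variance", float(pv)),
                ):
                    rows.append(
                        {
                            "variant": cfg.variant,
                            "size": size,
                            "repeat": rep,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)
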