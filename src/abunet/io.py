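"""Dataset directory I/O, run configuration, and result persistence.

A dataset directory holds paired rasters with matching basenames::

    <root>/images/xxx.png   greyscale or RGB intensities
    <root>/masks/xxx.png    single-channel integer labels in {0..c-1}
    <root>/manifest.csv     columns: filename, split  (optional)

Masks are stored as indexed 8-bit PNG (16-bit past 256 classes) so labels
survive a round trip losslessly; intensities are rescaled to [0, 1] on load.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "load_dataset_dir",
    "save_dataset_dir",
    "write_mask_png",
]


def write_mask_png(path, mask: np.ndarray):
    mask = np.asarray(mask)
    if mask.max(initial=0) > 65535:
        raise ValueError("mask labels exceed 16-bit PNG range")
    dtype = np.uint8 if mask.max(initial=0) <= 255 else np.uint16
    iio.imwrite(path, mask.astype(dtype))


def save_dataset_dir(root, images, masks, splits=None, names=None):
    """Write a dataset directory (PNG pairs + manifest)."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    n = len(images)
    if names is None:
        names = [f"img_{i:04d}.png" for i in range(n)]
    if splits is None:
        splits = ["train"] * n
    for name, img, msk in zip(names, images, masks):
        arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
        iio.imwrite(root / "images" / name, np.round(arr * 255).astype(np.uint8))
        write_mask_png(root / "masks" / name, msk)
    pd.DataFrame({"filename": names, "split": splits}).to_csv(
        root / "manifest.csv", index=False
    )


def load_dataset_dir(root, n_classes: int | None = None, split: str | None = None):
    """Load aligned (images, masks, names) from a dataset directory.

    images: (N, H, W[, C]) float32 rescaled to [0, 1]; masks: (N, H, W)
    integer.  With ``n_classes`` given, any mask label >= n_classes is a
    validation error; with ``split`` given, only manifest rows of that split
    are loaded.
    """
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError(
            f"{root} must contain images/ and masks/ subdirectories"
        )
    manifest = root / "manifest.csv"
    if manifest.exists():
        df = pd.read_csv(manifest)
        if split is not None:
            df = df[df["split"] == split]
        names = list(df["filename"])
    else:
        names = sorted(p.name for p in img_dir.iterdir())
    if not names:
        raise ValueError(f"no image/mask pairs found under {root}")
    images, masks = [], []
    for name in names:
        ip, mp = img_dir / name, mask_dir / name
        if not ip.exists() or not mp.exists():
            raise FileNotFoundError(f"missing image or mask for basename {name!r}")
        img = np.asarray(iio.imread(ip), dtype=np.float32)
        scale = 65535.0 if img.max(initial=0) > 255 else 255.0
        images.append(img / scale)
        msk = np.asarray(iio.imread(mp))
        if msk.ndim != 2:
            raise ValueError(f"mask {name!r} is not single-channel")
        if not np.issubdtype(msk.dtype, np.integer):
            raise ValueError(f"mask {name!r} is not integer-valued")
        if n_classes is not None and msk.max(initial=0) >= n_classes:
            raise ValueError(
                f"mask {name!r} contains label {int(msk.max())} >= "
                f"n_classes={n_classes}"
            )
        masks.append(msk.astype(np.int64))
    return np.stack(images), np.stack(masks), names


@dataclass
class RunConfig:
    """Resolved configuration of one run; round-trips through YAML."""

    # architecture
    depth: int = 3
    base_filters: int = 16
    n_classes: int = 5
    in_channels: int = 1
    variant: str = "maxpool_dropout"
    dropout_rate: float = 0.5
    use_batchnorm: bool = True
    # training
    lr: float = 1e-3
    batch_size: int = 4
    max_epochs: int = 60
    patience: int = 5
    # active learning
    acquisition: str = "committee_jsd"
    k: int = 2
    iterations: int = 15
    initial_size: int = 2
    subsample_size: int | None = None
    T: int = 20
    # bookkeeping
    data_dir: str | None = None
    output_dir: str | None = None
    seed: int = 0

    def model_config(self):
        from .model import ModelConfig

        return ModelConfig(
            depth=self.depth,
            base_filters=self.base_filters,
            n_classes=self.n_classes,
            in_channels=self.in_channels,
            variant=self.variant,
            dropout_rate=self.dropout_rate,
            use_batchnorm=self.use_batchnorm,
        )

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def overridden(self, **kwargs) -> "RunConfig":
        vals = asdict(self)
        vals.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**vals)
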