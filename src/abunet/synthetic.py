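"""Procedural multi-class segmentation data.

Emulates the structure of the microscopy benchmarks this method targets —
images containing several compact objects of distinct tissue classes over a
dark background — at a size a CPU can train on.  Each image renders a random
number of geometric objects (discs, rectangles, rings); the object's class
sets its intensity band, the rendered geometry is the ground-truth mask, and
additive Gaussian noise controls difficulty.  The companion augmentation
applies one random affine map (rotation, shift, scale, shear) to image and
mask jointly, bilinear for intensities and nearest-neighbour for labels.

What this emulates: multi-class pixel labelling with class-intensity
correlation, object shape variety, and label-preserving geometric
augmentation.  What it does not: real microscopy texture, staining
variation, touching-object ambiguity, or annotation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SyntheticSpec",
    "AugmentParams",
    "generate_dataset",
    "augment_pair",
    "expected_foreground_fraction",
    "HELA_LIKE",
]

_SHAPES = ("disc", "rect", "ring")
# shape size ranges as fractions of min(H, W)
_RADIUS_FRAC = (0.06, 0.16)
_RING_INNER_FRAC = (0.4, 0.7)   # inner radius as fraction of outer


@dataclass(frozen=True)
class SyntheticSpec:
    """Dataset recipe; label 0 is background, classes 1..c-1 are objects."""

    n_images: int = 40
    height: int = 64
    width: int = 64
    n_classes: int = 5
    shapes_per_image: tuple[int, int] = (2, 5)  # inclusive range
    noise_sd: float = 0.05
    texture: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.texture and self.n_classes > 256:
            raise ValueError(
                "flat rendering offers at most 256 distinguishable intensity "
                f"bands; got n_classes={self.n_classes} with texture=False"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.shapes_per_image
        if lo < 1 or hi < lo:
            raise ValueError("shapes_per_image must be a non-empty range")


#: default difficulty preset: 5 classes at 64x64, moderate noise
HELA_LIKE = SyntheticSpec()


def _class_intensity(label: int, c: int) -> float:
    """Flat intensity band for a class: evenly spaced in (0, 1]."""
    return label / (c - 1)


def _render_shape(mask, img, kind, label, intensity, rng, yy, xx):
    h, w = mask.shape
    s = min(h, w)
    r = rng.uniform(*_RADIUS_FRAC) * s
    cy = rng.uniform(r, h - r)
    cx = rng.uniform(r, w - r)
    if kind == "disc":
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    elif kind == "rect":
        ry = rng.uniform(*_RADIUS_FRAC) * s
        inside = (np.abs(yy - cy) <= ry) & (np.abs(xx - cx) <= r)
    else:  # ring
        q = rng.uniform(*_RING_INNER_FRAC)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = (d2 <= r ** 2) & (d2 > (q * r) ** 2)
    mask[inside] = label
    img[inside] = intensity


def generate_dataset(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the dataset; returns (images, masks).

    images: (N, H, W) float32 in [0, 1]; masks: (N, H, W) uint8 (or uint16
    past 255 classes).  Fully determined by ``spec.seed``; later shapes
    overdraw earlier ones.
    """
    rng = np.random.default_rng(spec.seed)
    c = spec.n_classes
    mask_dtype = np.uint8 if c <= 256 else np.uint16
    images = np.zeros((spec.n_images, spec.height, spec.width), dtype=np.float32)
    masks = np.zeros((spec.n_images, spec.height, spec.width), dtype=mask_dtype)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    for i in range(spec.n_images):
        img = images[i]
        msk = masks[i]
        n_shapes = int(rng.integers(spec.shapes_per_image[0],
                                    spec.shapes_per_image[1] + 1))
        for _ in range(n_shapes):
            label = int(rng.integers(1, c))
            kind = _SHAPES[rng.integers(len(_SHAPES))]
            intensity = _class_intensity(label, c)
            if spec.texture:
                # jitter within the class band, keeping bands disjoint
                intensity = np.clip(
                    intensity + rng.uniform(-0.3, 0.3) / (c - 1), 0.0, 1.0
                )
            _render_shape(msk, img, kind, label, intensity, rng, yy, xx)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
            np.clip(img, 0.0, 1.0, out=img)
    return images, masks


def expected_foreground_fraction(spec: SyntheticSpec) -> float:
    """Analytic expectation of the non-background pixel fraction.

    Treats shapes as independently, uniformly placed: with mean per-shape
    coverage f and mean shape count k the union covers 1 - (1 - f)^k of the
    frame in expectation.  Exact per-shape areas: E[pi r^2] for discs (r
    uniform on the radius range), 4 E[ry] E[rx] for rectangles, and the disc
    value scaled by 1 - E[q^2] for rings.
    """
    h, w = spec.height, spec.width
    s = min(h, w)
    a, b = (f * s for f in _RADIUS_FRAC)
    e_r = (a + b) / 2
    e_r2 = (a * a + a * b + b * b) / 3
    ql, qh = _RING_INNER_FRAC
    e_q2 = (ql * ql + ql * qh + qh * qh) / 3
    area_disc = np.pi * e_r2
    area_rect = 4 * e_r * e_r
    area_ring = area_disc * (1 - e_q2)
    f = (area_disc + area_rect + area_ring) / 3 / (h * w)
    k = (spec.shapes_per_image[0] + spec.shapes_per_image[1]) / 2
    return float(1.0 - (1.0 - f) ** k)


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the random affine family; degenerate ranges give identity."""

    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    shift_frac: tuple[float, float] = (-0.05, 0.05)
    scale: tuple[float, float] = (0.9, 1.1)
    shear_deg: tuple[float, float] = (-5.0, 5.0)
    seed: int = 0


def _sample_affine(params: AugmentParams, shape, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample one affine map about the image centre; returns (matrix, offset)
    in the output->input convention scipy's affine_transform uses."""
    theta = np.deg2rad(rng.uniform(*params.rotation_deg))
    shear = np.deg2rad(rng.uniform(*params.shear_deg))
    scale = rng.uniform(*params.scale)
    h, w = shape
    shift = np.array(
        [rng.uniform(*params.shift_frac) * h, rng.uniform(*params.shift_frac) * w]
    )
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    shr = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    fwd = scale * (rot @ shr)          # input -> output, about the centre
    inv = np.linalg.inv(fwd)
    centre = (np.array([h, w]) - 1) / 2.0
    offset = centre - inv @ (centre + shift)
    return inv, offset


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    params: AugmentParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one shared random affine transform to an image/mask pair.

    The identical geometric map is used for both; the image is resampled
    bilinearly and the mask nearest-neighbour so labels stay integral.
    Regions mapped in from outside the frame get background (label 0,
    intensity 0).
    """
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask shapes differ")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    matrix, offset = _sample_affine(params, mask.shape[:2], rng)
    out_img = ndimage.affine_transform(
        np.asarray(image, dtype=np.float32), matrix, offset=offset,
        order=1, mode="constant", cval=0.0,
    )
    out_mask = ndimage.affine_transform(
        mask, matrix, offset=offset, order=0, mode="constant", cval=0
    )
    return out_img, out_mask
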