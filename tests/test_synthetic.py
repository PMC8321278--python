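"""Synthetic dataset generator and joint image/mask augmentation."""

import numpy as np
import pytest

from abunet import AugmentParams, SyntheticSpec, augment_pair, generate_dataset
from abunet.synthetic import expected_foreground_fraction

IDENTITY = AugmentParams(
    rotation_deg=(0, 0), shift_frac=(0, 0), scale=(1, 1), shear_deg=(0, 0)
)


def test_generation_is_seed_deterministic():
    spec = SyntheticSpec(n_images=6, seed=123)
    a_img, a_msk = generate_dataset(spec)
    b_img, b_msk = generate_dataset(spec)
    np.testing.assert_array_equal(a_img, b_img)
    np.testing.assert_array_equal(a_msk, b_msk)
    c_img, _ = generate_dataset(SyntheticSpec(n_images=6, seed=124))
    assert not np.array_equal(a_img, c_img)


def test_counts_shapes_and_label_range():
    spec = SyntheticSpec(n_images=40, height=32, width=48, n_classes=4, seed=1)
    imgs, msks = generate_dataset(spec)
    assert imgs.shape == (40, 32, 48) and msks.shape == (40, 32, 48)
    assert imgs.min() >= 0.0 and imgs.max() <= 1.0
    assert msks.min() >= 0 and msks.max() < 4
    assert np.issubdtype(msks.dtype, np.integer)
    # every class should appear somewhere across 40 images
    assert set(np.unique(msks)) == {0, 1, 2, 3}


def test_noiseless_flat_intensity_is_function_of_label():
    spec = SyntheticSpec(n_images=10, noise_sd=0.0, texture=False, seed=2)
    imgs, msks = generate_dataset(spec)
    c = spec.n_classes
    for label in np.unique(msks):
        vals = imgs[msks == label]
        np.testing.assert_allclose(vals, label / (c - 1), atol=1e-7)


def test_foreground_fraction_near_analytic_expectation():
    spec = SyntheticSpec(n_images=100, noise_sd=0.0, seed=5)
    _, msks = generate_dataset(spec)
    observed = (msks > 0).mean()
    expected = expected_foreground_fraction(spec)
    assert abs(observed - expected) <= 0.2 * expected


def test_too_many_flat_classes_rejected():
    with pytest.raises(ValueError, match="distinguishable"):
        SyntheticSpec(n_classes=300, texture=False)


# ------------------------------------------------------------- augmentation


def test_identity_params_reproduce_pair_exactly():
    spec = SyntheticSpec(n_images=1, seed=8)
    imgs, msks = generate_dataset(spec)
    out_img, out_msk = augment_pair(imgs[0], msks[0], IDENTITY)
    np.testing.assert_array_equal(out_img, imgs[0])
    np.testing.assert_array_equal(out_msk, msks[0])


def test_augmented_mask_labels_subset_of_original_plus_background():
    spec = SyntheticSpec(n_images=4, seed=9)
    imgs, msks = generate_dataset(spec)
    params = AugmentParams(seed=1)
    for img, msk in zip(imgs, msks):
        _, out = augment_pair(img, msk, params)
        assert set(np.unique(out)) <= set(np.unique(msk)) | {0}
        assert out.dtype == msk.dtype


def test_double_180_rotation_restores_interior():
    spec = SyntheticSpec(n_images=1, noise_sd=0.0, seed=10)
    imgs, msks = generate_dataset(spec)
    rot180 = AugmentParams(
        rotation_deg=(180, 180), shift_frac=(0, 0), scale=(1, 1), shear_deg=(0, 0)
    )
    i1, m1 = augment_pair(imgs[0], msks[0], rot180)
    i2, m2 = augment_pair(i1, m1, rot180)
    interior = (slice(2, -2), slice(2, -2))
    np.testing.assert_allclose(i2[interior], imgs[0][interior], atol=1e-4)
    np.testing.assert_array_equal(m2[interior], msks[0][interior])


def test_same_transform_applied_to_image_and_mask():
    """With flat noiseless rendering the label->intensity map must survive
    any affine warp applied jointly."""
    spec = SyntheticSpec(n_images=1, noise_sd=0.0, texture=False, seed=11)
    imgs, msks = generate_dataset(spec)
    params = AugmentParams(seed=3)
    out_img, out_msk = augment_pair(imgs[0], msks[0], params)
    c = spec.n_classes
    # nearest-neighbour mask vs bilinear image: compare away from label edges
    from scipy import ndimage

    for label in np.unique(out_msk):
        core = ndimage.binary_erosion(out_msk == label, iterations=2)
        if core.any():
            np.testing.assert_allclose(
                out_img[core], label / (c - 1), atol=0.02
            )
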