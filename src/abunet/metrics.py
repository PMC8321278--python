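"""Segmentation overlap metrics.

The dice / Sorensen coefficient DSC = 2|a . b| / (|a|^2 + |b|^2) on binary
masks equals 2TP / (2TP + FP + FN), the F1 score of pixel classification.
Multi-class masks are scored as the macro average of one-vs-rest binary dice
over the classes present in the ground truth.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dice_binary", "dice_multiclass"]


def dice_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient of two binary masks.

    Both masks all-empty is scored 1.0 (the formula's 0/0 case): two raters
    who both found nothing agree perfectly.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not (_is_binary(a) and _is_binary(b)):
        raise ValueError("dice_binary requires masks with values in {0,1}")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _is_binary(m: np.ndarray) -> bool:
    if not np.issubdtype(m.dtype, np.number) and m.dtype != bool:
        return False
    return bool(np.isin(m, (0, 1)).all())


def dice_multiclass(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> float:
    """Macro-averaged one-vs-rest dice over classes present in ``truth``.

    Averaging only over classes the ground truth contains avoids crediting a
    prediction for omitting classes that were never there; background (class
    0) participates like any other class.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if not np.issubdtype(m.dtype, np.integer):
            raise ValueError(f"{name} mask must be integer-typed")
        if m.size and (m.min() < 0 or m.max() >= n_classes):
            raise ValueError(
                f"{name} mask labels outside [0, {n_classes - 1}]"
            )
    present = np.unique(truth)
    scores = [dice_binary(pred == k, truth == k) for k in present]
    return float(np.mean(scores))
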