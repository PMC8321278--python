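"""Image-level informativeness scores for active learning.

Every function reduces a predictive distribution to a single non-negative
score I(X) per image by summing a per-pixel information quantity (natural
log, so scores are in nats):

- ``score_entropy``        sum of per-pixel Shannon entropies of a
  probability map (usually the MC mean);
- ``score_bald``           mutual information between prediction and model
  posterior: entropy of the MC-mean distribution minus the mean per-pass
  entropy, summed over pixels;
- ``score_committee_kl``   KL(standard prediction || MC mean) summed over
  pixels — the information lost by approximating the deterministic
  prediction with the posterior average;
- ``score_committee_jsd``  the symmetric, bounded Jensen-Shannon divergence
  of the same pair.

Zero probabilities follow the exact convention 0*ln 0 = 0 (via ``xlogy``);
log denominators are floored at 1e-12 so KL stays finite when the committee
distributions have disjoint support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

__all__ = [
    "AcquisitionScore",
    "FUNCTION_NAMES",
    "pixel_entropy_map",
    "score_entropy",
    "score_bald",
    "score_committee_kl",
    "score_committee_jsd",
    "score_stack",
    "select_top_k",
]

FUNCTION_NAMES = ("entropy", "bald", "committee_kl", "committee_jsd")

_EPS = 1e-12  # floor for log denominators only


@dataclass(frozen=True)
class AcquisitionScore:
    image_id: object
    score: float
    function_name: str


def _entropy(p: np.ndarray) -> np.ndarray:
    """Shannon entropy in nats along the last axis, exact at zeros."""
    return -xlogy(p, p).sum(axis=-1)


def pixel_entropy_map(p: np.ndarray) -> np.ndarray:
    """Per-pixel entropy of an (H, W, c) probability map; values in [0, ln c]."""
    return _entropy(np.asarray(p, dtype=np.float64))


def score_entropy(p: np.ndarray) -> float:
    """Image informativeness as the sum of pixel entropies."""
    return float(pixel_entropy_map(p).sum())


def score_bald(stack: np.ndarray) -> float:
    """Mutual information between prediction and posterior, summed over pixels.

    stack: (T, H, W, c) probability maps from T stochastic passes.
    H[mean over passes] - mean over passes of H[pass]; non-negative by
    Jensen's inequality (floored at 0 against roundoff).
    """
    stack = np.asarray(stack, dtype=np.float64)
    mean_entropy_term = _entropy(stack.mean(axis=0)).sum()
    expected_entropy_term = _entropy(stack).sum(axis=(1, 2)).mean()
    return float(max(mean_entropy_term - expected_entropy_term, 0.0))


def _kl_terms(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Per-pixel KL(p || q); q floored at _EPS inside the log."""
    return (xlogy(p, p) - xlogy(p, np.maximum(q, _EPS))).sum(axis=-1)


def score_committee_kl(standard: np.ndarray, mc_mean: np.ndarray) -> float:
    """Sum over pixels of KL(standard || MC mean), in nats."""
    p = np.asarray(standard, dtype=np.float64)
    q = np.asarray(mc_mean, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"probability map shapes differ: {p.shape} vs {q.shape}")
    return float(max(_kl_terms(p, q).sum(), 0.0))


def score_committee_jsd(standard: np.ndarray, mc_mean: np.ndarray) -> float:
    """Sum over pixels of the Jensen-Shannon divergence of the committee pair.

    JSD(p, q) = KL(p || m)/2 + KL(q || m)/2 with m = (p + q)/2; symmetric and
    bounded by ln 2 per pixel.
    """
    p = np.asarray(standard, dtype=np.float64)
    q = np.asarray(mc_mean, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"probability map shapes differ: {p.shape} vs {q.shape}")
    m = 0.5 * (p + q)
    jsd = 0.5 * _kl_terms(p, m) + 0.5 * _kl_terms(q, m)
    return float(max(jsd.sum(), 0.0))


def score_stack(
    function_name: str,
    *,
    standard: np.ndarray | None = None,
    mc_mean: np.ndarray | None = None,
    stack: np.ndarray | None = None,
) -> float:
    """Dispatch a score by name from whichever inputs it needs."""
    if function_name == "entropy":
        return score_entropy(mc_mean if mc_mean is not None else standard)
    if function_name == "bald":
        return score_bald(stack)
    if function_name == "committee_kl":
        return score_committee_kl(standard, mc_mean)
    if function_name == "committee_jsd":
        return score_committee_jsd(standard, mc_mean)
    raise ValueError(f"unknown acquisition function {function_name!r}")


def select_top_k(scores: list[AcquisitionScore], k: int) -> list:
    """Ids of the k highest-scoring images.

    Ties are broken toward the smallest image id; k larger than the pool
    returns every id.
    """
    if not scores:
        raise ValueError("select_top_k needs a non-empty score list")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    names = {s.function_name for s in scores}
    if len(names) > 1:
        raise ValueError(f"mixed acquisition functions in one selection: {names}")
    ranked = sorted(scores, key=lambda s: (-s.score, s.image_id))
    return [s.image_id for s in ranked[:k]]
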