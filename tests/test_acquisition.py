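"""Acquisition scores vs closed forms and a scalar-loop brute-force oracle."""

import math

import numpy as np
import pytest

from abunet import (
    AcquisitionScore,
    pixel_entropy_map,
    score_bald,
    score_committee_jsd,
    score_committee_kl,
    score_entropy,
    select_top_k,
)
from conftest import random_probmap, random_stack

EPS = 1e-12

# ------------------------------------------------------- brute-force oracle
# Independent per-pixel scalar loops in pure Python; deliberately naive.


def brute_entropy(p):
    total = 0.0
    h, w, c = p.shape
    for i in range(h):
        for j in range(w):
            for k in range(c):
                v = p[i, j, k]
                if v > 0:
                    total -= v * math.log(v)
    return total


def brute_bald(stack):
    t, h, w, c = stack.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            mean = [sum(stack[a, i, j, k] for a in range(t)) / t for k in range(c)]
            hm = -sum(v * math.log(v) for v in mean if v > 0)
            hp = 0.0
            for a in range(t):
                hp -= sum(
                    stack[a, i, j, k] * math.log(stack[a, i, j, k])
                    for k in range(c)
                    if stack[a, i, j, k] > 0
                )
            total += hm - hp / t
    return total


def brute_kl(p, q):
    h, w, c = p.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            for k in range(c):
                if p[i, j, k] > 0:
                    total += p[i, j, k] * math.log(
                        p[i, j, k] / max(q[i, j, k], EPS)
                    )
    return total


def brute_jsd(p, q):
    m = 0.5 * (p + q)
    return 0.5 * brute_kl(p, m) + 0.5 * brute_kl(q, m)


# ------------------------------------------------------------- closed forms


def test_pixel_entropy_closed_forms():
    p = np.array([[[0.5, 0.5]]])
    assert abs(pixel_entropy_map(p)[0, 0] - math.log(2)) < 1e-12
    p = np.array([[[1.0, 0.0, 0.0]]])
    assert pixel_entropy_map(p)[0, 0] == 0.0
    p = np.array([[[0.9, 0.1]]])
    expected = -(0.9 * math.log(0.9) + 0.1 * math.log(0.1))
    assert abs(pixel_entropy_map(p)[0, 0] - expected) < 1e-12


def test_entropy_image_sum():
    p = np.full((2, 2, 2), 0.5)
    assert abs(score_entropy(p) - 4 * math.log(2)) < 1e-12
    onehot = np.zeros((3, 3, 4))
    onehot[..., 1] = 1.0
    assert score_entropy(onehot) == 0.0


def test_bald_closed_forms():
    # identical passes -> zero mutual information
    stack = np.full((5, 2, 2, 2), 0.5)
    assert score_bald(stack) == 0.0
    # two opposing one-hot passes -> ln 2 per pixel
    stack = np.zeros((2, 1, 1, 2))
    stack[0, 0, 0] = [1.0, 0.0]
    stack[1, 0, 0] = [0.0, 1.0]
    assert abs(score_bald(stack) - math.log(2)) < 1e-12


def test_kl_closed_forms():
    p = np.array([[[1.0, 0.0]]])
    q = np.array([[[0.5, 0.5]]])
    assert abs(score_committee_kl(p, q) - math.log(2)) < 1e-12
    assert score_committee_kl(q, q) == 0.0


def test_jsd_closed_forms():
    p = np.array([[[1.0, 0.0]]])
    q = np.array([[[0.0, 1.0]]])
    assert abs(score_committee_jsd(p, q) - math.log(2)) < 1e-12
    assert score_committee_jsd(p, p) == 0.0


# ------------------------------------------------------- oracle equivalence


def test_all_scores_match_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(8):
        stack = random_stack(rng, 8, 16, 16, 3)
        standard = random_probmap(rng, 16, 16, 3)
        mean = stack.mean(axis=0)
        pairs = [
            (score_entropy(mean), brute_entropy(mean)),
            (score_bald(stack), brute_bald(stack)),
            (score_committee_kl(standard, mean), brute_kl(standard, mean)),
            (score_committee_jsd(standard, mean), brute_jsd(standard, mean)),
        ]
        for got, want in pairs:
            assert abs(got - want) <= 1e-10 * max(1.0, abs(want))


# ------------------------------------------------------- bounds & invariance


def test_bounds_on_random_draws():
    rng = np.random.default_rng(7)
    c = 4
    for _ in range(1000):
        stack = random_stack(rng, 3, 2, 2, c)
        standard = random_probmap(rng, 2, 2, c)
        mean = stack.mean(axis=0)
        ent = score_entropy(mean)
        assert ent <= 2 * 2 * math.log(c) + 1e-12
        bald = score_bald(stack)
        assert 0.0 <= bald <= ent + 1e-12
        assert score_committee_kl(standard, mean) >= 0.0
        jsd = score_committee_jsd(standard, mean)
        assert 0.0 <= jsd <= 2 * 2 * math.log(2) + 1e-12
        assert abs(jsd - score_committee_jsd(mean, standard)) < 1e-12


def test_scores_invariant_under_class_permutation():
    rng = np.random.default_rng(3)
    stack = random_stack(rng, 4, 6, 6, 3)
    standard = random_probmap(rng, 6, 6, 3)
    mean = stack.mean(axis=0)
    perm = [2, 0, 1]
    assert np.isclose(score_entropy(mean), score_entropy(mean[..., perm]))
    assert np.isclose(score_bald(stack), score_bald(stack[..., perm]))
    assert np.isclose(
        score_committee_kl(standard, mean),
        score_committee_kl(standard[..., perm], mean[..., perm]),
    )
    assert np.isclose(
        score_committee_jsd(standard, mean),
        score_committee_jsd(standard[..., perm], mean[..., perm]),
    )


# ------------------------------------------------------------- selection


def _scores(vals, name="entropy"):
    return [AcquisitionScore(i, v, name) for i, v in vals.items()]


def test_select_top_k_orders_by_score():
    assert select_top_k(_scores({0: 3.0, 1: 1.0, 2: 2.0}), 1) == [0]
    assert select_top_k(_scores({0: 3.0, 1: 1.0, 2: 2.0}), 2) == [0, 2]


def test_select_top_k_ties_break_to_smallest_id():
    assert select_top_k(_scores({3: 1.0, 1: 1.0, 2: 1.0}), 2) == [1, 2]


def test_select_top_k_clamps_to_pool():
    assert sorted(select_top_k(_scores({0: 1.0, 1: 2.0, 2: 3.0}), 10)) == [0, 1, 2]


def test_select_top_k_rejects_bad_input():
    with pytest.raises(ValueError, match="non-empty"):
        select_top_k([], 1)
    with pytest.raises(ValueError, match="mixed"):
        select_top_k(
            [AcquisitionScore(0, 1.0, "entropy"), AcquisitionScore(1, 1.0, "bald")],
            1,
        )
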