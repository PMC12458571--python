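"""Regional enrichment: K-S running statistic and ROI permutation test."""

import itertools
import math

import numpy as np
import pytest

from udrwm import (
    LabelAtlas,
    ks_enrichment,
    ks_statistic,
    rank_voxels,
    roi_permutation_test,
    tissue_enrichment,
)
from udrwm.volumes import Volume3D


def brute_force_ks(ranked_membership):
    """Independent oracle: enumerate the running curve for every n."""
    member = list(ranked_membership)
    N = len(member)
    V = sum(member)
    best = -math.inf
    k = 0
    for n in range(1, N + 1):
        k += int(member[n - 1])
        best = max(best, k / V - n / N)
    return best


def _atlas_1d(labels_flat, shape=None):
    labels_flat = np.asarray(labels_flat)
    shape = shape or (labels_flat.size, 1, 1)
    return LabelAtlas(labels_flat.reshape(shape), np.eye(4))


def _vol(t_flat, shape=None):
    t_flat = np.asarray(t_flat, dtype=float)
    shape = shape or (t_flat.size, 1, 1)
    return Volume3D(t_flat.reshape(shape), np.eye(4))


def test_rank_order_and_ties():
    atlas = _atlas_1d([1, 1, 1])
    order, t_flat, labels = rank_voxels(_vol([3.0, 1.0, 2.0]), atlas)
    np.testing.assert_array_equal(order, [0, 2, 1])
    # all-equal map: scan order preserved (stable tie rule)
    order2, *_ = rank_voxels(_vol([5.0, 5.0, 5.0]), atlas)
    np.testing.assert_array_equal(order2, [0, 1, 2])


def test_rank_covers_labeled_only():
    atlas = _atlas_1d([0, 1, 0, 2, 1])
    order, t_flat, labels = rank_voxels(_vol([9, 1, 9, 2, 3]), atlas)
    assert len(order) == 3  # N = labeled voxels only
    assert set(labels) == {1, 2}


def test_ks_worked_examples():
    """Top-ranked 3-of-10 region scores 0.7; ranks {2,4} of 5 score 0.2."""
    member10 = np.zeros(10, dtype=bool)
    member10[:3] = True
    assert ks_statistic(member10) == pytest.approx(0.7)

    member5 = np.array([False, True, False, True, False])
    assert ks_statistic(member5) == pytest.approx(0.2)


def test_ks_self_enrichment_zero():
    """A region equal to the whole ranking scores exactly 0."""
    assert ks_statistic(np.ones(7, dtype=bool)) == pytest.approx(0.0)


def test_ks_matches_bruteforce_random():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        N = int(rng.integers(2, 51))
        member = rng.random(N) < rng.uniform(0.1, 0.9)
        if not member.any():
            member[int(rng.integers(N))] = True
        assert ks_statistic(member) == pytest.approx(brute_force_ks(member))


def test_ks_monotone_invariance(rng):
    """K-S is rank-based: any strictly monotone transform leaves it unchanged."""
    labels = rng.integers(1, 4, size=60)
    t = rng.random(60)
    atlas = _atlas_1d(labels)
    base = ks_enrichment(_vol(t), atlas).table
    transformed = ks_enrichment(_vol(np.exp(3 * t) + 5), atlas).table
    np.testing.assert_allclose(base["ks"], transformed["ks"], atol=1e-12)


def test_permutation_constant_map_p_one():
    atlas = _atlas_1d([1, 1, 2, 2, 1, 2])
    res = roi_permutation_test(_vol(np.full(6, 2.5)), atlas, n_perm=99, seed=1)
    assert (res.table["p_raw"] == 1.0).all()
    assert (res.table["p_bonf"] == 1.0).all()


def test_permutation_p_floor():
    """Minimum attainable raw p is 1/(n_perm+1), reached when no permuted
    statistic matches the observed one."""
    # 10 high voxels concentrated in a 10-voxel region among 200: the chance
    # a shuffle puts >= 5 highs back into the region is ~6e-8, so with 500
    # shuffles the exceedance count is 0 and p sits exactly at the floor
    labels = np.array([1] * 10 + [2] * 190)
    t = np.array([100.0] * 10 + [0.0] * 190)
    res = roi_permutation_test(_vol(t), _atlas_1d(labels), n_perm=500, seed=2)
    p1 = float(res.table[res.table.region_id == 1]["p_raw"].iloc[0])
    assert p1 == pytest.approx(1 / 501)
    assert (res.table["p_raw"] >= 1 / 501 - 1e-15).all()


def test_permutation_matches_exhaustive_enumeration():
    """2 regions x 2 voxels, |t| = (10,10,0,0): P(median >= 10 in region 1)
    = 1/6 by exhaustive assignment; Monte-Carlo converges to the add-one
    smoothed value."""
    labels = np.array([1, 1, 2, 2])
    t = np.array([10.0, 10.0, 0.0, 0.0])

    # exhaustive oracle over all distinct assignments
    hits = 0
    total = 0
    for perm in set(itertools.permutations(t)):
        total += 1
        if np.median(perm[:2]) >= 10.0:
            hits += 1
    assert hits / total == pytest.approx(1 / 6)

    n_perm = 6000
    res = roi_permutation_test(_vol(t), _atlas_1d(labels), n_perm=n_perm, seed=3)
    p1 = float(res.table[res.table.region_id == 1]["p_raw"].iloc[0])
    expected = (1 + n_perm / 6) / (n_perm + 1)
    assert p1 == pytest.approx(expected, abs=0.02)


def test_permutation_exhaustive_small_instances(rng):
    """Monte-Carlo p converges to the exact permutation tail on <= 8 voxels."""
    for trial in range(3):
        N = 6
        labels = np.array([1, 1, 1, 2, 2, 2])
        t = np.round(rng.random(N), 3)
        exact = {}
        for r, sl in [(1, slice(0, 3)), (2, slice(3, 6))]:
            obs = np.median(t[sl])
            hits = sum(np.median(np.array(p)[sl]) >= obs for p in itertools.permutations(t))
            exact[r] = hits / math.factorial(N)
        res = roi_permutation_test(_vol(t), _atlas_1d(labels), n_perm=4000, seed=trial)
        for r in (1, 2):
            mc = float(res.table[res.table.region_id == r]["p_raw"].iloc[0])
            assert mc == pytest.approx((1 + 4000 * exact[r]) / 4001, abs=0.03)


def test_permutation_super_uniform_under_null():
    """On i.i.d. voxel maps, raw per-region p-values are super-uniform."""
    rng = np.random.default_rng(7)
    labels = np.repeat([1, 2, 3, 4], 25)
    alpha = 0.05
    n_rep = 100
    rejections = 0
    for rep in range(n_rep):
        t = rng.standard_normal(100)
        res = roi_permutation_test(_vol(t), _atlas_1d(labels), n_perm=199, seed=rep)
        rejections += int((res.table["p_raw"] <= alpha).sum())
    rate = rejections / (n_rep * 4)
    assert rate <= alpha + 0.03, rate


def test_bonferroni_factor_is_tested_regions():
    labels = np.array([1, 1, 5, 5, 9, 9])
    res = roi_permutation_test(_vol(np.arange(6.0)), _atlas_1d(labels), n_perm=19, seed=0)
    assert res.bonferroni_factor == 3
    np.testing.assert_allclose(
        res.table["p_bonf"], np.minimum(1.0, 3 * res.table["p_raw"])
    )


def test_tissue_enrichment_delegates():
    rng = np.random.default_rng(5)
    labels = rng.integers(1, 4, size=50)
    t = rng.random(50)
    a = _atlas_1d(labels)
    np.testing.assert_allclose(
        tissue_enrichment(_vol(t), a).table["ks"], ks_enrichment(_vol(t), a).table["ks"]
    )


def test_tissue_enrichment_supported_class_wins():
    labels = np.array([1] * 10 + [2] * 10 + [3] * 10)
    t = np.zeros(30)
    t[:10] = np.linspace(1, 2, 10)  # support only on class 1
    res = tissue_enrichment(_vol(t), _atlas_1d(labels))
    tab = res.table.set_index("region_id")
    assert tab.loc[1, "ks"] == tab["ks"].max()


def test_tissue_enrichment_needs_two_classes():
    with pytest.raises(ValueError):
        tissue_enrichment(_vol(np.ones(4)), _atlas_1d([1, 1, 1, 1]))


def test_constant_map_random_tiebreak_scores_near_zero():
    """Under random tie-shuffling a constant map has no real enrichment."""
    labels = np.repeat([1, 2, 3], 40)
    t = np.ones(120)
    scores = []
    for seed in range(30):
        tab = ks_enrichment(_vol(t), _atlas_1d(labels), tie_break_seed=seed).table
        scores.append(tab["ks"].mean())
    assert np.mean(scores) < 0.15
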