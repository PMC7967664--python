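"""Factor/ecological/interaction detectors, natural breaks, grid sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from geodrivers.errors import NumericalError, ValidationError
from geodrivers.geodetector import (StrataAssignment,
                                    discretize_natural_breaks,
                                    ecological_detector, factor_q,
                                    grid_sample, interaction_detector)


def naive_q(y, labels):
    """Group-by oracle for the q statistic (population variances)."""
    y = np.asarray(y, float)
    N = len(y)
    ssw = 0.0
    for h in np.unique(labels):
        sub = y[np.asarray(labels) == h]
        ssw += len(sub) * sub.var()
    return 1.0 - ssw / (N * y.var())


def exhaustive_jenks_ssw(values, k):
    """Minimum within-class SSD over all ordered partitions (brute force)."""
    xs = np.sort(np.asarray(values, float))
    n = len(xs)
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = (0,) + cuts + (n,)
        ssw = sum(xs[a:b].var() * (b - a) for a, b in zip(edges, edges[1:]))
        best = min(best, ssw)
    return best


# ---------------------------------------------------------------------------
# natural breaks


def test_breaks_separate_obvious_clusters():
    s = discretize_natural_breaks([1, 2, 3, 10, 11, 12], 2)
    assert s.L == 2
    assert s.labels.tolist() == [0, 0, 0, 1, 1, 1]


def test_saturated_classification_zero_ssw():
    vals = [3.0, 1.0, 7.0, 5.0]
    s = discretize_natural_breaks(vals, 4)
    assert len(np.unique(s.labels)) == 4
    assert naive_q(vals, s.labels) == pytest.approx(1.0)


def test_breaks_match_exhaustive_partition_search(rng):
    for n, k in [(8, 2), (10, 3), (12, 4)]:
        vals = rng.normal(size=n) * 10
        s = discretize_natural_breaks(vals, k)
        ssw = sum(vals[s.labels == h].var() * (s.labels == h).sum()
                  for h in range(k))
        assert ssw == pytest.approx(exhaustive_jenks_ssw(vals, k), abs=1e-9)


def test_breaks_errors():
    with pytest.raises(ValidationError):
        discretize_natural_breaks([1, 1, 1], 2)
    with pytest.raises(ValueError):
        discretize_natural_breaks([1, 2, 3], 1)


# ---------------------------------------------------------------------------
# factor detector


def test_worked_four_point_example():
    res = factor_q([1, 2, 3, 4], StrataAssignment.from_categories(list("AABB")))
    assert res.q == pytest.approx(0.8, abs=1e-12)


def test_q_limits():
    assert factor_q([1, 2, 3, 4],
                    StrataAssignment.from_categories(list("AAAA"))).q == 0.0
    res = factor_q([5, 5, 9, 9],
                   StrataAssignment.from_categories(list("AABB")))
    assert res.q == pytest.approx(1.0)
    assert res.p == pytest.approx(0.0, abs=1e-12)


def test_q_matches_groupby_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(20, 50))
        y = rng.normal(size=n)
        labels = rng.integers(0, 4, size=n)
        labels[:4] = np.arange(4)
        s = StrataAssignment(labels=labels, L=4)
        assert factor_q(y, s).q == pytest.approx(naive_q(y, labels), abs=1e-12)


def test_q_affine_invariance(rng):
    y = rng.normal(size=60)
    labels = rng.integers(0, 3, size=60)
    labels[:3] = np.arange(3)
    s = StrataAssignment(labels=labels, L=3)
    assert factor_q(2.5 * y - 7, s).q == pytest.approx(factor_q(y, s).q,
                                                       abs=1e-12)


def test_refining_strata_never_decreases_q(rng):
    y = rng.normal(size=80)
    labels = rng.integers(0, 3, size=80)
    labels[:3] = np.arange(3)
    coarse = StrataAssignment(labels=labels, L=3)
    # split stratum 0 randomly in two
    fine_labels = labels.copy()
    zero = np.where(labels == 0)[0]
    fine_labels[zero[: len(zero) // 2]] = 3
    fine = StrataAssignment(labels=fine_labels, L=4)
    assert factor_q(y, fine).q >= factor_q(y, coarse).q - 1e-12


def test_q_zero_variance_errors():
    s = StrataAssignment.from_categories(list("AABB"))
    with pytest.raises(NumericalError):
        factor_q([1, 1, 1, 1], s)


def test_permutation_p_agrees_qualitatively(rng):
    y = np.concatenate([rng.normal(0, 1, 100), rng.normal(3, 1, 100)])
    labels = np.repeat([0, 1], 100)
    s = StrataAssignment(labels=labels, L=2)
    a = factor_q(y, s)
    b = factor_q(y, s, p_method="permutation", n_perm=199, seed=3)
    assert a.p < 0.01 and b.p < 0.01


# ---------------------------------------------------------------------------
# ecological detector


def test_ecological_self_comparison_not_significant(rng):
    y = rng.normal(size=50)
    labels = rng.integers(0, 3, 50)
    labels[:3] = np.arange(3)
    s = StrataAssignment(labels=labels, L=3)
    sig, F, _ = ecological_detector(y, s, s)
    assert not sig
    assert F == pytest.approx(1.0)


def test_ecological_extreme_separation(rng):
    n = 200
    means = np.repeat([0.0, 10.0, 20.0, 30.0], n // 4)
    y = means + rng.normal(0, 0.1, n)
    good = StrataAssignment(labels=np.repeat(np.arange(4), n // 4), L=4)
    bad = StrataAssignment(labels=np.tile(np.arange(4), n // 4), L=4)
    sig, F, p = ecological_detector(y, good, bad)
    assert sig and F > 1 and p < 1e-6


def test_ecological_invariant_to_stratum_relabeling(rng):
    y = rng.normal(size=60)
    la = rng.integers(0, 3, 60)
    la[:3] = np.arange(3)
    lb = rng.integers(0, 4, 60)
    lb[:4] = np.arange(4)
    sA = StrataAssignment(labels=la, L=3)
    sA2 = StrataAssignment(labels=(2 - la), L=3)  # relabel
    sB = StrataAssignment(labels=lb, L=4)
    assert ecological_detector(y, sA, sB)[:2] == ecological_detector(y, sA2, sB)[:2]


# ---------------------------------------------------------------------------
# interaction detector


def test_overlay_with_constant_factor_is_identity(rng):
    y = rng.normal(size=40)
    la = rng.integers(0, 3, 40)
    la[:3] = np.arange(3)
    sA = StrataAssignment(labels=la, L=3)
    sB = StrataAssignment(labels=np.zeros(40, dtype=int), L=1)
    qAB, cls, qA, qB = interaction_detector(y, sA, sB)
    assert qAB == pytest.approx(qA, abs=1e-12)


def test_additive_two_factor_field_enhances(rng):
    n = 400
    a = rng.integers(0, 4, n)
    b = rng.integers(0, 4, n)
    a[:4] = np.arange(4); b[-4:] = np.arange(4)
    y = 2.0 * a + 3.0 * b + rng.normal(0, 0.5, n)
    sA = StrataAssignment(labels=a, L=4)
    sB = StrataAssignment(labels=b, L=4)
    qAB, cls, qA, qB = interaction_detector(y, sA, sB)
    assert qAB > max(qA, qB)
    assert cls in ("bi_enhance", "nonlinear_enhance")


def test_overlay_q_matches_groupby_oracle(rng):
    y = rng.normal(size=100)
    a = rng.integers(0, 3, 100); a[:3] = np.arange(3)
    b = rng.integers(0, 3, 100); b[-3:] = np.arange(3)
    sA = StrataAssignment(labels=a, L=3)
    sB = StrataAssignment(labels=b, L=3)
    qAB, *_ = interaction_detector(y, sA, sB)
    pair_labels = [f"{i}-{j}" for i, j in zip(a, b)]
    assert qAB == pytest.approx(naive_q(y, pair_labels), abs=1e-12)


# ---------------------------------------------------------------------------
# grid sampling


def test_square_yields_expected_lattice_count():
    geoms = {"A": box(0, 0, 20, 20)}
    vals = pd.DataFrame({"y": [7.0]}, index=["A"])
    gs = grid_sample(geoms, vals, 10.0)
    assert len(gs.points) == 4
    assert (gs.values["y"] == 7.0).all()


def test_point_attributes_inherited_from_unit():
    geoms = {"A": box(0, 0, 10, 10), "B": box(10, 0, 20, 10)}
    vals = pd.DataFrame({"y": [1.0, 2.0]}, index=["A", "B"])
    gs = grid_sample(geoms, vals, 5.0)
    for pt, val in zip(gs.points, gs.values["y"]):
        expected = 1.0 if pt[0] < 10 else 2.0
        assert val == expected


def test_halving_spacing_quadruples_count():
    geoms = {"A": box(0, 0, 40, 40)}
    vals = pd.DataFrame({"y": [0.0]}, index=["A"])
    n1 = len(grid_sample(geoms, vals, 10.0).points)
    n2 = len(grid_sample(geoms, vals, 5.0).points)
    assert n2 == pytest.approx(4 * n1, rel=0.3)


def test_no_point_in_any_unit_errors():
    geoms = {"A": box(0, 0, 1, 1)}
    vals = pd.DataFrame({"y": [0.0]}, index=["A"])
    with pytest.raises(NumericalError, match="spacing"):
        grid_sample(geoms, vals, 50.0)
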