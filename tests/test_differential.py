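"""Kruskal-Wallis screening, BH adjustment and the NB count test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from soiltrace import bh_adjust, kruskal_screen, marker_set, nb_test, shared_features, size_factors
from soiltrace.differential import TIE

from conftest import make_counts, make_relative


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_empty(self):
        assert len(bh_adjust([])) == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_dominates_p(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)
        shuffled = list(reversed(ps))
        assert sorted(bh_adjust(shuffled)) == pytest.approx(sorted(q))


class TestKruskalScreen:
    def screen(self, cols, labels):
        rows = np.array(cols).T
        rows = rows / rows.sum(axis=1, keepdims=True)
        return kruskal_screen(make_relative(rows), np.asarray(labels))

    def test_constant_feature_never_marker(self):
        t = make_relative(np.tile([0.5, 0.5], (6, 1)))
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        res = kruskal_screen(t, labels)
        assert all(r.p_value == 1.0 for r in res)
        assert len(marker_set(res, "x", 0.05)) == 0

    def test_p_matches_scipy_kruskal(self):
        col = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        other = 100 - col
        rows = np.stack([col, other], axis=1)
        rows /= rows.sum(axis=1, keepdims=True)
        labels = np.repeat(["a", "b", "c"], 3)
        res = kruskal_screen(make_relative(rows), labels)
        h, p = stats.kruskal(col[:3], col[3:6], col[6:])
        assert h == pytest.approx(7.2)  # textbook no-tie value
        feat = [r for r in res if r.feature_id == "f0"][0]
        assert feat.p_value == pytest.approx(p)
        assert feat.enriched_group == "c"

    def test_within_group_permutation_leaves_p_unchanged(self, rng):
        rows = rng.dirichlet(np.ones(5), size=9)
        labels = np.repeat(["a", "b", "c"], 3)
        r1 = kruskal_screen(make_relative(rows), labels)
        shuffled = rows.copy()
        shuffled[[0, 1, 2]] = shuffled[[2, 0, 1]]  # permute within group a
        r2 = kruskal_screen(make_relative(shuffled), labels)
        assert [x.p_value for x in r1] == pytest.approx([x.p_value for x in r2])

    def test_null_p_values_uniform(self, rng):
        # label-shuffled data: KS test against uniform over 500 features
        n, m = 24, 500
        rows = rng.dirichlet(np.ones(m), size=n)
        labels = rng.permutation(np.repeat(["a", "b", "c"], 8))
        res = kruskal_screen(make_relative(rows), labels)
        ps = [r.p_value for r in res]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_absent_feature_excluded(self):
        rows = np.array([[0.5, 0.5, 0.0], [0.4, 0.6, 0.0], [0.3, 0.7, 0.0], [0.2, 0.8, 0.0]])
        res = kruskal_screen(make_relative(rows), np.array(["a", "a", "b", "b"]))
        assert {r.feature_id for r in res} == {"f0", "f1"}


def test_shared_features_requires_presence_in_every_group():
    rows = np.array(
        [[0.5, 0.5, 0.0], [0.6, 0.4, 0.0], [0.2, 0.4, 0.4], [0.3, 0.3, 0.4]]
    )
    t = make_relative(rows)
    feats = shared_features(t, np.array(["a", "a", "b", "b"]))
    assert feats == ["f0", "f1"]


class TestNbTest:
    def test_size_factors_median_of_ratios(self, rng):
        base = rng.integers(10, 100, size=12).astype(float)
        counts = np.stack([base, 2 * base])
        sf = size_factors(counts)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_planted_tenfold_shift_detected(self, rng):
        n, m = 10, 60
        mu = rng.uniform(20, 200, size=m)
        counts = rng.poisson(np.tile(mu, (2 * n, 1))).astype(float)
        counts[n:, 0] = rng.poisson(mu[0] * 10, size=n)  # planted shift
        t = make_counts(counts)
        res = nb_test(t, np.array(["a"] * n + ["b"] * n))
        hit = [r for r in res if r.feature_id == "f0"][0]
        assert hit.q_value < 0.05
        assert hit.enriched_group == "b"
        assert hit.group_means["b"] > 5 * hit.group_means["a"]

    def test_type_one_error_calibrated(self, rng):
        # all features from one NB(mu, alpha): rejection rate at p<0.05
        # should sit near nominal (3 binomial SEs over 2000 features)
        n_per, m = 10, 2000
        mu, alpha = 80.0, 0.1
        lam = rng.gamma(1 / alpha, mu * alpha, size=(3 * n_per, m))
        counts = rng.poisson(lam).astype(float)
        res = nb_test(make_counts(counts), np.repeat(["a", "b", "c"], n_per))
        rate = np.mean([r.p_value < 0.05 for r in res])
        se = np.sqrt(0.05 * 0.95 / m)
        assert abs(rate - 0.05) < 3 * se

    def test_all_zero_feature_excluded(self, rng):
        counts = rng.poisson(50, size=(8, 5)).astype(float)
        counts[:, 2] = 0
        res = nb_test(make_counts(counts), np.array(["a"] * 4 + ["b"] * 4))
        assert {r.feature_id for r in res} == {"f0", "f1", "f3", "f4"}


def test_direction_tie_handling():
    rows = np.array([[0.5, 0.5], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5]])
    res = kruskal_screen(make_relative(rows), np.array(["a", "a", "b", "b"]))
    assert all(r.enriched_group == TIE for r in res)
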