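"""Histogram construction and the classic / restricted Otsu objectives.

The exhaustive solvers are checked against independent naive enumerations
written here in plain Python, so the test-side oracle shares no code with the
implementation.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbotsu.histogram import (
    EmptyRangeError,
    GrayHistogram,
    NoSeparationError,
    between_class_variance_single,
    compute_histogram,
    exhaustive_otsu_multi,
    exhaustive_otsu_single,
    multi_otsu_objective,
    restrict_histogram,
)


# --- independent naive oracles (plain python, no shared code) ---------------


def naive_objective(counts, th, thresholds, levels):
    """Restricted between-class variance by direct summation."""
    n_r = sum(counts[i] for i in range(th + 1, levels))
    p = {i: counts[i] / n_r for i in range(th + 1, levels)}
    mu = sum(i * pi for i, pi in p.items())
    edges = [th, *thresholds, levels - 1]
    j = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        w = sum(p.get(i, 0.0) for i in range(a + 1, b + 1))
        if w > 0:
            m = sum(i * p.get(i, 0.0) for i in range(a + 1, b + 1)) / w
            j += w * (m - mu) ** 2
    return j


def naive_best(counts, th, q, levels):
    best_t, best_v = None, -1.0
    for t in itertools.combinations(range(th + 1, levels), q):
        v = naive_objective(counts, th, t, levels)
        if v > best_v + 1e-12:
            best_t, best_v = t, v
    return best_t, best_v


# --- construction -----------------------------------------------------------


class TestComputeHistogram:
    @pytest.mark.parametrize(
        "pixels, expect",
        [
            ([[5, 5], [5, 5]], {5: 4}),
            ([[0, 0], [255, 255]], {0: 2, 255: 2}),
            ([[10, 10, 20]], {10: 2, 20: 1}),
        ],
    )
    def test_counts(self, pixels, expect):
        hist = compute_histogram(np.array(pixels))
        for level, count in expect.items():
            assert hist.counts[level] == count
        assert hist.total == np.asarray(pixels).size
        np.testing.assert_allclose(hist.probabilities.sum(), 1.0, atol=1e-12)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            compute_histogram(np.empty((0, 3), dtype=np.int64))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_histogram(np.array([[0, 300]]))

    def test_csv_round_trip(self, tmp_path):
        hist = GrayHistogram.from_counts({3: 7, 200: 11})
        path = tmp_path / "hist.csv"
        hist.to_csv(path)
        back = GrayHistogram.from_csv(path)
        np.testing.assert_array_equal(back.counts, hist.counts)


class TestRestrictHistogram:
    def test_direct_split(self):
        hist = GrayHistogram.from_counts({0: 2, 255: 2})
        rh = restrict_histogram(hist, 100)
        assert rh.n_l == 2 and rh.n_r == 2
        assert rh.p_r[255] == 1.0

    def test_conditional_probabilities(self):
        hist = GrayHistogram.from_counts({100: 3, 200: 1, 250: 2})
        rh = restrict_histogram(hist, 150)
        assert rh.n_r == 3
        np.testing.assert_allclose(rh.p_r[200], 1 / 3)
        np.testing.assert_allclose(rh.p_r[250], 2 / 3)
        np.testing.assert_allclose(rh.p_r.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(rh.p_l.sum(), 1.0, atol=1e-12)

    def test_empty_range_signal(self):
        hist = GrayHistogram.from_counts({10: 5})
        with pytest.raises(EmptyRangeError):
            restrict_histogram(hist, 254)


# --- single-threshold objective ---------------------------------------------


class TestSingleThreshold:
    def test_two_delta_closed_form(self):
        # equal mass at 0 and 255: mG = 127.5, P1 = .5, m(k) = 0 for any k < 255
        hist = GrayHistogram.from_counts({0: 2, 255: 2})
        for k in (0, 100, 254):
            np.testing.assert_allclose(
                between_class_variance_single(hist, k), 16256.25
            )

    def test_degenerate_partition_is_zero(self):
        hist = GrayHistogram.from_counts({77: 9})
        assert between_class_variance_single(hist, 100) == 0.0

    def test_equivalent_two_class_form(self):
        # sigma_B^2 via the cumulative form equals P1*P2*(m1-m2)^2
        hist = GrayHistogram.from_counts({0: 1, 100: 3})
        assert between_class_variance_single(hist, 50) == pytest.approx(1875.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_decomposition_identity(self, seed):
        """Eq-5-style decomposition equals the cumulative form for random histograms."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, size=256)
        counts[rng.integers(0, 256)] += 1  # nonempty
        hist = GrayHistogram(counts=counts.astype(np.int64))
        p = hist.probabilities
        idx = np.arange(256)
        m_g = (idx * p).sum()
        for k in rng.integers(0, 255, size=8):
            p1 = p[: k + 1].sum()
            got = between_class_variance_single(hist, int(k))
            if p1 <= 0 or p1 >= 1:
                assert got == 0.0
                continue
            m1 = (idx[: k + 1] * p[: k + 1]).sum() / p1
            m2 = (idx[k + 1 :] * p[k + 1 :]).sum() / (1 - p1)
            expect = p1 * (m1 - m_g) ** 2 + (1 - p1) * (m2 - m_g) ** 2
            np.testing.assert_allclose(got, expect, rtol=1e-9, atol=1e-9)

    def test_exhaustive_ties_break_small(self):
        hist = GrayHistogram.from_counts({0: 2, 255: 2})
        k, v = exhaustive_otsu_single(hist)
        assert (k, v) == (0, pytest.approx(16256.25))
        hist = GrayHistogram.from_counts({10: 2, 200: 2})
        assert exhaustive_otsu_single(hist)[0] == 10

    def test_exhaustive_matches_naive_loop(self, rng):
        from conftest import random_histogram

        for _ in range(5):
            hist = random_histogram(rng, occupied=16)
            naive = max(
                range(256 - 1),
                key=lambda k: (round(between_class_variance_single(hist, k), 12), -k),
            )
            k, _ = exhaustive_otsu_single(hist)
            assert between_class_variance_single(hist, k) == pytest.approx(
                between_class_variance_single(hist, naive)
            )

    def test_single_level_no_separation(self):
        with pytest.raises(NoSeparationError):
            exhaustive_otsu_single(GrayHistogram.from_counts({42: 10}))


# --- multi-threshold objective ----------------------------------------------


class TestMultiObjective:
    def test_one_class_partition_is_zero(self):
        hist = GrayHistogram.from_counts({160: 5, 170: 5})
        rh = restrict_histogram(hist, 150)
        assert multi_otsu_objective(rh, (255, 255, 255, 255)) == pytest.approx(0.0)

    def test_perfect_separation_attains_total_variance(self):
        hist = GrayHistogram.from_counts({160: 2, 180: 2, 200: 2, 220: 2, 250: 2})
        rh = restrict_histogram(hist, 150)
        idx = np.arange(256)
        p = rh.p_r
        mu = (idx * p).sum()
        total_var = (p * (idx - mu) ** 2).sum()
        j = multi_otsu_objective(rh, (160, 180, 200, 220))
        np.testing.assert_allclose(j, total_var, rtol=1e-12)

    def test_eight_level_frozen_oracle_value(self):
        # value frozen from the independent enumeration oracle in this file
        hist = GrayHistogram.from_counts(
            {1: 4, 2: 4, 4: 6, 5: 2, 6: 2, 7: 2}, levels=8
        )
        rh = restrict_histogram(hist, 0)
        assert multi_otsu_objective(rh, (2, 4, 5, 6)) == pytest.approx(3.74)
        assert naive_objective(hist.counts, 0, (2, 4, 5, 6), 8) == pytest.approx(3.74)

    def test_full_objective_decomposition(self):
        hist = GrayHistogram.from_counts({1: 4, 2: 4, 4: 6, 5: 2, 6: 2, 7: 2}, levels=8)
        rh = restrict_histogram(hist, 0)
        obj = multi_otsu_objective(rh, (2, 4, 5, 6), full=True)
        np.testing.assert_allclose(obj.weights.sum(), 1.0, atol=1e-12)
        assert obj.value >= 0
        empty = obj.weights == 0
        assert np.isnan(obj.means[empty]).all()

    def test_duplicate_thresholds_allowed(self):
        hist = GrayHistogram.from_counts({160: 3, 200: 3})
        rh = restrict_histogram(hist, 150)
        j = multi_otsu_objective(rh, (180, 180, 180, 180))
        assert j == pytest.approx(multi_otsu_objective(rh, (180,)))


class TestExhaustiveMulti:
    def test_q1_consistent_with_single(self):
        hist = GrayHistogram.from_counts({0: 3, 40: 2, 200: 5})
        rh = restrict_histogram(hist, -1)
        (k_multi,), v_multi = exhaustive_otsu_multi(rh, 1)
        k_single, v_single = exhaustive_otsu_single(hist)
        assert k_multi == k_single
        np.testing.assert_allclose(v_multi, v_single, rtol=1e-9)

    def test_q2_matches_double_loop(self):
        hist = GrayHistogram.from_counts({1: 3, 2: 5, 4: 1, 6: 4, 7: 2}, levels=8)
        rh = restrict_histogram(hist, 0)
        got_t, got_v = exhaustive_otsu_multi(rh, 2)
        best_t, best_v = None, -1.0
        for a in range(1, 8):
            for b in range(a + 1, 8):
                v = naive_objective(hist.counts, 0, (a, b), 8)
                if v > best_v + 1e-12:
                    best_t, best_v = (a, b), v
        assert got_t == best_t
        np.testing.assert_allclose(got_v, best_v, rtol=1e-12)

    def test_five_delta_q4_separators(self):
        hist = GrayHistogram.from_counts({160: 2, 180: 2, 200: 2, 220: 2, 250: 2})
        rh = restrict_histogram(hist, 150)
        thresholds, j = exhaustive_otsu_multi(rh, 4, max_combinations=5_000_000)
        idx = np.arange(256)
        p = rh.p_r
        mu = (idx * p).sum()
        np.testing.assert_allclose(j, (p * (idx - mu) ** 2).sum(), rtol=1e-12)
        # each threshold separates consecutive occupied levels
        occupied = [160, 180, 200, 220, 250]
        for t, lo, hi in zip(thresholds, occupied[:-1], occupied[1:]):
            assert lo <= t < hi

    @pytest.mark.parametrize("q", [1, 2, 4])
    def test_oracle_equivalence_random(self, q, rng):
        """Exact tie-broken agreement with the naive enumeration at 16 levels."""
        for _ in range(4):
            counts = np.zeros(16, dtype=np.int64)
            sel = rng.choice(np.arange(1, 16), size=8, replace=False)
            counts[sel] = rng.integers(1, 30, size=8)
            hist = GrayHistogram(counts=counts, levels=16)
            rh = restrict_histogram(hist, 0)
            got_t, got_v = exhaustive_otsu_multi(rh, q)
            exp_t, exp_v = naive_best(counts, 0, q, 16)
            assert got_t == exp_t
            np.testing.assert_allclose(got_v, exp_v, rtol=1e-9)

    def test_upper_bound_property(self, rng):
        """The objective never exceeds the restricted level-distribution variance."""
        for _ in range(5):
            counts = np.zeros(64, dtype=np.int64)
            sel = rng.choice(np.arange(20, 64), size=10, replace=False)
            counts[sel] = rng.integers(1, 30, size=10)
            hist = GrayHistogram(counts=counts, levels=64)
            rh = restrict_histogram(hist, 19)
            idx = np.arange(64)
            p = rh.p_r
            mu = (idx * p).sum()
            total_var = (p * (idx - mu) ** 2).sum()
            _, v = exhaustive_otsu_multi(rh, 4)
            assert v <= total_var + 1e-9

    def test_combination_cap(self):
        hist = GrayHistogram.from_counts({i: 1 for i in range(256)})
        rh = restrict_histogram(hist, 0)
        with pytest.raises(ValueError, match="combinations"):
            exhaustive_otsu_multi(rh, 4, max_combinations=1000)
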