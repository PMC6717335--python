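"""Applicability-domain constructions and the trade-off tuner."""

import numpy as np
import pytest

from acutetox.domain import (
    AdParams,
    confidence_ad,
    distance_percentile_ad,
    dummy_matrix_ad,
    error_percentile_ad,
    outlier_similarity_ad,
    tune_ad,
)
from acutetox.similarity import BinaryFingerprint


def fp(bits):
    return BinaryFingerprint("TEST", np.asarray(bits, dtype=np.uint8))


class TestDistanceAd:
    def test_query_equal_to_training_row_in_ad(self, rng):
        train = rng.normal(size=(30, 4))
        flags = distance_percentile_ad(train, train[[0]], k=1, percentile=90)
        assert flags.in_ad[0]

    def test_percentile_100_keeps_all_training_rows(self, rng):
        train = rng.normal(size=(40, 3))
        flags = distance_percentile_ad(train, train, k=3, percentile=100)
        assert flags.in_ad.all()
        assert flags.coverage == 1.0

    def test_matches_double_loop_oracle(self, rng):
        train = rng.normal(size=(50, 3))
        query = rng.normal(size=(20, 3))
        k, pct = 5, 95
        flags = distance_percentile_ad(train, query, k=k, percentile=pct)
        # independent double-loop recomputation
        def manhattan(a, b):
            return sum(abs(x - y) for x, y in zip(a, b))

        train_means = []
        for i in range(50):
            d = sorted(manhattan(train[i], train[j]) for j in range(50) if j != i)
            train_means.append(sum(d[:k]) / k)
        t_d = np.percentile(train_means, pct)
        for q_i in range(20):
            d = sorted(manhattan(query[q_i], train[j]) for j in range(50))
            expected = (sum(d[:k]) / k) <= t_d
            assert flags.in_ad[q_i] == expected

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            distance_percentile_ad(rng.normal(size=(5, 2)), rng.normal(size=(2, 2)), k=5)

    def test_coverage_monotone_in_percentile(self, rng):
        train = rng.normal(size=(60, 4))
        query = rng.normal(size=(40, 4))
        covs = [distance_percentile_ad(train, query, k=1, percentile=p).coverage
                for p in (100, 97.5, 95, 90)]
        assert all(a >= b for a, b in zip(covs, covs[1:]))


class TestConfidenceAd:
    def test_boundary_is_out_below_threshold(self):
        flags = confidence_ad([0.64], 0.65)
        assert not flags.in_ad[0]

    def test_threshold_value_is_in(self):
        assert confidence_ad([0.65], 0.65).in_ad[0]

    def test_zero_threshold_keeps_all(self, rng):
        assert confidence_ad(rng.random(50), 0.0).coverage == 1.0

    def test_coverage_monotone_over_grid(self, rng):
        conf = rng.random(200)
        covs = [confidence_ad(conf, t).coverage for t in (0.60, 0.65, 0.70, 0.75)]
        assert all(a >= b for a, b in zip(covs, covs[1:]))


class TestErrorAd:
    def test_percentile_100_inclusive(self, rng):
        tr = rng.random(100)
        flags = error_percentile_ad(tr, tr, percentile=100)
        assert flags.in_ad.all()

    def test_all_equal_errors_all_in(self):
        tr = np.full(50, 0.3)
        for p in (100, 90, 75, 65):
            assert error_percentile_ad(tr, tr, percentile=p).in_ad.all()

    def test_matches_percentile_oracle(self, rng):
        tr = rng.random(200)
        qu = rng.random(200)
        for p in (100, 90, 75, 65):
            flags = error_percentile_ad(tr, qu, percentile=p)
            expected = qu <= np.percentile(tr, p)
            assert np.array_equal(flags.in_ad, expected)

    def test_coverage_monotone_in_percentile(self, rng):
        tr, qu = rng.random(100), rng.random(80)
        covs = [error_percentile_ad(tr, qu, percentile=p).coverage
                for p in (100, 90, 75, 65)]
        assert all(a >= b for a, b in zip(covs, covs[1:]))


class TestDummyMatrixAd:
    @staticmethod
    def _correlated(rng, n):
        z = rng.normal(size=(n, 1))
        return np.hstack([z + 0.2 * rng.normal(size=(n, 1)) for _ in range(5)])

    def test_real_like_queries_mostly_in_ad(self, rng):
        train = self._correlated(rng, 300)
        query = self._correlated(rng, 100)
        flags = dummy_matrix_ad(train, query, seed=0)
        assert flags.coverage >= 0.8

    def test_permuted_queries_mostly_out(self, rng):
        train = self._correlated(rng, 300)
        query = self._correlated(rng, 100)
        shuffled = np.column_stack([rng.permutation(query[:, j]) for j in range(5)])
        flags = dummy_matrix_ad(train, shuffled, seed=0)
        assert flags.coverage <= 0.5

    def test_seed_deterministic(self, rng):
        train = self._correlated(rng, 100)
        query = self._correlated(rng, 30)
        a = dummy_matrix_ad(train, query, seed=9)
        b = dummy_matrix_ad(train, query, seed=9)
        assert np.array_equal(a.in_ad, b.in_ad)


class TestOutlierSimilarityAd:
    def test_inlier_like_query_in_ad(self):
        inliers = [fp([1, 1, 1, 0, 0, 0, 0, 0]), fp([1, 1, 0, 1, 0, 0, 0, 0]),
                   fp([1, 0, 1, 1, 0, 0, 0, 0])]
        outliers = [fp([0, 0, 0, 0, 1, 1, 1, 0]), fp([0, 0, 0, 0, 1, 1, 0, 1]),
                    fp([0, 0, 0, 0, 1, 0, 1, 1])]
        flags = outlier_similarity_ad([inliers[0]], outliers, inliers)
        assert flags.in_ad[0]

    def test_outlier_like_query_out_of_ad(self):
        inliers = [fp([1, 1, 1, 0, 0, 0, 0, 0]), fp([1, 1, 0, 1, 0, 0, 0, 0]),
                   fp([1, 0, 1, 1, 0, 0, 0, 0])]
        outliers = [fp([0, 0, 0, 0, 1, 1, 1, 0]), fp([0, 0, 0, 0, 1, 1, 0, 1]),
                    fp([0, 0, 0, 0, 1, 0, 1, 1])]
        flags = outlier_similarity_ad([outliers[0]], outliers, inliers)
        assert not flags.in_ad[0]

    def test_matches_top3_oracle(self, rng):
        def rand_fp():
            return fp(rng.integers(0, 2, size=16))

        inliers = [rand_fp() for _ in range(8)]
        outliers = [rand_fp() for _ in range(8)]
        queries = [rand_fp() for _ in range(20)]
        flags = outlier_similarity_ad(queries, outliers, inliers)
        from acutetox.similarity import tanimoto

        for i, q in enumerate(queries):
            s_out = sorted((tanimoto(q, o) for o in outliers), reverse=True)[:3]
            s_in = sorted((tanimoto(q, o) for o in inliers), reverse=True)[:3]
            assert flags.in_ad[i] == (np.mean(s_out) <= np.mean(s_in))

    def test_too_few_references(self):
        with pytest.raises(ValueError):
            outlier_similarity_ad([fp([1, 0])], [fp([1, 0])], [fp([1, 0])] * 3)


class TestTuneAd:
    def test_single_combination(self):
        p = AdParams(k=1, t_d_percentile=95)
        assert tune_ad([p], lambda _: (0.5, 0.9)) == p

    def test_dominating_combination_selected(self):
        params = [AdParams(k=1), AdParams(k=5), AdParams(k=1, t_c=0.5)]
        perf = {params[0]: (0.40, 0.95), params[1]: (0.55, 0.80), params[2]: (0.60, 0.70)}
        assert tune_ad(params, lambda p: perf[p]) == params[0]

    def test_invariant_to_ordering(self):
        params = [AdParams(k=1, t_c=t) for t in (0.1, 0.2, 0.3, 0.4)]
        perf = {0.1: (0.5, 0.95), 0.2: (0.45, 0.85), 0.3: (0.42, 0.75), 0.4: (0.40, 0.60)}
        fn = lambda p: perf[p.t_c]
        a = tune_ad(params, fn)
        b = tune_ad(list(reversed(params)), fn)
        assert a == b

    def test_floor_fallback_to_best_coverage(self):
        params = [AdParams(k=1, t_c=0.1), AdParams(k=1, t_c=0.2)]
        perf = {0.1: (0.3, 0.5), 0.2: (0.2, 0.6)}
        out = tune_ad(params, lambda p: perf[p.t_c], coverage_floor=0.9)
        assert out.t_c == 0.2
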