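"""Read-across decision rules, LOO cross-validation and grid search."""

import numpy as np
import pytest

from acutetox.readacross import (
    IstKnnParams,
    IstKnnRegressor,
    default_param_grid,
    istknn_grid_search,
    istknn_loo_cv,
    istknn_predict_from_sims,
)


def brute_force_readacross(sims, values, ids, p):
    """Independent re-derivation of the decision rules (plain loops)."""
    eligible = []
    for i in range(len(sims)):
        if sims[i] > p.t_sim1:
            eligible.append((ids[i], sims[i], values[i]))
    eligible = sorted(eligible, key=lambda t: (-t[1], t[0]))[: p.k]
    if len(eligible) == 0:
        return None, "NO_NEIGHBOR"
    if len(eligible) == 1:
        if eligible[0][1] > p.t_sim2:
            return eligible[0][2], "OK"
        return None, "SINGLE_BELOW_T2"
    vals = [v for _, _, v in eligible]
    if max(vals) - min(vals) >= p.t_minmax:
        return None, "RANGE_EXCEEDED"
    num = den = 0.0
    for _, si, v in eligible:
        num += si**p.enhancement * v
        den += si**p.enhancement
    return num / den, "OK"


class TestDecisionRules:
    def test_single_neighbor_above_strict_threshold(self):
        p = IstKnnParams(k=3, t_sim1=0.80, t_sim2=0.85)
        res = istknn_predict_from_sims([0.86, 0.3], [1.7, 0.0], p)
        assert res.reason == "OK"
        assert res.prediction == pytest.approx(1.7)

    def test_single_neighbor_below_second_threshold(self):
        p = IstKnnParams(k=3, t_sim1=0.80, t_sim2=0.85)
        res = istknn_predict_from_sims([0.84, 0.3], [1.7, 0.0], p)
        assert res.abstained and res.reason == "SINGLE_BELOW_T2"

    def test_range_rule_abstains(self):
        p = IstKnnParams(k=2, t_sim1=0.70, t_minmax=2.0)
        res = istknn_predict_from_sims([0.9, 0.8], [1.0, 3.5], p)
        assert res.abstained and res.reason == "RANGE_EXCEEDED"

    def test_weighted_mean(self):
        p = IstKnnParams(k=2, t_sim1=0.70, t_minmax=2.0, enhancement=1)
        res = istknn_predict_from_sims([0.9, 0.8], [1.0, 2.0], p)
        assert res.prediction == pytest.approx(2.5 / 1.7)

    def test_no_neighbor(self):
        p = IstKnnParams(t_sim1=0.90, t_sim2=0.95)
        res = istknn_predict_from_sims([0.5, 0.6], [1.0, 2.0], p)
        assert res.abstained and res.reason == "NO_NEIGHBOR"

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            istknn_predict_from_sims([], [], IstKnnParams())

    def test_prediction_within_neighbor_range(self, si_table, rng):
        sims, values, ids = si_table
        for _ in range(200):
            p = IstKnnParams(
                k=int(rng.integers(2, 6)),
                t_sim1=float(rng.choice([0.70, 0.75, 0.80])),
                t_sim2=float(rng.choice([0.85, 0.90])),
                enhancement=int(rng.integers(1, 4)),
                t_minmax=float(rng.choice([1.0, 1.5, 2.0])),
            )
            res = istknn_predict_from_sims(sims, values, p, ids)
            if res.prediction is not None and len(res.neighbors) >= 2:
                vals = [v for _, _, v in res.neighbors]
                assert min(vals) <= res.prediction <= max(vals)

    def test_enhancement_limit_converges_to_nearest(self):
        """Very large enhancement factors reduce to the single best neighbor."""
        sims = [0.95, 0.71, 0.71]
        values = [-1.2, -0.7, -0.2]
        p = IstKnnParams(k=3, t_sim1=0.70, enhancement=50, t_minmax=5.0)
        res = istknn_predict_from_sims(sims, values, p)
        assert res.prediction == pytest.approx(values[0], abs=1e-6)

    def test_coverage_monotone_in_t_sim1(self, si_table):
        sims, values, ids = si_table
        covered = []
        for t1 in (0.70, 0.75, 0.80, 0.85):
            p = IstKnnParams(k=3, t_sim1=t1, t_sim2=max(t1, 0.85), t_minmax=5.0)
            res = istknn_predict_from_sims(sims, values, p, ids)
            covered.append(0 if res.abstained else 1)
        assert all(a >= b for a, b in zip(covered, covered[1:]))

    def test_matches_brute_force_oracle(self, si_table, rng):
        sims, values, ids = si_table
        for _ in range(300):
            n = int(rng.integers(1, 7))
            pick = rng.choice(6, size=n, replace=False)
            t1 = float(rng.choice([0.70, 0.75, 0.80, 0.85, 0.90]))
            p = IstKnnParams(
                k=int(rng.integers(2, 6)),
                t_sim1=t1,
                t_sim2=max(t1, float(rng.choice([0.85, 0.90]))),
                enhancement=int(rng.integers(1, 4)),
                t_minmax=float(rng.choice([1.0, 1.5, 2.0])),
            )
            res = istknn_predict_from_sims(sims[pick], values[pick], p, [ids[i] for i in pick])
            exp_val, exp_reason = brute_force_readacross(
                sims[pick], values[pick], [ids[i] for i in pick], p
            )
            assert res.reason == exp_reason
            if exp_val is None:
                assert res.prediction is None
            else:
                assert res.prediction == pytest.approx(exp_val, abs=1e-12)


class TestEstimator:
    def test_fit_predict_with_custom_similarity(self):
        """Integer 'compounds' with similarity 1/(1+|a-b|) exercise the API."""
        sim = lambda a, b: 1.0 / (1.0 + abs(a - b))
        est = IstKnnRegressor(k=2, t_sim1=0.4, t_sim2=0.9, t_minmax=10.0, sim_fn=sim)
        est.fit([0, 1, 2, 10], [0.0, 1.0, 2.0, 9.0])
        # neighbors of 1: itself (sim 1.0, y 1.0) and compound 0 (sim 0.5, y 0.0)
        pred = est.predict([1])
        assert pred[0] == pytest.approx(2 / 3)

    def test_get_set_params_roundtrip(self):
        est = IstKnnRegressor()
        est.set_params(k=5, t_minmax=2.0)
        assert est.get_params()["k"] == 5
        assert est.params_.t_minmax == 2.0


class TestLooCv:
    def test_duplicate_compounds_perfect(self):
        S = np.ones((4, 4))
        y = np.full(4, 1.5)
        out = istknn_loo_cv(S, y, IstKnnParams(k=3, t_sim1=0.7, t_minmax=1.0))
        assert out["coverage"] == 1.0
        assert out["rmse"] == pytest.approx(0.0)

    def test_unreachable_threshold_gives_zero_coverage(self):
        S = np.full((4, 4), 0.2)
        np.fill_diagonal(S, 1.0)
        out = istknn_loo_cv(S, np.arange(4.0), IstKnnParams(t_sim1=0.9, t_sim2=0.95))
        assert out["coverage"] == 0.0
        assert np.isnan(out["rmse"])

    def test_matches_brute_force_loo(self, rng):
        """LOO metrics equal an independent per-compound recomputation."""
        n = 25
        S = rng.random((n, n)) * 0.5 + 0.5
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        y = rng.normal(size=n)
        p = IstKnnParams(k=3, t_sim1=0.75, t_sim2=0.85, enhancement=2, t_minmax=2.0)
        out = istknn_loo_cv(S, y, p)
        preds, truths = [], []
        ids = [str(i) for i in range(n)]
        for i in range(n):
            keep = [j for j in range(n) if j != i]
            val, reason = brute_force_readacross(
                S[i, keep], y[keep], [ids[j] for j in keep], p
            )
            if reason == "OK":
                preds.append(val)
                truths.append(y[i])
        assert out["coverage"] == pytest.approx(len(preds) / n)
        preds, truths = np.array(preds), np.array(truths)
        assert out["rmse"] == pytest.approx(float(np.sqrt(np.mean((preds - truths) ** 2))))
        assert out["mae"] == pytest.approx(float(np.mean(np.abs(preds - truths))))


class TestGridSearch:
    @staticmethod
    def _toy_problem(rng, n=30):
        S = rng.random((n, n)) * 0.4 + 0.6
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        y = rng.normal(size=n)
        return S[:20, :20], y[:20], S[20:, :20], y[20:]

    def test_single_element_grid(self, rng):
        st, yt, sv, yv = self._toy_problem(rng)
        p = IstKnnParams(k=3, t_sim1=0.70, t_minmax=5.0)
        best, _ = istknn_grid_search([p], st, yt, sv, yv, min_coverage=0.0)
        assert best == p

    def test_deterministic(self, rng):
        st, yt, sv, yv = self._toy_problem(rng)
        grid = [IstKnnParams(k=k, t_sim1=0.70, t_minmax=2.0) for k in (2, 3, 4)]
        a = istknn_grid_search(grid, st, yt, sv, yv, min_coverage=0.0)
        b = istknn_grid_search(grid, st, yt, sv, yv, min_coverage=0.0)
        assert a[0] == b[0]

    def test_default_grid_respects_constraints(self):
        grid = default_param_grid()
        assert len(grid) > 100
        assert all(p.t_sim2 >= p.t_sim1 for p in grid)
        assert all(2 <= p.k <= 5 for p in grid)
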