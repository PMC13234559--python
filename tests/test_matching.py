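"""Propensity fitting, distance metrics, greedy matching and balance."""

import numpy as np
import pandas as pd
import pytest

from geobaci.matching import (
    DistanceModel,
    balance_evaluation,
    fit_propensity,
    mahalanobis_distances,
    match_exact,
    match_nearest,
)

from conftest import make_table
from oracles import greedy_match_oracle


def _score_model(impact_scores, control_scores):
    """DistanceModel with hand-set logit scores (impact ids first)."""
    n_i, n_c = len(impact_scores), len(control_scores)
    ids = np.arange(n_i + n_c)
    logit = pd.Series(np.r_[impact_scores, control_scores], index=ids)
    return DistanceModel(
        kind="propensity-logistic",
        unit_ids=ids,
        scores=1 / (1 + np.exp(-logit)),
        logit_scores=logit,
    )


def _score_table(n_i, n_c):
    return make_table(n_i, n_c, {})


class TestFitPropensity:
    def test_recovers_known_slope(self):
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.normal(size=(n, 3))
        beta = np.array([1.5, -0.8, 0.3])
        p = 1 / (1 + np.exp(-(x @ beta - 0.2)))
        y = rng.random(n) < p
        df = make_table(0, n, {f"x{j}": x[:, j] for j in range(3)})
        df["treatment"] = y.astype(int)
        model = fit_propensity(df)
        # within 3 SE of the truth (SE ~ 1/sqrt(n * p(1-p) * var x))
        for j, b in enumerate(beta):
            est = model.coefficients[f"x{j}"]
            assert abs(est - b) < 3 * 0.12, f"x{j}: {est} vs {b}"

    def test_independent_treatment_gives_prevalence(self):
        rng = np.random.default_rng(12)
        n = 2000
        df = make_table(0, n, {"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        df["treatment"] = (rng.random(n) < 0.3).astype(int)
        model = fit_propensity(df)
        prev = df["treatment"].mean()
        assert abs(model.coefficients["const"] - np.log(prev / (1 - prev))) < 0.2
        assert abs(model.coefficients["x1"]) < 0.15
        assert model.scores.mean() == pytest.approx(prev, abs=0.02)

    def test_constant_covariates_yield_prevalence_scores(self):
        df = make_table(10, 30, {"x1": np.ones(40)})
        model = fit_propensity(df)
        np.testing.assert_allclose(model.scores.to_numpy(), 0.25, atol=1e-6)

    def test_perfect_separation_raises(self):
        rng = np.random.default_rng(8)
        x = np.r_[rng.uniform(1.01, 2.0, 20), rng.uniform(0.0, 0.99, 20)]
        df = make_table(20, 20, {"x1": x})
        with pytest.raises(ValueError, match="separation|converge"):
            fit_propensity(df)


class TestMahalanobis:
    def _table_with_points(self, pts_i, pts_c):
        n_i, n_c = len(pts_i), len(pts_c)
        pts = np.r_[pts_i, pts_c]
        df = make_table(n_i, n_c, {"u": pts[:, 0], "v": pts[:, 1]})
        return df

    def test_identity_covariance_is_euclidean(self):
        df = self._table_with_points([[0.0, 0.0]], [[3.0, 4.0]])
        model = DistanceModel(
            kind="mahalanobis", unit_ids=df["unit_id"].to_numpy(),
            covariance=np.eye(2), covariance_inv=np.eye(2),
        )
        D, _, _, _ = mahalanobis_distances(df, model)
        assert D[0, 0] == pytest.approx(5.0)

    def test_zero_distance_for_identical_points(self):
        df = self._table_with_points([[1.0, 2.0]], [[1.0, 2.0], [0.0, 0.0]])
        model = DistanceModel(
            kind="mahalanobis", unit_ids=df["unit_id"].to_numpy(),
            covariance=np.eye(2), covariance_inv=np.eye(2),
        )
        D, _, _, _ = mahalanobis_distances(df, model)
        assert D[0, 0] == 0.0

    def test_diagonal_scaling(self):
        df = self._table_with_points([[2.0, 0.0]], [[0.0, 0.0]])
        S = np.diag([4.0, 1.0])
        model = DistanceModel(
            kind="mahalanobis", unit_ids=df["unit_id"].to_numpy(),
            covariance=S, covariance_inv=np.linalg.inv(S),
        )
        D, _, _, _ = mahalanobis_distances(df, model)
        assert D[0, 0] == pytest.approx(1.0)

    def test_match_nearest_on_mahalanobis(self):
        rng = np.random.default_rng(6)
        df = make_table(4, 20, {"u": rng.normal(size=24), "v": rng.normal(size=24)})
        _, _, _, model = mahalanobis_distances(df)
        res = match_nearest(df, model, ratio=2, replace=True, caliper=10.0)
        assert res.spec["caliper_scale"] == "raw"
        assert len(res.pairs) <= 8
        D, imp, ctl, _ = mahalanobis_distances(df, model)
        for _, p in res.pairs.iterrows():
            i = list(imp).index(p.impact_id)
            j = list(ctl).index(p.control_id)
            assert p.distance == pytest.approx(D[i, j])
            if p['rank'] == 1:
                assert p.distance == pytest.approx(D[i].min())

    def test_pooled_covariance_default(self):
        rng = np.random.default_rng(5)
        df = make_table(10, 30, {"u": rng.normal(size=40), "v": rng.normal(size=40)})
        D, imp, ctl, model = mahalanobis_distances(df)
        assert D.shape == (10, 30)
        assert model.covariance.shape == (2, 2)
        assert np.all(D >= 0)


class TestMatchNearest:
    def test_nearest_two_controls(self):
        model = _score_model([0.5], [0.4, 0.45, 0.9])
        res = match_nearest(_score_table(1, 3), model, ratio=2, replace=False)
        got = res.pairs.sort_values("rank")[["control_id", "rank"]].to_numpy()
        np.testing.assert_array_equal(got, [[2, 1], [1, 2]])  # 0.45 then 0.4

    def test_replacement_reuses_control(self):
        model = _score_model([0.5, 0.52], [0.51, 5.0, 6.0])
        res = match_nearest(_score_table(2, 3), model, ratio=1, replace=True)
        assert (res.pairs["control_id"] == 2).all()
        assert res.control_weights.loc[2] == 2.0

    def test_caliper_excludes_everything(self):
        model = _score_model([0.0, 1.0], [10.0, 12.0])
        res = match_nearest(
            _score_table(2, 2), model, ratio=1, replace=True, caliper=0.01
        )
        assert res.pairs.empty
        assert len(res.unmatched_impact) == 2
        assert res.spec["caliper_scale"] == "sd-of-logit"

    def test_tie_breaks_to_lowest_control_id(self):
        model = _score_model([0.5], [0.6, 0.4])  # equidistant
        res = match_nearest(_score_table(1, 2), model, ratio=1, replace=False)
        assert res.pairs["control_id"].iloc[0] == 1  # id 1 < id 2

    def test_without_replacement_is_injective(self):
        rng = np.random.default_rng(0)
        model = _score_model(rng.normal(size=8), rng.normal(size=30))
        res = match_nearest(_score_table(8, 30), model, ratio=3, replace=False)
        assert res.pairs["control_id"].is_unique

    def test_with_replacement_weights_sum_to_pairs(self):
        rng = np.random.default_rng(1)
        model = _score_model(rng.normal(size=8), rng.normal(size=30))
        res = match_nearest(_score_table(8, 30), model, ratio=3, replace=True)
        assert res.control_weights.sum() == len(res.pairs)

    def test_insufficient_controls_without_caliper(self):
        model = _score_model([0.0, 1.0], [0.5])
        with pytest.raises(ValueError, match="controls"):
            match_nearest(_score_table(2, 1), model, ratio=1, replace=False)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        model = _score_model(rng.normal(size=6), rng.normal(size=25))
        kw = dict(ratio=2, replace=False, order="random", seed=99)
        r1 = match_nearest(_score_table(6, 25), model, **kw)
        r2 = match_nearest(_score_table(6, 25), model, **kw)
        pd.testing.assert_frame_equal(r1.pairs, r2.pairs)

    @pytest.mark.parametrize("replace", [False, True])
    @pytest.mark.parametrize("ratio", [1, 2, 10])
    @pytest.mark.parametrize("caliper", [None, 0.5])
    def test_oracle_equivalence(self, replace, ratio, caliper):
        """Greedy matching matches a naive reimplementation exactly."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            need_pool = not replace and caliper is None
            n_i = int(rng.integers(2, min(10, 50 // ratio if need_pool else 10) + 1))
            n_c = int(rng.integers(ratio * n_i if need_pool else 5, 51))
            si = rng.normal(size=n_i)
            sc = rng.normal(size=n_c)
            model = _score_model(si, sc)
            res = match_nearest(
                _score_table(n_i, n_c), model, ratio=ratio, replace=replace,
                caliper=caliper, order="data",
            )
            caliper_abs = None
            if caliper is not None:
                caliper_abs = caliper * np.std(np.r_[si, sc], ddof=1)
            impact_ids = np.arange(n_i)
            control_ids = np.arange(n_i, n_i + n_c)
            pairs, unmatched = greedy_match_oracle(
                impact_ids, control_ids, si, sc, ratio, replace, caliper_abs,
                order_idx=range(n_i),
            )
            got = set(map(tuple, res.pairs[["impact_id", "control_id", "rank"]].to_numpy()))
            assert got == pairs, f"seed {seed}"
            assert res.unmatched_impact == sorted(unmatched)

    def test_extremity_order_matches_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n_i, n_c = 6, 12
            si, sc = rng.normal(size=n_i), rng.normal(size=n_c)
            model = _score_model(si, sc)
            res = match_nearest(
                _score_table(n_i, n_c), model, ratio=2, replace=False, order="extremity"
            )
            # independent ordering: descending |logit - mean of all logits|
            ext = np.abs(si - np.r_[si, sc].mean())
            order_idx = np.lexsort((np.arange(n_i), -ext))
            pairs, _ = greedy_match_oracle(
                np.arange(n_i), np.arange(n_i, n_i + n_c), si, sc, 2, False, None,
                order_idx,
            )
            got = set(map(tuple, res.pairs[["impact_id", "control_id", "rank"]].to_numpy()))
            assert got == pairs, f"seed {seed}"


class TestMatchExact:
    def test_single_stratum_matches_all(self):
        df = make_table(2, 5, {"lc": np.r_[[1, 1], [1] * 5]}, categorical=["lc"])
        res = match_exact(df, ["lc"])
        assert len(res.pairs) == 10
        np.testing.assert_allclose(res.pairs["weight"], 0.2)

    def test_stratum_without_controls_unmatched(self):
        df = make_table(2, 3, {"lc": np.r_[[1, 2], [1, 1, 1]]}, categorical=["lc"])
        res = match_exact(df, ["lc"])
        assert res.unmatched_impact == [1]

    def test_pairs_never_cross_strata(self):
        df = make_table(
            4, 8, {"lc": np.r_[[1, 1, 2, 2], [1] * 4 + [2] * 4]}, categorical=["lc"]
        )
        res = match_exact(df, ["lc"])
        lc = df.set_index("unit_id")["lc"]
        for _, p in res.pairs.iterrows():
            assert lc[p.impact_id] == lc[p.control_id]

    def test_no_common_stratum_errors(self):
        df = make_table(2, 2, {"lc": np.r_[[1, 1], [2, 2]]}, categorical=["lc"])
        with pytest.raises(ValueError, match="stratum"):
            match_exact(df, ["lc"])


class TestBalance:
    def test_identical_distributions_near_zero_smd(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=400)
        df = make_table(200, 200, {"x1": x})
        model = fit_propensity(df)
        res = match_nearest(df, model, ratio=1, replace=True)
        rep = balance_evaluation(res, df)
        assert abs(rep.smd.loc["x1", "smd_before"]) < 0.2

    def test_exact_match_zeroes_smd_after(self):
        rng = np.random.default_rng(22)
        lc = rng.integers(1, 3, size=80).astype(float)
        df = make_table(30, 50, {"lc": lc}, categorical=["lc"])
        res = match_exact(df, ["lc"])
        rep = balance_evaluation(res, df)
        after = rep.smd["smd_after"].dropna()
        np.testing.assert_allclose(after.to_numpy(), 0.0, atol=1e-12)

    def test_matching_improves_confounded_balance(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(30 + seed)
            n = 400
            x = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(1.5 * x - 1.0)))
            tr = (rng.random(n) < p).astype(int)
            if tr.sum() < 10 or tr.sum() > n - 50:
                continue
            df = pd.DataFrame(
                {
                    "unit_id": np.arange(n), "x": 0.0, "y": 0.0, "treatment": tr,
                    "x1": x, "x2": rng.normal(size=n),
                }
            )
            model = fit_propensity(df)
            res = match_nearest(df, model, ratio=2, replace=True)
            rep = balance_evaluation(res, df)
            if (
                rep.smd["smd_after"].abs().mean()
                < rep.smd["smd_before"].abs().mean()
            ):
                wins += 1
        assert wins >= 4

    def test_control_selection_counts(self):
        model = _score_model([0.0, 0.0], [0.1, 5.0])
        res = match_nearest(_score_table(2, 2), model, ratio=1, replace=True)
        rep = balance_evaluation(res, _score_table(2, 2))
        assert rep.control_selection.loc[2] == 2

    def test_zero_variance_covariate_smd_missing(self):
        df = make_table(10, 20, {"x1": np.ones(30), "x2": np.random.default_rng(1).normal(size=30)})
        model = fit_propensity(df)
        res = match_nearest(df, model, ratio=1, replace=True)
        rep = balance_evaluation(res, df)
        assert np.isnan(rep.smd.loc["x1", "smd_before"])
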