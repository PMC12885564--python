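"""WIS, FC, composite, selection, categories and the final ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wisfc as w
from wisfc.aggregate import WisVector, _quantile_threshold
from wisfc.core import Orientation


def rank_matrix(rows, models=None, pool=None):
    return w.RankMatrix.from_ranks(rows, model_ids=models, rank_pool_size=pool)


def wis_of(rows, weights=None, pool=None):
    m = rank_matrix(rows, pool=pool)
    wv = weights or w.equal_weights(m.models)
    return w.weighted_importance_score(m, wv)


class TestWeightedImportanceScore:
    def test_blood_pressure_mean_rank(self):
        wis = wis_of({"bp": [1, 2, 4, 1, 3]}, pool=20)
        assert wis.values["bp"] == pytest.approx(2.2)

    def test_cholesterol_mean_rank(self):
        wis = wis_of({"chol": [1, 8, 2, 15, 1]}, pool=20)
        assert wis.values["chol"] == pytest.approx(5.4)

    def test_degenerate_weight_vector_returns_first_model(self):
        m = rank_matrix({"a": [1, 3], "b": [2, 1]})
        wv = w.WeightVector(model_ids=("m1", "m2"), weights=(1.0, 0.0))
        wis = w.weighted_importance_score(m, wv)
        assert wis.values["a"] == pytest.approx(1.0)

    def test_misaligned_weights_error(self):
        m = rank_matrix({"a": [1, 2]})
        with pytest.raises(ValueError):
            w.weighted_importance_score(m, w.equal_weights(["x", "y"]))

    def test_equal_weight_wis_is_column_mean_oracle(self):
        """Equal-weight WIS == brute-force row mean on 100 random matrices."""
        rng = np.random.default_rng(4)
        for _ in range(100):
            p, n = rng.integers(2, 9), rng.integers(2, 7)
            grid = np.array([rng.permutation(p) + 1 for _ in range(n)], dtype=float).T
            rows = {f"x{i}": grid[i].tolist() for i in range(p)}
            m = rank_matrix(rows)
            wis = w.weighted_importance_score(m, w.equal_weights(m.models))
            oracle = grid.mean(axis=1)
            assert np.allclose(wis.values.to_numpy(), oracle, atol=1e-12)

    def test_exclude_policy_renormalizes_weights(self):
        outs = [
            w.ModelImportance("m1", {"A": 3, "B": 2}),
            w.ModelImportance("m2", {"A": 2}),
        ]
        m = w.build_rank_matrix(outs, w.AggregationConfig(fill_policy=w.FillPolicy.EXCLUDE))
        wis = w.weighted_importance_score(m, w.equal_weights(m.models))
        assert wis.values["B"] == pytest.approx(2.0)  # only m1 reports B


class TestFrequencyCount:
    @pytest.mark.parametrize(
        "ranks,k,frac",
        [
            ([1, 2, 4, 1, 3], 10, 1.0),
            ([1, 8, 2, 15, 1], 10, 0.8),
            ([1, 8, 2, 15, 1], 3, 0.6),
        ],
    )
    def test_examples(self, ranks, k, frac):
        fc = w.frequency_count(rank_matrix({"f": ranks}, pool=20), k)
        assert fc.loc["f", "fc_fraction"] == pytest.approx(frac)
        assert fc.loc["f", "fc_percent"] == pytest.approx(100 * frac)

    def test_one_of_five_is_twenty_percent(self):
        fc = w.frequency_count(rank_matrix({"gene": [1, 12, 15, 11, 18]}, pool=20), 10)
        assert fc.loc["gene", "fc_percent"] == pytest.approx(20.0)

    def test_score_matrix_rejected_with_guidance(self):
        m = w.RankMatrix(
            data=pd.DataFrame({"m1": [0.6], "m2": [0.4]}, index=["a"]),
            orientation=Orientation.SCORE_HIGH_BEST,
        )
        with pytest.raises(ValueError, match="rank"):
            w.frequency_count(m, 3)

    def test_matches_brute_force_threshold_count(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p, n = rng.integers(2, 9), rng.integers(2, 7)
            grid = np.array([rng.permutation(p) + 1 for _ in range(n)], dtype=float).T
            m = rank_matrix({f"x{i}": grid[i].tolist() for i in range(p)})
            k = int(rng.integers(1, p + 1))
            fc = w.frequency_count(m, k)
            brute = [sum(1 for r in grid[i] if r <= k) for i in range(p)]
            assert fc["fc_count"].tolist() == brute

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_k(self, data):
        p = data.draw(st.integers(2, 8))
        n = data.draw(st.integers(2, 5))
        rng = np.random.default_rng(data.draw(st.integers(0, 10**6)))
        grid = np.array([rng.permutation(p) + 1 for _ in range(n)]).T
        m = rank_matrix({f"x{i}": grid[i].tolist() for i in range(p)})
        k1 = data.draw(st.integers(1, p))
        k2 = data.draw(st.integers(k1, p))
        c1 = w.frequency_count(m, k1)["fc_count"]
        c2 = w.frequency_count(m, k2)["fc_count"]
        assert (c1 <= c2).all()
        assert (w.frequency_count(m, p)["fc_count"] == n).all()


class TestCompositeScore:
    def test_full_consensus_identity(self):
        wis = WisVector(pd.Series({"a": 0.5}), Orientation.SCORE_HIGH_BEST)
        c = w.composite_score(wis, pd.Series({"a": 5}), 5)
        assert c["a"] == pytest.approx(0.5)

    def test_zero_frequency_annihilation(self):
        wis = WisVector(pd.Series({"a": 0.4}), Orientation.SCORE_HIGH_BEST)
        assert w.composite_score(wis, pd.Series({"a": 0}), 5)["a"] == 0.0

    def test_direct_product(self):
        wis = WisVector(pd.Series({"a": 0.4}), Orientation.SCORE_HIGH_BEST)
        assert w.composite_score(wis, pd.Series({"a": 2}), 5)["a"] == pytest.approx(0.16)

    def test_rank_orientation_forbidden(self):
        wis = WisVector(pd.Series({"a": 2.0}), Orientation.RANK_LOW_BEST)
        with pytest.raises(ValueError, match="invert"):
            w.composite_score(wis, pd.Series({"a": 2}), 5)


class TestInvertWis:
    @pytest.mark.parametrize("val,p,expected", [(1, 20, 20), (20, 20, 1), (2.2, 20, 18.8)])
    def test_affine_form(self, val, p, expected):
        wis = WisVector(pd.Series({"a": float(val)}), Orientation.RANK_LOW_BEST)
        assert w.invert_wis(wis, p).values["a"] == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        wis = WisVector(pd.Series({"a": 25.0}), Orientation.RANK_LOW_BEST)
        with pytest.raises(ValueError, match="outside"):
            w.invert_wis(wis, 20)

    def test_order_reversing_bijection_brute_force(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 20, size=50)
        wis = WisVector(pd.Series(vals, index=[f"x{i}" for i in range(50)]), Orientation.RANK_LOW_BEST)
        inv = w.invert_wis(wis, 20)
        # every pairwise order flips
        order = np.argsort(vals)
        assert list(np.argsort(-inv.values.to_numpy())) == list(order)
        assert inv.orientation is Orientation.SCORE_HIGH_BEST


class TestJointSelect:
    def _wis(self, d):
        return WisVector(pd.Series(d, dtype=float), Orientation.RANK_LOW_BEST)

    def test_dominating_feature_selected(self):
        wis = self._wis({f"x{i}": i + 1 for i in range(20)})
        fc = pd.Series({f"x{i}": 0.8 if i == 0 else 0.6 for i in range(20)})
        sel = w.joint_select(wis, fc)
        assert sel["x0"]

    def test_fc_gate_blocks_best_wis(self):
        wis = self._wis({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        fc = pd.Series({"a": 0.2, "b": 1.0, "c": 1.0, "d": 1.0})
        assert not w.joint_select(wis, fc)["a"]

    def test_quantile_boundary_inclusive(self):
        wis = self._wis({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        fc = pd.Series(1.0, index=list("abcd"))
        sel = w.joint_select(wis, fc, wis_quantile=0.25)
        assert sel.to_dict() == {"a": True, "b": False, "c": False, "d": False}

    def test_empty_feature_set_errors(self):
        wis = WisVector(pd.Series(dtype=float), Orientation.RANK_LOW_BEST)
        with pytest.raises(ValueError, match="empty"):
            w.joint_select(wis, pd.Series(dtype=float))

    def test_nearest_rank_quantile_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            vals = rng.uniform(1, 10, size=rng.integers(1, 30))
            q = rng.uniform(0.05, 1.0)
            cut = _quantile_threshold(vals, q, lower_is_better=True)
            m = max(1, int(np.ceil(q * vals.size)))
            assert cut == sorted(vals)[m - 1]


class TestRankFeatures:
    def _rank(self, wis_d, fc_d):
        wis = WisVector(pd.Series(wis_d, dtype=float), Orientation.RANK_LOW_BEST)
        return w.rank_features(wis, pd.Series(fc_d, dtype=float))

    def test_wis_primary_sort(self):
        ranks = self._rank({"A": 2.2, "B": 5.4}, {"A": 5, "B": 4})
        assert ranks["A"] == 1 and ranks["B"] == 2

    def test_fc_tie_break(self):
        ranks = self._rank({"A": 3.0, "B": 3.0}, {"A": 3, "B": 4})
        assert ranks["B"] == 1

    def test_lexicographic_final_tie_break(self):
        ranks = self._rank({"B": 3.0, "A": 3.0}, {"A": 4, "B": 4})
        assert ranks["A"] == 1

    def test_total_order_permutation(self):
        rng = np.random.default_rng(2)
        wis_d = {f"x{i}": float(rng.integers(1, 4)) for i in range(12)}
        fc_d = {f: float(rng.integers(0, 3)) for f in wis_d}
        ranks = self._rank(wis_d, fc_d)
        assert sorted(ranks) == list(range(1, 13))


class TestCategorize:
    def _cat(self, wis_d, fc_d, **kw):
        wis = WisVector(pd.Series(wis_d, dtype=float), Orientation.RANK_LOW_BEST)
        return w.categorize(wis, pd.Series(fc_d, dtype=float), **kw)

    def test_interpretation_matrix(self):
        # 4 features: best-quartile WIS = the single best
        wis_d = {"a": 1.0, "b": 1.5, "c": 5.0, "d": 8.0}
        fc_d = {"a": 1.0, "b": 0.2, "c": 0.9, "d": 0.1}
        cats = self._cat(wis_d, fc_d, wis_quantile=0.5)
        assert cats["a"] is w.Category.ROBUST
        assert cats["b"] is w.Category.MODEL_SPECIFIC
        assert cats["c"] is w.Category.CONSISTENT_MODERATE
        assert cats["d"] is w.Category.LOW_SIGNAL


class TestAggregatePipeline:
    def test_feature_and_model_order_invariance(self):
        rng = np.random.default_rng(5)
        outs = [
            w.ModelImportance(f"m{j}", {f"x{i}": float(rng.uniform(0, 1)) for i in range(6)})
            for j in range(4)
        ]
        a = w.aggregate(outs)
        shuffled = [
            w.ModelImportance(o.model_id, dict(reversed(list(o.values.items()))), o.metric)
            for o in outs[::-1]
        ]
        b = w.aggregate(shuffled)
        pd.testing.assert_frame_equal(
            a.table.set_index("feature"), b.table.set_index("feature")
        )

    def test_unanimous_best_feature(self):
        """A feature ranked 1 by every model attains WIS 1 and FC = N for any k."""
        outs = [
            w.ModelImportance(f"m{j}", {"top": 10.0, "x": 2.0 + j, "y": 1.0})
            for j in range(4)
        ]
        res = w.aggregate(outs, w.AggregationConfig(k=1))
        row = res.table.set_index("feature").loc["top"]
        assert row["wis"] == pytest.approx(1.0)
        assert row["fc_count"] == 4
        assert row["final_rank"] == 1

    def test_result_invariants(self, churn_outputs):
        res = w.aggregate(churn_outputs, w.AggregationConfig(k=3))
        t = res.table
        assert (t["fc_fraction"] * res.n_models - t["fc_count"]).abs().max() == 0
        assert np.allclose(t["fc_percent"], 100 * t["fc_fraction"])
        assert sorted(t["final_rank"]) == list(range(1, len(t) + 1))

    def test_softmax_weighting_requires_performance(self):
        outs = [w.ModelImportance("m1", {"a": 1.0, "b": 2.0}), w.ModelImportance("m2", {"a": 2.0, "b": 1.0})]
        cfg = w.AggregationConfig(weighting=w.Weighting.SOFTMAX_PERFORMANCE)
        with pytest.raises(ValueError, match="performance"):
            w.aggregate(outs, cfg)

    def test_sum_scale_pipeline_has_fc_from_rank_companion(self, churn_outputs):
        cfg = w.AggregationConfig(k=3, normalization=w.Normalization.SUM_SCALE)
        res = w.aggregate(churn_outputs, cfg)
        t = res.table.set_index("feature")
        assert t.loc["tenure", "fc_count"] == 3
        assert res.orientation is Orientation.SCORE_HIGH_BEST

    def test_k_sweep_columns(self, worked_example):
        sweep = w.k_sweep(worked_example, ks=(3, 10))
        assert list(sweep.columns) == ["fc_fraction_k3", "fc_fraction_k10"]
        assert sweep.loc["cholesterol", "fc_fraction_k10"] == pytest.approx(0.8)
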