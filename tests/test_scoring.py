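import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glstrat import io
from glstrat.scoring import (
    ExpressionMatrix,
    ScoringError,
    area_tf_activity,
    cpm_normalize,
    expression_filter,
    immune_infiltration_scores,
    rci,
    ssgsea_score,
)

from _oracles import ssgsea_oracle


def _counts(arr, features=None, samples=None):
    arr = np.asarray(arr)
    features = features or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return io.CountMatrix(pd.DataFrame(arr, index=features, columns=samples))


def _expr(arr, features=None, samples=None, scale="cpm"):
    arr = np.asarray(arr, dtype=float)
    features = features or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=features, columns=samples), scale)


class TestCpm:
    def test_forced_arithmetic(self):
        expr = cpm_normalize(_counts([[5], [5]]))
        assert np.allclose(expr.values.to_numpy().ravel(), [500000, 500000])

    def test_scale_invariance_and_column_sums(self):
        cm = _counts([[3, 6], [7, 14]])
        expr = cpm_normalize(cm)
        assert np.allclose(expr.values.sum(axis=0), 1e6)
        assert np.allclose(expr.values["s0"], expr.values["s1"])

    def test_zero_library_rejected(self):
        with pytest.raises(ScoringError, match="s1"):
            cpm_normalize(_counts([[1, 0], [2, 0]]))


class TestExpressionFilter:
    def test_strict_boundaries(self):
        # count 11 in 95% of samples -> kept; count 10 everywhere -> dropped
        arr = np.full((2, 100), 10)
        arr[0, :95] = 11
        kept = expression_filter(_counts(arr), min_count=10, min_fraction=0.9)
        assert kept == ["g0"]

    def test_fraction_zero_keeps_any_expressed(self):
        arr = np.array([[11, 0, 0], [0, 0, 0]])
        kept = expression_filter(_counts(arr), min_count=10, min_fraction=0.0)
        assert kept == ["g0"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ScoringError):
            expression_filter(_counts(np.empty((0, 0), dtype=int)))


class TestSsgsea:
    def test_matches_enumeration_oracle_small_universe(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = rng.integers(5, 20)
            vals = rng.random((n, 3)) * 100
            m = rng.integers(1, n - 1)
            members = set(rng.choice(n, size=m, replace=False).tolist())
            gene_set = {f"g{i}" for i in members}
            alpha = rng.choice([0.0, 0.25, 0.75, 1.0])
            expr = _expr(vals)
            if len(gene_set) < 2:
                continue
            scores = ssgsea_score(expr, gene_set, weight_exponent=alpha, normalize=False)
            mask = np.array([i in members for i in range(n)])
            for j, s in enumerate(expr.sample_ids):
                expected = ssgsea_oracle(vals[:, j], mask, alpha)
                assert scores[s] == pytest.approx(expected, abs=1e-10)

    def test_top_pair_hand_enumeration(self):
        # 5-feature universe, set = top two features, alpha = 0; the 5-step
        # running sum is 1/2, 1, 1 - 1/3, 1 - 2/3, 0 -> integral 2.5
        vals = np.array([[50.0], [40.0], [30.0], [20.0], [10.0]])
        expr = _expr(vals)
        score = ssgsea_score(expr, {"g0", "g1"}, weight_exponent=0.0, normalize=False)
        expected = 0.5 + 1.0 + (1 - 1 / 3) + (1 - 2 / 3) + 0.0
        assert score["s0"] == pytest.approx(expected)
        mask = np.array([True, True, False, False, False])
        assert score["s0"] == pytest.approx(ssgsea_oracle(vals[:, 0], mask, 0.0))

    def test_identical_columns_identical_scores(self):
        vals = np.array([[3.0, 3.0], [2.0, 2.0], [1.0, 1.0], [5.0, 5.0]])
        s = ssgsea_score(_expr(vals), {"g0", "g3"}, normalize=False)
        assert s["s0"] == s["s1"]

    def test_top_set_beats_bottom_set_everywhere(self):
        rng = np.random.default_rng(1)
        vals = np.sort(rng.random((10, 4)), axis=0)[::-1] * 100
        expr = _expr(vals)
        top = ssgsea_score(expr, {"g0", "g1"}, normalize=False)
        bottom = ssgsea_score(expr, {"g8", "g9"}, normalize=False)
        assert (top > bottom).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        """Rank-based scores are unchanged by strictly monotone transforms."""
        rng = np.random.default_rng(seed)
        vals = rng.random((8, 2)) * 10
        gene_set = {"g1", "g4", "g6"}
        a = ssgsea_score(_expr(vals), gene_set, normalize=False)
        b = ssgsea_score(_expr(np.exp(vals / 3.0)), gene_set, normalize=False)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_preconditions(self):
        expr = _expr(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ScoringError):
            ssgsea_score(expr, {"g0"})
        with pytest.raises(ScoringError):
            ssgsea_score(expr, {"g0", "g1", "g2", "g3", "g4"})


class TestGeneSetScorer:
    def test_transformer_matches_functional_api(self, default_bundle, default_expression):
        from glstrat.scoring import GeneSetScorer

        sets = default_bundle.gene_sets
        scorer = GeneSetScorer(gene_sets={"GLY": sets["GLYCOLYSIS"]})
        X = default_expression.values.T  # samples x features
        out = scorer.fit(X).transform(X)
        direct = ssgsea_score(default_expression, sets["GLYCOLYSIS"])
        assert np.allclose(out["GLY"].to_numpy(), direct.to_numpy())

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        from glstrat.scoring import GeneSetScorer

        scorer = GeneSetScorer(gene_sets={"S": {"a", "b"}}, weight_exponent=0.5)
        cloned = clone(scorer)
        assert cloned.get_params()["weight_exponent"] == 0.5


class TestImmuneScores:
    def test_consistency_with_single_set_scoring(self, default_bundle, default_expression):
        sets = default_bundle.gene_sets
        marker = io.GeneSetCollection({"X": sets["GLYCOLYSIS"]}, {})
        scores = immune_infiltration_scores(default_expression, marker)
        direct = ssgsea_score(default_expression, sets["GLYCOLYSIS"])
        assert np.allclose(scores.loc["X"].to_numpy(), direct.to_numpy())

    def test_planted_blocks_score_their_own_group_higher(self):
        rng = np.random.default_rng(0)
        base = rng.normal(5, 1, size=(40, 40))
        base[:5, :20] += 3.0  # block A up in group 1
        base[5:10, 20:] += 3.0  # block B up in group 2
        expr = _expr(np.exp2(base))
        markers = io.GeneSetCollection(
            {"A": {f"g{i}" for i in range(5)}, "B": {f"g{i}" for i in range(5, 10)}}, {}
        )
        scores = immune_infiltration_scores(expr, markers)
        assert scores.loc["A"].iloc[:20].mean() > scores.loc["A"].iloc[20:].mean()
        assert scores.loc["B"].iloc[20:].mean() > scores.loc["B"].iloc[:20].mean()

    def test_empty_collection_gives_empty_matrix(self, default_expression):
        out = immune_infiltration_scores(default_expression, io.GeneSetCollection({}, {}))
        assert out.empty

    def test_error_names_cell_type(self, default_expression):
        bad = io.GeneSetCollection({"Tcell": {"NOT_A_GENE", "ALSO_NOT"}}, {})
        with pytest.raises(ScoringError, match="Tcell"):
            immune_infiltration_scores(default_expression, bad)


class TestAreaTfActivity:
    def _regulons(self, pairs):
        return io.RegulonCollection(pairs)

    def test_median_rank_targets_score_near_zero(self):
        # 11 features; targets sit at ranks 5-9 of 11 -> quantiles near 0
        vals = np.arange(11, dtype=float)[:, None] + 1
        expr = _expr(vals)
        regs = self._regulons({"TF": [(f"g{i}", 1) for i in (3, 4, 5, 6, 7)]})
        act = area_tf_activity(expr, regs)
        assert abs(act.loc["TF", "s0"]) < 0.1

    def test_flipping_modes_negates_activity(self, default_expression):
        regs1 = self._regulons({"TF": [(f"PCG000{i}", 1) for i in range(5)]})
        regs2 = self._regulons({"TF": [(f"PCG000{i}", -1) for i in range(5)]})
        a1 = area_tf_activity(default_expression, regs1)
        a2 = area_tf_activity(default_expression, regs2)
        assert np.allclose(a1.to_numpy(), -a2.to_numpy())

    def test_null_regulons_standard_normal(self):
        """Random regulons on exchangeable data give mean 0, variance 1."""
        rng = np.random.default_rng(0)
        vals = rng.random((200, 60))
        expr = _expr(vals)
        regs = {}
        for t in range(25):
            targets = rng.choice(200, size=10, replace=False)
            modes = rng.choice([1, -1], size=10)
            regs[f"T{t}"] = [(f"g{i}", int(m)) for i, m in zip(targets, modes)]
        act = area_tf_activity(expr, self._regulons(regs)).to_numpy().ravel()
        assert abs(act.mean()) < 0.05
        assert abs(act.var() - 1.0) < 0.15

    def test_small_regulon_skipped_with_warning(self, default_expression, caplog):
        regs = self._regulons({"TINY": [("PCG0000", 1), ("PCG0001", 1)]})
        with caplog.at_level("WARNING"):
            act = area_tf_activity(default_expression, regs)
        assert act.empty
        assert any("TINY" in r.message for r in caplog.records)

    def test_planted_active_tf_recovered(self, default_bundle, default_expression):
        act = area_tf_activity(default_expression.log2(), default_bundle.regulons)
        labels = default_bundle.truth.labels
        diff = act.loc[:, labels == 3].mean(axis=1) - act.loc[:, labels == 1].mean(axis=1)
        top3 = diff.sort_values(ascending=False).index[:3]
        assert set(top3) == set(default_bundle.truth.active_tfs)


class TestRci:
    def test_forced_log_ratio(self):
        cyt = _expr([[8.0]], features=["l1"])
        nuc = _expr([[2.0]], features=["l1"])
        assert rci(cyt, nuc, pseudo=0.0)["l1"] == pytest.approx(2.0)

    def test_equal_compartments_zero(self):
        vals = np.random.default_rng(0).random((5, 3))
        assert np.allclose(rci(_expr(vals), _expr(vals)).to_numpy(), 0.0)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = _expr(rng.random((5, 2))), _expr(rng.random((5, 2)))
        assert np.allclose(rci(a, b).to_numpy(), -rci(b, a).to_numpy())

    def test_feature_mismatch_rejected(self):
        a = _expr([[1.0]], features=["x"])
        b = _expr([[1.0]], features=["y"])
        with pytest.raises(ScoringError, match="mismatch"):
            rci(a, b)

    def test_nuclear_fraction_recovered_on_generated_compartments(self):
        from glstrat import generate_compartment_expression
        from glstrat.synthetic import CohortConfig

        cfg = CohortConfig(seed=0, n_lncrnas=300, n_compartment_samples=30)
        cyt, nuc, truth = generate_compartment_expression(cfg)
        r = rci(cpm_normalize(cyt), cpm_normalize(nuc))
        lnc_rci = r.loc[truth.index]
        frac_nuclear = (lnc_rci < 0).mean()
        assert abs(frac_nuclear - cfg.nuclear_fraction) < 0.07
        # planted sign agreement
        agree = (np.sign(lnc_rci) == np.sign(truth["expected_log2_ratio"])).mean()
        assert agree > 0.9
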