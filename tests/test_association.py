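import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glstrat.association import (
    DegenerateInputError,
    first_order_partial_correlation,
    ks_two_sample,
    multivariate_adjusted_association,
    partial_corr_from_r,
    partial_correlation_shift,
    pearson_with_fdr,
    select_associated_features,
)

from _oracles import bh_oracle, partial_corr_residual_oracle


def _frame(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


def _series(v):
    return pd.Series(np.asarray(v, dtype=float), index=[f"s{j}" for j in range(len(v))])


class TestPearsonWithFdr:
    def test_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        table = pearson_with_fdr(_series(x), _frame(x[None, :]))
        assert table["r"].iloc[0] == pytest.approx(1.0)
        assert table["p"].iloc[0] < 1e-12

    def test_bh_matches_stepup_by_hand(self):
        # p = [0.01, 0.02, 0.03] -> q = [0.03, 0.03, 0.03]
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(q, [0.03, 0.03, 0.03])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bh_equals_bruteforce_on_random_pvalues(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(8)
        assert np.allclose(multipletests(p, method="fdr_bh")[1], bh_oracle(list(p)))

    def test_zero_variance_feature_gets_nan_excluded_from_bh(self):
        rng = np.random.default_rng(0)
        arr = rng.random((3, 12))
        arr[1] = 5.0
        table = pearson_with_fdr(_series(rng.random(12)), _frame(arr))
        assert np.isnan(table["r"].iloc[1]) and np.isnan(table["q"].iloc[1])
        assert table["q"].drop("f1").notna().all()

    def test_permuted_score_yields_no_discoveries(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            arr = rng.random((50, 40))
            score = _series(rng.random(40))
            table = pearson_with_fdr(score, _frame(arr))
            hits += (table["q"] < 0.05).sum()
        assert hits <= 2

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4"):
            pearson_with_fdr(_series([1, 2, 3]), _frame(np.ones((2, 3))))


class TestSelection:
    def _table(self, rows):
        return pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))])

    def test_boundary_r_excluded(self):
        t = self._table([{"r": 0.3, "p": 1e-5, "q": 1e-4}])
        assert select_associated_features(t).empty

    def test_negative_r_included_with_sign(self):
        t = self._table([{"r": -0.5, "p": 1e-4, "q": 0.01}])
        out = select_associated_features(t)
        assert out["sign"].iloc[0] == -1

    def test_boundary_q_excluded(self):
        t = self._table([{"r": 0.9, "p": 0.04, "q": 0.05}])
        assert select_associated_features(t).empty


class TestPartialCorrelation:
    def test_formula_collapses_when_z_uncorrelated(self):
        assert partial_corr_from_r(0.42, 0.0, 0.0) == pytest.approx(0.42)

    def test_zero_numerator(self):
        assert partial_corr_from_r(0.12, 0.4, 0.3) == pytest.approx(0.0)

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(DegenerateInputError):
            partial_corr_from_r(0.5, 1.0, 0.2)

    def test_matches_residual_oracle_on_gaussian_data(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            z = rng.normal(size=50)
            x = 0.5 * z + rng.normal(size=50)
            y = -0.3 * z + rng.normal(size=50)
            ours = first_order_partial_correlation(x, y, z)
            assert ours == pytest.approx(partial_corr_residual_oracle(x, y, z), abs=1e-10)
            assert -1.0 <= ours <= 1.0

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        z = rng.normal(size=60)
        x = 0.7 * z + rng.normal(size=60)
        y = 0.4 * z + rng.normal(size=60)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        expected = pingouin.partial_corr(df, x="x", y="y", covar="z")["r"].iloc[0]
        assert first_order_partial_correlation(x, y, z) == pytest.approx(expected, abs=1e-9)


class TestKs:
    def test_identical_samples_zero_statistic(self):
        a = np.arange(10.0)
        D, p = ks_two_sample(a, a.copy())
        assert D == pytest.approx(0.0)

    def test_disjoint_supports(self):
        D, _ = ks_two_sample(np.linspace(0.1, 0.9, 20), np.linspace(2.1, 2.9, 20))
        assert D == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestPartialCorrelationShift:
    def test_independent_lncrna_leaves_distribution_unchanged(self):
        rng = np.random.default_rng(0)
        n = 200
        score = _series(rng.normal(size=n))
        genes = _frame(
            0.5 * score.to_numpy() + rng.normal(size=(60, n)), prefix="g"
        )
        lnc = _series(rng.normal(size=n))
        res = partial_correlation_shift(score, genes, lnc)
        assert res["ks_p"] > 0.1
        assert np.allclose(res["raw"], res["adjusted"], atol=0.08)

    def test_mediating_lncrna_shifts_distribution_toward_zero(self):
        rng = np.random.default_rng(1)
        n = 300
        z = rng.normal(size=n)
        score = _series(z + 0.4 * rng.normal(size=n))
        genes = _frame(z[None, :] + rng.normal(size=(200, n)), prefix="g")
        lnc = pd.Series(z + 0.2 * rng.normal(size=n), index=score.index)
        res = partial_correlation_shift(score, genes, lnc)
        assert res["ks_p"] < 0.01
        assert np.abs(res["adjusted"]).mean() < np.abs(res["raw"]).mean()

    def test_lncrna_equal_to_score_is_degenerate(self):
        score = _series(np.arange(20.0))
        genes = _frame(np.random.default_rng(0).random((12, 20)), prefix="g")
        with pytest.raises(DegenerateInputError):
            partial_correlation_shift(score, genes, score.copy())

    def test_few_genes_warns_but_computes(self, caplog):
        rng = np.random.default_rng(2)
        score = _series(rng.normal(size=30))
        genes = _frame(rng.normal(size=(4, 30)), prefix="g")
        with caplog.at_level("WARNING"):
            res = partial_correlation_shift(score, genes, _series(rng.normal(size=30)))
        assert "ks_p" in res
        assert any("10 genes" in r.message for r in caplog.records)


class TestMultivariateAdjusted:
    def test_gene_equal_to_lncrna_gives_unit_coefficient(self):
        rng = np.random.default_rng(0)
        n = 100
        lnc = _series(rng.normal(size=n))
        genes = _frame(lnc.to_numpy()[None, :], prefix="g")
        cnv = _series(rng.normal(size=n))
        meth = _series(rng.random(n))
        out = multivariate_adjusted_association(genes, lnc, cnv, meth)
        assert out["coefficient"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_gene_driven_by_cnv_gives_null_lncrna_coefficient(self):
        rng = np.random.default_rng(1)
        n = 200
        cnv = _series(rng.normal(size=n))
        genes = _frame(cnv.to_numpy()[None, :], prefix="g")
        lnc = _series(rng.normal(size=n))
        meth = _series(rng.random(n))
        out = multivariate_adjusted_association(genes, lnc, cnv, meth)
        assert abs(out["coefficient"].iloc[0]) < 0.1

    def test_confounded_association_shrinks_after_adjustment(self):
        rng = np.random.default_rng(2)
        shrunk = 0
        for rep in range(10):
            n = 150
            c = rng.normal(size=n)
            gene = c + rng.normal(size=n)
            lnc = c + rng.normal(size=n)
            raw_r = np.corrcoef(gene, lnc)[0, 1]
            out = multivariate_adjusted_association(
                _frame(gene[None, :], prefix="g"),
                _series(lnc),
                _series(c),
                _series(rng.random(n)),
            )
            shrunk += abs(out["coefficient"].iloc[0]) < abs(raw_r)
        assert shrunk >= 9

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(3)
        n = 50
        v = rng.normal(size=n)
        with pytest.raises(ValueError, match="collinear"):
            multivariate_adjusted_association(
                _frame(rng.normal(size=(2, n)), prefix="g"),
                _series(v),
                _series(v),
                _series(rng.random(n)),
            )
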