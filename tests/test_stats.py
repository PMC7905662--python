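import numpy as np
import pandas as pd
import pytest

from glstrat.stats import (
    anova_effect_screen,
    dunn_posthoc,
    fisher_enrichment,
    kaplan_meier,
    kruskal_wallis,
    logrank_test,
)

from _oracles import fisher_two_sided_oracle, km_product_limit_oracle


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        fit = kaplan_meier([5, 10, 15], [0, 0, 0])
        assert (fit.survival == 1.0).all()

    def test_single_event_among_four(self):
        fit = kaplan_meier([10, 20, 30, 40], [1, 0, 0, 0])
        assert fit.survival_at(10) == pytest.approx(0.75)

    def test_matches_hand_product_limit_with_censoring(self):
        times = [2, 4, 5, 7, 9, 11]
        events = [1, 0, 1, 0, 0, 0]
        fit = kaplan_meier(times, events)
        for t, s in km_product_limit_oracle(times, events):
            assert fit.survival_at(t) == pytest.approx(s)

    def test_pooled_identical_groups_equal_curve(self):
        times = [3, 6, 9, 12]
        events = [1, 1, 0, 1]
        single = kaplan_meier(times, events)
        pooled = kaplan_meier(times * 2, events * 2)
        for t in times:
            assert pooled.survival_at(t) == pytest.approx(single.survival_at(t))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        times = [5, 8, 12, 20, 25]
        events = [1, 1, 0, 1, 0]
        chi2, df, p = logrank_test(times * 2, events * 2, [0] * 5 + [1] * 5)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_three_group_df(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=30)
        chi2, df, p = logrank_test(t, np.ones(30), np.repeat([0, 1, 2], 10))
        assert df == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])

    def test_matches_permutation_oracle_small_fixture(self):
        """Two-group log-rank p agrees with a permutation reference."""
        rng = np.random.default_rng(0)
        times = np.concatenate([rng.exponential(10, 15), rng.exponential(25, 15)])
        events = rng.random(30) < 0.8
        groups = np.repeat([0, 1], 15)
        chi2, _, p = logrank_test(times, events, groups)
        perm_stats = []
        for _ in range(1000):
            perm = rng.permutation(groups)
            c, _, _ = logrank_test(times, events, perm)
            perm_stats.append(c)
        p_perm = np.mean(np.asarray(perm_stats) >= chi2)
        assert abs(p - p_perm) < 0.03

    def test_power_against_planted_hazard_ratio(self):
        from glstrat import generate_cohort

        from conftest import small_config

        detected = 0
        for seed in range(10):
            b = generate_cohort(small_config(seed=seed, n_samples=150))
            _, _, p = logrank_test(
                b.clinical.time, b.clinical.event, b.truth.labels.to_numpy()
            )
            detected += p < 0.01
        assert detected >= 9


class TestKruskalDunn:
    def test_constant_values(self):
        H, p = kruskal_wallis([5.0] * 9, np.repeat([1, 2, 3], 3))
        assert H == 0.0 and p == 1.0

    def test_ordered_groups_extreme_pair_largest_z(self):
        values = np.concatenate([np.arange(5), np.arange(10, 15), np.arange(20, 25)])
        groups = np.repeat([1, 2, 3], 5)
        table = dunn_posthoc(values, groups)
        extreme = table[(table.group_a == 1) & (table.group_b == 3)]["z"].abs().iloc[0]
        assert extreme == table["z"].abs().max()

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = [
            kruskal_wallis(rng.normal(size=30), np.repeat([0, 1, 2], 10))[1]
            for _ in range(300)
        ]
        assert 0.02 < np.mean(np.asarray(ps) < 0.05) < 0.10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], [1, 1])

    def test_dunn_agrees_with_kruskal_direction(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)])
        groups = np.repeat([1, 2], 20)
        table = dunn_posthoc(values, groups)
        assert table["z"].iloc[0] < 0  # group 1 mean rank below group 2


class TestFisher:
    def _matrix(self, rows, samples):
        return pd.DataFrame(
            rows, index=[f"m{i}" for i in range(len(rows))], columns=samples
        )

    def test_balanced_table_null(self):
        samples = [f"s{i}" for i in range(20)]
        labels = pd.Series([1] * 10 + [2] * 10, index=samples)
        row = [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5
        res = fisher_enrichment(self._matrix([row], samples), labels, focus=1, p_max=1.1)
        assert res[0].p == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 31)
            a = rng.integers(0, n + 1)
            b = rng.integers(0, n + 1 - a)
            c = rng.integers(0, n + 1 - a - b)
            d = n - a - b - c
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = fisher_exact([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-12)

    def test_symmetry_under_row_and_column_swap(self):
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[7, 2], [3, 9]])
        _, p_rows = fisher_exact([[3, 9], [7, 2]])
        _, p_cols = fisher_exact([[2, 7], [9, 3]])
        assert p == pytest.approx(p_rows) == pytest.approx(p_cols)

    def test_constant_feature_noted(self):
        samples = [f"s{i}" for i in range(10)]
        labels = pd.Series([1] * 5 + [2] * 5, index=samples)
        res = fisher_enrichment(self._matrix([[1] * 10], samples), labels, focus=1)
        assert res[0].note == "constant feature"
        assert res[0].p == 1.0

    def test_planted_mutation_detected_across_seeds(self):
        from glstrat import generate_cohort

        from conftest import small_config

        detected = 0
        for seed in range(10):
            b = generate_cohort(small_config(seed=seed, n_samples=150))
            res = fisher_enrichment(b.mutations, b.truth.labels, focus=3, p_max=0.01)
            detected += any(
                r.feature_id == b.truth.enriched_mutation and r.odds_ratio > 1
                for r in res
            )
        assert detected >= 9


class TestAnovaScreen:
    def _values(self, rows):
        arr = np.asarray(rows, dtype=float)
        return pd.DataFrame(
            arr,
            index=[f"f{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        )

    def _labels(self, groups):
        return pd.Series(groups, index=[f"s{j}" for j in range(len(groups))])

    def test_identical_groups_excluded(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=30)
        out = anova_effect_screen(
            self._values([np.tile(row[:10], 3)]), self._labels(np.repeat([1, 2, 3], 10))
        )
        assert not out["selected"].iloc[0]

    def test_cohen_f_boundary_excluded(self):
        # two groups, means 0 and 1, sd ~1 -> f ~ 0.5; strict > excludes values at the boundary
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 2000)
        b = rng.normal(1, 1, 2000)
        a = (a - a.mean()) / a.std(ddof=0)
        b = (b - b.mean()) / b.std(ddof=0) + 1.0
        out = anova_effect_screen(
            self._values([np.concatenate([a, b])]),
            self._labels(np.repeat([1, 2], 2000)),
            es_min=0.5,
        )
        assert out["effect_size"].iloc[0] == pytest.approx(0.5, abs=0.01)
        assert not out["selected"].iloc[0]

    def test_null_features_rarely_selected(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(200, 60))
        out = anova_effect_screen(
            self._values(vals), self._labels(np.repeat([1, 2, 3], 20))
        )
        assert out["selected"].mean() < 0.02

    def test_effect_size_variants(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(3, 1, 50)])
        labels = self._labels(np.repeat([1, 2], 50))
        for effect in ("cohen_f", "eta_squared", "max_cohen_d"):
            out = anova_effect_screen(self._values([vals]), labels, effect=effect)
            assert out["selected"].iloc[0]

    def test_zero_within_variance_flagged(self):
        out = anova_effect_screen(
            self._values([[1.0] * 5 + [2.0] * 5]), self._labels(np.repeat([1, 2], 5))
        )
        assert out["zero_within_variance"].iloc[0]
        assert np.isinf(out["effect_size"].iloc[0])
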