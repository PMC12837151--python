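"""Percentile thresholds and the four-category classification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from abubench import (
    Category,
    PercentileBenchmark,
    categorize,
    classify_cohort,
    compute_thresholds,
    mean_pati_contributions,
    percentile,
)

PATI_COLS = ["practice_id", "species", "year", "scope", "pati", "corrected", "practice_type"]


def _table(rows):
    return pd.DataFrame(rows, columns=PATI_COLS)


def _practice_years(pid, values, species="dog", scope="all", ptype="mixed", corrected=None):
    corrected = corrected or [False] * len(values)
    return [
        (pid, species, 2022 + i, scope, v, c, ptype)
        for i, (v, c) in enumerate(zip(values, corrected))
    ]


class TestPercentile:
    def test_closed_form_on_integers_1_to_100(self):
        assert percentile(range(1, 101), 0.95) == pytest.approx(95.05)
        assert percentile(range(1, 101), 0.75) == pytest.approx(75.25)

    def test_single_value_and_constant_vector(self):
        assert percentile([3.2], 0.1) == 3.2
        assert percentile([3.2], 0.9) == 3.2
        assert percentile([5.0] * 17, 0.75) == 5.0

    def test_matches_library_quantile_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(1, 60))
            xs = rng.exponential(size=n)
            q = float(rng.random())
            assert percentile(xs, q) == pytest.approx(
                float(np.quantile(xs, q)), rel=1e-12, abs=1e-12
            )

    def test_rejects_empty_and_bad_q(self):
        with pytest.raises(ValueError):
            percentile([], 0.5)
        with pytest.raises(ValueError):
            percentile([1.0], 1.5)


class TestMeanContributions:
    def test_corrected_years_excluded_from_mean(self):
        table = _table(
            _practice_years("A", [0.5, 0.7, 9.9], corrected=[False, False, True])
        )
        out = mean_pati_contributions(table)
        assert len(out) == 1
        assert out["mean_pati"].iloc[0] == pytest.approx(0.6)

    def test_non_users_contribute_nothing(self):
        table = _table(_practice_years("A", [0.0, 0.0, 0.0]))
        assert len(mean_pati_contributions(table)) == 0

    def test_null_years_dropped_from_mean(self):
        table = _table(_practice_years("A", [0.0, 0.4, 0.8]))
        out = mean_pati_contributions(table)
        assert out["mean_pati"].iloc[0] == pytest.approx(0.6)

    def test_matches_filter_and_mean_oracle(self, small_pipeline):
        table = small_pipeline.pati_table
        out = mean_pati_contributions(table).set_index(
            ["practice_id", "practice_type", "species", "scope"]
        )["mean_pati"]
        # brute force over raw rows
        expected = {}
        for _, r in table.iterrows():
            if r.corrected or r.pati <= 0:
                continue
            expected.setdefault(
                (r.practice_id, r.practice_type, r.species, r.scope), []
            ).append(r.pati)
        assert len(out) == len(expected)
        for key, vals in expected.items():
            assert out.loc[key] == pytest.approx(sum(vals) / len(vals))


class TestThresholds:
    def test_all_twelve_strata_populated(self, small_pipeline):
        thr = small_pipeline.benchmark.thresholds_
        assert len(thr) == 12
        assert (thr["signal"] <= thr["action"]).all()
        assert (thr["signal"] > 0).all()
        assert (thr["n_contributing"] >= 1).all()

    def test_twenty_value_fixture_matches_sort_and_interpolate(self):
        rng = np.random.default_rng(5)
        vals = rng.exponential(size=20)
        rows = [
            (f"P{i}", "dog", 2024, "all", v, False, "mixed") for i, v in enumerate(vals)
        ]
        thr = compute_thresholds(_table(rows))
        assert thr["signal"].iloc[0] == pytest.approx(float(np.quantile(vals, 0.75)))
        assert thr["action"].iloc[0] == pytest.approx(float(np.quantile(vals, 0.95)))
        assert thr["n_contributing"].iloc[0] == 20

    def test_stochastically_larger_species_gets_larger_thresholds(self):
        rng = np.random.default_rng(6)
        dogs = rng.lognormal(0, 0.5, 40)
        rows = []
        for i, v in enumerate(dogs):
            rows += [(f"P{i}", "dog", 2024, "all", v, False, "mixed")]
            rows += [(f"P{i}", "cat", 2024, "all", v * 2.0, False, "mixed")]
        thr = compute_thresholds(_table(rows)).set_index("species")
        assert thr.loc["cat", "signal"] > thr.loc["dog", "signal"]
        assert thr.loc["cat", "action"] > thr.loc["dog", "action"]

    def test_invariant_to_permutation_and_duplication(self):
        rng = np.random.default_rng(7)
        rows = [
            (f"P{i}", "dog", 2024, "all", v, False, "mixed")
            for i, v in enumerate(rng.exponential(size=25))
        ]
        table = _table(rows)
        thr = compute_thresholds(table)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(thr, compute_thresholds(shuffled))
        doubled = _table(
            rows + [(f"Q{i}", *r[1:]) for i, r in enumerate(rows)]
        )
        # duplication shifts the interpolation position within one
        # order-statistic gap, so agreement is approximate, not exact
        thr2 = compute_thresholds(doubled)
        assert thr2["signal"].iloc[0] == pytest.approx(thr["signal"].iloc[0], rel=0.05)
        assert thr2["action"].iloc[0] == pytest.approx(thr["action"].iloc[0], rel=0.05)


class TestCategorize:
    @pytest.mark.parametrize(
        "pati, expected",
        [
            (0.0, Category.NONE),
            (1e-9, Category.ACCEPTABLE),
            (0.5, Category.ACCEPTABLE),
            (1.0, Category.ACCEPTABLE),  # exactly at signal
            (1.2, Category.HIGH),
            (2.0, Category.HIGH),  # exactly at action
            (2.0 + 1e-12, Category.VERY_HIGH),
            (99.0, Category.VERY_HIGH),
        ],
    )
    def test_boundaries_above_is_strict(self, pati, expected):
        assert categorize(pati, signal=1.0, action=2.0) is expected

    def test_monotone_in_pati(self):
        order = [Category.NONE, Category.ACCEPTABLE, Category.HIGH, Category.VERY_HIGH]
        rng = np.random.default_rng(8)
        grid = np.sort(np.concatenate([[0.0, 1.0, 2.0], rng.uniform(0, 3, 50)]))
        ranks = [order.index(categorize(p, 1.0, 2.0)) for p in grid]
        assert ranks == sorted(ranks)

    def test_negative_pati_rejected(self):
        with pytest.raises(ValueError):
            categorize(-0.1, 1.0, 2.0)


class TestClassifyCohort:
    def test_corrected_practices_are_classified(self):
        rows = []
        for i in range(20):
            rows += _practice_years(f"P{i}", [0.5 + 0.01 * i] * 3)
        rows += _practice_years("CORR", [3.0] * 3, corrected=[True] * 3)
        table = _table(rows)
        cats = classify_cohort(table)
        corr = cats[cats.practice_id == "CORR"]
        assert len(corr) == 1
        assert corr["category"].iloc[0] == Category.VERY_HIGH.value

    def test_classification_limited_to_eligible_species(self, small_pipeline):
        cats = small_pipeline.categories
        pt = small_pipeline.pati_table
        year = small_pipeline.benchmark_year
        scored = set(map(tuple, pt[pt.year == year][["practice_id", "species"]].values))
        classified = set(map(tuple, cats[["practice_id", "species"]].values))
        assert classified <= scored

    def test_retrospective_year_uses_same_thresholds(self):
        rows = []
        for i in range(20):
            rows += _practice_years(f"P{i}", [0.5, 5.0, 0.5])
        table = _table(rows)
        bench = PercentileBenchmark().fit(table)
        past = bench.predict(table, year=2023)
        assert len(past) == 20
        # every 2023 value sits above the action threshold built from means
        assert (past["category"] == Category.VERY_HIGH.value).all()

    def test_contributor_share_above_thresholds_is_bounded(self, small_pipeline):
        """Among threshold contributors the very-high share cannot exceed
        5% + 1/n, nor the above-signal share 25% + 1/n, by construction
        of the interpolated percentiles."""
        bench = small_pipeline.benchmark
        contrib = bench.contributions_
        thr = bench.thresholds_
        for _, t in thr.iterrows():
            g = contrib[
                (contrib.practice_type == t.practice_type)
                & (contrib.species == t.species)
                & (contrib.scope == t.scope)
            ]["mean_pati"]
            n = len(g)
            assert (g > t.action).mean() <= 0.05 + 1.0 / n
            assert (g > t.signal).mean() <= 0.25 + 1.0 / n


class TestEstimatorApi:
    def test_get_params_set_params_clone(self):
        est = PercentileBenchmark(signal_q=0.8, action_q=0.9, benchmark_year=2023)
        params = est.get_params()
        assert params == {"signal_q": 0.8, "action_q": 0.9, "benchmark_year": 2023}
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(signal_q=0.7)
        assert est.signal_q == 0.7

    def test_unfitted_predict_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            PercentileBenchmark().predict(_table([]))

    def test_invalid_quantile_order_raises(self):
        with pytest.raises(ValueError):
            PercentileBenchmark(signal_q=0.9, action_q=0.5).fit(
                _table(_practice_years("A", [0.5] * 3))
            )
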