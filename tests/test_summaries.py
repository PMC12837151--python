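"""Printed-share rounding, practice/cohort summaries, canton aggregation,
and the cluster-bootstrap quantile comparison."""

import collections

import numpy as np
import pandas as pd
import pytest

from abubench import bootstrap_quantile_diff, canton_summary, ratio_pct, summarize_practice
from abubench.summaries import practice_species_stats, summarize_cohort

PRESC_COLS = [
    "practice_id", "year", "species", "vmp_id", "substances",
    "therapy_days", "animals_treated", "indication", "dosage_mg_per_kg",
]


def _presc(rows):
    return pd.DataFrame(rows, columns=PRESC_COLS)


class TestRatioPct:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (686, 989, 69.4),
            (9, 32, 28.1),
            (0, 7, 0.0),
            (1, 16, 6.3),  # 6.25 rounds half away from zero
            (25, 200, 12.5),  # exact one-decimal value untouched
        ],
    )
    def test_half_away_from_zero_one_decimal(self, num, den, expected):
        assert ratio_pct(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ratio_pct(1, 0)


class TestPracticeSummary:
    def test_treatment_percentage(self, catalog):
        rows = [
            ("A", 2024, "dog", "VMP-amoxicillin", "amoxicillin", 7.0, 60, "wound", 10.0),
            ("A", 2024, "dog", "VMP-cefovecin", "cefovecin", 1.0, 60, "skin_infection", 8.0),
        ]
        s = summarize_practice(_presc(rows), "A", "dog", 2024, 1000, catalog)
        assert s.n_treatments == 120
        assert s.pct_ab_treatments == pytest.approx(12.0)
        assert s.n_critical_treatments == 60
        assert s.pct_critical == pytest.approx(50.0)
        # therapy days incl. carry-over: (7*60 + 14*60) / 120
        assert s.therapy_days_per_animal == pytest.approx((7 * 60 + 14 * 60) / 120)
        assert sum(s.treatments_by_class.values()) == s.n_treatments
        assert sum(s.treatments_by_indication.values()) == s.n_treatments

    def test_no_treatments(self, catalog):
        s = summarize_practice(_presc([]), "A", "dog", 2024, 500, catalog)
        assert s.n_treatments == 0 and s.pct_critical == 0.0
        assert s.top_vmps == [] and s.pct_ab_treatments == 0.0

    def test_top_vmps_are_ten_most_frequent(self, catalog):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(12):
            for _ in range(int(rng.integers(1, 30))):
                rows.append(
                    ("A", 2024, "dog", f"VMP{i:02d}", "amoxicillin", 5.0, 1, "wound",
                     float(rng.choice([5.0, 10.0, 10.0, 20.0])))
                )
        df = _presc(rows)
        s = summarize_practice(df, "A", "dog", 2024, 5000, catalog)
        counts = collections.Counter(df["vmp_id"])  # brute-force ranking
        expected = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
        assert [(v, c) for v, c, _ in s.top_vmps] == expected

    def test_modal_dosage_ties_take_smallest(self, catalog):
        rows = [
            ("A", 2024, "dog", "V", "amoxicillin", 5.0, 1, "wound", d)
            for d in (10.0, 10.0, 5.0, 5.0, 20.0)
        ]
        s = summarize_practice(_presc(rows), "A", "dog", 2024, 500, catalog)
        assert s.top_vmps[0][2] == 5.0


class TestCohortSummary:
    def test_single_practice_stratum_degenerates_to_its_values(self, catalog):
        elig = pd.DataFrame(
            [("A", "dog", 2024, 1000.0, 1000.0, False, True, None)],
            columns=["practice_id", "species", "year", "nbconsult_raw",
                     "nbconsult_used", "corrected", "eligible", "exclusion_reason"],
        )
        presc = _presc([("A", 2024, "dog", "V", "amoxicillin", 5.0, 80, "wound", 10.0)])
        stats = practice_species_stats(presc, elig, catalog, 2024)
        pati = pd.DataFrame(
            [("A", "dog", 2024, "all", 0.4, False, "mixed"),
             ("A", "dog", 2024, "critical", 0.0, False, "mixed")],
            columns=["practice_id", "species", "year", "scope", "pati", "corrected", "practice_type"],
        )
        out = summarize_cohort(stats, pati, 2024)
        row = out.iloc[0]
        assert row.consultations_median == row.consultations_mean == row.consultations_max == 1000
        assert row.treatments_median == row.treatments_mean == row.treatments_max == 80
        assert row.pct_ab_treatments_median == pytest.approx(8.0)
        assert row.pati_median == pytest.approx(0.4)
        assert row.n_practices == 1

    def test_invariant_to_row_order_and_matches_sort_oracle(self, small_pipeline):
        stats = small_pipeline.stats
        pati = small_pipeline.pati_table
        out = summarize_cohort(stats, pati, small_pipeline.benchmark_year)
        shuffled = summarize_cohort(
            stats.sample(frac=1.0, random_state=1).reset_index(drop=True),
            pati.sample(frac=1.0, random_state=2).reset_index(drop=True),
            small_pipeline.benchmark_year,
        )
        pd.testing.assert_frame_equal(out, shuffled)
        # median against a sort-based oracle for one stratum
        row = out.iloc[0]
        merged = stats.merge(
            pati[(pati.year == small_pipeline.benchmark_year) & (pati.scope == "all")],
            on=["practice_id", "species"],
        )
        g = merged[(merged.practice_type == row.practice_type) & (merged.species == row.species)]
        xs = sorted(g["nbconsult_used"])
        n = len(xs)
        med = xs[n // 2] if n % 2 else 0.5 * (xs[n // 2 - 1] + xs[n // 2])
        assert row.consultations_median == pytest.approx(med)


class TestCantonSummary:
    def test_single_canton_gets_full_share(self, catalog):
        practices = pd.DataFrame(
            {"practice_id": ["A", "B"], "declared_type": ["mixed_practice"] * 2, "canton": ["BE"] * 2}
        )
        categories = pd.DataFrame({"practice_id": ["A", "B"]})
        presc = _presc([("A", 2024, "dog", "V", "amoxicillin", 5.0, 10, "wound", 1.0)])
        out = canton_summary(practices, categories, presc, 2024)
        assert out["share_practices_pct"].tolist() == [100.0]
        assert out["share_treatments_pct"].tolist() == [100.0]

    def test_counts_only_benchmarked_practices(self, catalog):
        practices = pd.DataFrame(
            {
                "practice_id": ["A", "B", "C"],
                "declared_type": ["mixed_practice"] * 3,
                "canton": ["BE", "BE", "ZH"],
            }
        )
        categories = pd.DataFrame({"practice_id": ["A", "C"]})  # B not benchmarked
        out = canton_summary(practices, categories, _presc([]), 2024).set_index("canton")
        assert out.loc["BE", "n_practices"] == 1
        assert out.loc["ZH", "n_practices"] == 1

    def test_raw_shares_sum_to_100(self, small_pipeline):
        out = canton_summary(
            small_pipeline.practices, small_pipeline.categories,
            small_pipeline.prescriptions, small_pipeline.benchmark_year,
        )
        assert out["share_practices_raw"].sum() == pytest.approx(100.0)
        assert out["share_treatments_raw"].sum() == pytest.approx(100.0)


class TestBootstrapQuantileDiff:
    def test_identical_groups_give_zero_and_p_one(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 1, 50)
        ids = np.arange(50)
        res = bootstrap_quantile_diff(vals, vals, 0.5, ids, ids, n_boot=500, seed=2)
        assert res.estimate == 0.0
        assert res.p_value > 0.99

    def test_constant_shift_detected_at_median(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 1, 200)
        b = a + 1.0
        ids = np.arange(200)
        res = bootstrap_quantile_diff(a, b, 0.5, ids, ids, n_boot=500, seed=3)
        assert res.estimate == pytest.approx(-1.0)
        assert res.p_value < 0.05
        assert res.ci_low <= -1.0 <= res.ci_high or res.ci_high < 0

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.3, 1, 40)
        ids = np.arange(40)
        r1 = bootstrap_quantile_diff(a, b, 0.75, ids, ids, n_boot=300, seed=9)
        r2 = bootstrap_quantile_diff(a, b, 0.75, ids, ids, n_boot=300, seed=9)
        assert r1 == r2

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            bootstrap_quantile_diff([1.0] * 5, [1.0] * 20, 0.5, list(range(5)),
                                    list(range(20)), n_boot=200, seed=0)

    def test_too_few_replicates_rejected(self):
        ids = list(range(20))
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_quantile_diff(list(range(20)), list(range(20)), 0.5, ids, ids,
                                    n_boot=50, seed=0)

    def test_unequal_cluster_sizes_supported(self):
        """Clusters holding several values (e.g. multiple years) take the
        slow path; the estimate is still the plain quantile difference."""
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0, 1, 45)
        ids_a = np.repeat(np.arange(30), 2)
        ids_b = np.repeat(np.arange(15), 3)
        res = bootstrap_quantile_diff(a, b, 0.5, ids_a, ids_b, n_boot=300, seed=6)
        assert res.estimate == pytest.approx(float(np.quantile(a, 0.5) - np.quantile(b, 0.5)))
        assert 0.0 <= res.p_value <= 1.0
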