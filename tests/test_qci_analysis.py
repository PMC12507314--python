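import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bcqci.qci_analysis import (
    assign_case_mix,
    case_mix_weights,
    kruskal_wallis,
    outcome_category_costs,
    pooled_proportion,
    qci_value,
    quarter_label,
    quarterly_summaries,
    standardize_over_case_mix,
)
from conftest import make_record


class TestQciValue:
    def test_unit_case(self):
        assert qci_value(1.0, 1000.0) == pytest.approx(100.0)

    def test_zero_outcome(self):
        assert qci_value(0.0, 12345.0) == 0.0

    def test_published_totals_cross_check(self):
        # direct arithmetic: (786/1449 * 100) / 29.297
        expected = (786 / 1449 * 100) / (29297 / 1000)
        assert qci_value(786 / 1449, 29297.0) == pytest.approx(expected)
        assert expected == pytest.approx(1.8515, abs=5e-4)

    @given(p=st.floats(0.01, 1.0), c=st.floats(100.0, 1e6))
    @settings(max_examples=50, derandomize=True)
    def test_homogeneity_in_cost(self, p, c):
        assert qci_value(p, 2 * c) == pytest.approx(qci_value(p, c) / 2)

    def test_nonpositive_cost_rejected(self):
        with pytest.raises(ValueError):
            qci_value(0.5, 0.0)


class TestQuarterly:
    def _cohort(self, dates):
        return [
            make_record(patient_id=f"P{i}", qci_date=d) for i, d in enumerate(dates)
        ]

    def test_single_quarter(self):
        import datetime as dt

        cohort = self._cohort([dt.date(2021, 2, d) for d in (1, 10, 20)])
        out = quarterly_summaries(cohort, [1000.0, 2000.0, 3000.0], [True, True, False])
        assert len(out) == 1 and out.loc[0, "quarter"] == "2021-Q1"
        assert out.loc[0, "n"] == 3
        assert out.loc[0, "to_proportion"] == pytest.approx(2 / 3)
        assert out.loc[0, "avg_total_cost"] == pytest.approx(2000.0)

    def test_empty_quarters_reported_not_dropped(self):
        import datetime as dt

        cohort = self._cohort([dt.date(2020, 1, 5), dt.date(2020, 12, 5)])
        out = quarterly_summaries(
            cohort, [1.0, 1.0], [True, False],
            window=(dt.date(2020, 1, 1), dt.date(2020, 12, 31)),
        )
        assert list(out["quarter"]) == ["2020-Q1", "2020-Q2", "2020-Q3", "2020-Q4"]
        assert list(out["n"]) == [1, 0, 0, 1]

    def test_date_outside_window_rejected(self):
        import datetime as dt

        cohort = self._cohort([dt.date(2024, 1, 1)])
        with pytest.raises(ValueError):
            quarterly_summaries(cohort, [1.0], [True],
                                window=(dt.date(2020, 1, 1), dt.date(2023, 6, 30)))

    def test_order_invariance(self, small_cohort):
        rng = np.random.default_rng(0)
        costs = rng.lognormal(9, 1, len(small_cohort))
        to = rng.uniform(size=len(small_cohort)) < 0.5
        a = quarterly_summaries(small_cohort, costs, to)
        perm = rng.permutation(len(small_cohort))
        b = quarterly_summaries(
            [small_cohort[i] for i in perm], costs[perm], to[perm]
        )
        pd.testing.assert_frame_equal(a, b)

    def test_pooled_proportion_is_patient_weighted(self, small_cohort):
        rng = np.random.default_rng(1)
        to = rng.uniform(size=len(small_cohort)) < 0.6
        out = quarterly_summaries(small_cohort, np.ones(len(small_cohort)), to)
        assert pooled_proportion(out) == pytest.approx(np.mean(to))


class TestCaseMix:
    @pytest.mark.parametrize(
        "age,tbsa,etiology,cell",
        [
            (60, 5.0, "flame", ("18-60", "0-5", "flame")),
            (61, 20.5, "scald", (">60", ">20", "other")),
            (25, 20.0, "electrical", ("18-60", "11-20", "other")),
            (80, 6.0, "flame", (">60", "6-10", "flame")),
        ],
    )
    def test_banding_boundaries(self, age, tbsa, etiology, cell):
        rec = make_record(age_years=age, tbsa_percent=tbsa, etiology=etiology)
        assert assign_case_mix(rec) == cell

    def test_grid_partitions_cohort(self, small_cohort):
        cells = [assign_case_mix(r) for r in small_cohort]
        w = case_mix_weights(cells)
        assert w.sum() == pytest.approx(1.0)
        assert len(cells) == len(small_cohort)

    def test_identity_weighting_returns_crude(self):
        df = pd.DataFrame(
            {
                "quarter": ["2020-Q1"] * 6,
                "cell": ["a", "a", "a", "b", "b", "b"],
                "to": [1, 0, 1, 0, 0, 1],
                "cost": [10.0, 20.0, 30.0, 100.0, 200.0, 300.0],
            }
        )
        out = standardize_over_case_mix(df)  # reference = this quarter's own mix
        assert out.loc[0, "adjusted_to"] == pytest.approx(out.loc[0, "crude_to"])
        assert out.loc[0, "adjusted_cost"] == pytest.approx(out.loc[0, "crude_cost"])

    def test_two_stratum_hand_computation(self):
        # quarter: cell a -> mean cost 20, TO 2/3 ; cell b -> 200, TO 1/3
        # reference weights: a 0.25, b 0.75
        df = pd.DataFrame(
            {
                "quarter": ["Q"] * 6,
                "cell": ["a", "a", "a", "b", "b", "b"],
                "to": [1, 0, 1, 0, 0, 1],
                "cost": [10.0, 20.0, 30.0, 100.0, 200.0, 300.0],
            }
        )
        w = pd.Series({"a": 0.25, "b": 0.75})
        out = standardize_over_case_mix(df, weights=w)
        assert out.loc[0, "adjusted_cost"] == pytest.approx(0.25 * 20 + 0.75 * 200)
        assert out.loc[0, "adjusted_to"] == pytest.approx(0.25 * (2 / 3) + 0.75 * (1 / 3))

    def test_adjusted_proportion_convex(self, small_cohort):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "quarter": [quarter_label(r.qci_date) for r in small_cohort],
                "cell": [assign_case_mix(r) for r in small_cohort],
                "to": rng.uniform(size=len(small_cohort)) < 0.5,
                "cost": rng.lognormal(9, 1, len(small_cohort)),
            }
        )
        out = standardize_over_case_mix(df)
        strata = df.groupby(["quarter", "cell"])["to"].mean()
        for _, row in out.iterrows():
            qs = strata.loc[row["quarter"]]
            assert qs.min() - 1e-12 <= row["adjusted_to"] <= qs.max() + 1e-12

    def test_missing_stratum_excluded_with_renormalization(self):
        df = pd.DataFrame(
            {
                "quarter": ["Q1", "Q1", "Q2", "Q2"],
                "cell": ["a", "b", "a", "a"],
                "to": [1, 0, 1, 0],
                "cost": [10.0, 30.0, 40.0, 60.0],
            }
        )
        out = standardize_over_case_mix(df).set_index("quarter")
        assert out.loc["Q2", "n_cells_excluded"] == 1
        # with only cell a present, the renormalized weight is 1 on a
        assert out.loc["Q2", "adjusted_cost"] == pytest.approx(50.0)


def _kw_h_oracle(groups):
    """Independent tie-corrected H from first principles."""
    pooled = np.concatenate(groups)
    n = pooled.size
    order = stats.rankdata(pooled)
    h = 12.0 / (n * (n + 1)) * sum(
        len(g) * (order[i:i + len(g)].mean() - (n + 1) / 2) ** 2
        for g, i in zip(groups, np.cumsum([0] + [len(g) for g in groups[:-1]]))
    )
    _, c = np.unique(pooled, return_counts=True)
    return h / (1 - ((c**3 - c).sum()) / (n**3 - n))


class TestKruskalWallis:
    def test_identical_groups_not_significant(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert p > 0.05

    def test_all_identical_observations(self):
        assert kruskal_wallis([[5, 5, 5], [5, 5]]) == (0.0, 1.0)

    def test_matches_scipy_on_large_groups(self):
        rng = np.random.default_rng(0)
        a, b, c = rng.normal(size=40), rng.normal(1, 1, 35), rng.normal(0.5, 2, 30)
        h, p = kruskal_wallis([a, b, c])
        h2, p2 = stats.kruskal(a, b, c)
        assert (h, p) == (pytest.approx(h2), pytest.approx(p2))

    def test_exact_p_on_separated_groups_is_permutation_fraction(self):
        # full enumeration of the C(6,3)=20 assignments: only the 2 extreme
        # splits reach the observed H, so p = 2/20
        h, p = kruskal_wallis([[1, 2, 3], [10, 11, 12]], method="exact")
        assert p == pytest.approx(2 / 20)

    def test_exact_statistic_agrees_with_enumeration_oracle(self):
        values = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        for k in range(1, 6):
            for combo in itertools.combinations(range(6), k):
                g1 = values[list(combo)]
                g2 = values[[i for i in range(6) if i not in combo]]
                h, _ = kruskal_wallis([g1, g2], method="exact")
                assert h == pytest.approx(_kw_h_oracle([g1, g2]), abs=1e-12)

    def test_type_one_error_near_nominal(self):
        """Null rejection rate of the chi-square approximation ~ alpha."""
        rng = np.random.default_rng(2024)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a, b = rng.normal(size=50), rng.normal(size=50)
            _, p = kruskal_wallis([a, b])
            rejections += p < 0.05
        assert 0.04 <= rejections / reps <= 0.06

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestOutcomeCategories:
    def _matrix(self, n, fail_counts, seed=0):
        rng = np.random.default_rng(seed)
        from bcqci.indicators import INDICATORS

        data = {}
        for ind in INDICATORS:
            fails = fail_counts.get(ind, n // 4)
            col = np.ones(n, dtype=bool)
            col[rng.choice(n, size=fails, replace=False)] = False
            data[ind] = col
        return pd.DataFrame(data)

    def test_small_arm_merged_into_other(self):
        m = self._matrix(60, {"wound_infection": 3})
        costs = np.arange(60, dtype=float)
        out = outcome_category_costs(m, costs, min_cell=5, B=50, seed=0)
        assert "wound_infection" not in set(out["category"])
        other = out[out["category"] == "other"].iloc[0]
        assert "wound_infection" in other["merged_from"]

    def test_no_merging_when_arms_large_enough(self):
        m = self._matrix(100, {})
        out = outcome_category_costs(m, np.ones(100), min_cell=5, B=10, seed=0)
        assert set(out["category"]) == {
            "length_of_stay", "wound_infection", "other_complications",
            "discharge_destination", "predicted_mortality",
        }

    def test_other_mean_is_patient_weighted_over_constituents(self):
        m = self._matrix(80, {"wound_infection": 2, "predicted_mortality": 3}, seed=5)
        rng = np.random.default_rng(8)
        costs = rng.lognormal(9, 1, 80)
        out = outcome_category_costs(m, costs, min_cell=5, B=20, seed=1)
        other = out[out["category"] == "other"].iloc[0]
        merged = other["merged_from"].split(",")
        # brute-force: fail 'other' = failed at least one merged indicator
        failed_any = ~m[merged].all(axis=1)
        assert other["mean_failed"] == pytest.approx(costs[failed_any].mean())
        assert other["mean_achieved"] == pytest.approx(costs[~failed_any].mean())
        assert other["n_failed"] == int(failed_any.sum())
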