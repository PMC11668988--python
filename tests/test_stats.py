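import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from wearpa.config import PipelineConfig
from wearpa.simulate import PUBLISHED_GROUP_COUNTS, AdherenceModel, simulate_outcomes
from wearpa.stats import (
    age_group_of,
    assign_age_group,
    classify_bmi,
    filter_adult_minutes,
    fit_logistic,
    group_adherence_table,
    mcnemar_compare_methods,
    odds_ratio_from_counts,
    pairwise_chisq,
)
from .conftest import make_minutes


class TestFilterAdultMinutes:
    def _frame(self, stamps):
        return make_minutes([(s, 5, 70) for s in stamps])

    def test_all_after_unchanged(self, config):
        frame = self._frame(["2021-03-01T08:00", "2021-03-02T08:00"])
        out = filter_adult_minutes(frame, dt.date(1990, 1, 1))
        assert len(out) == 2

    def test_all_before_empty(self, config):
        frame = self._frame(["2021-03-01T08:00"])
        out = filter_adult_minutes(frame, dt.date(2010, 1, 1))
        assert out.empty

    def test_straddling_birthday(self, config):
        frame = self._frame(
            ["2021-03-14T08:00", "2021-03-15T00:00", "2021-03-16T08:00"]
        )
        out = filter_adult_minutes(frame, dt.date(2003, 3, 15))
        # records on/after the 18th birthday kept
        assert list(out["datetime"].dt.date) == [
            dt.date(2021, 3, 15),
            dt.date(2021, 3, 16),
        ]


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age,group",
        [(18, "18-29"), (29, "18-29"), (30, "30-39"), (69, "60-69"), (70, "70+"), (95, "70+")],
    )
    def test_age_group_of(self, age, group):
        assert age_group_of(age) == group

    def _weeks(self, year, first, count):
        return [(year, w) for w in range(first, first + count)]

    def test_majority_group_wins_and_minority_dropped(self, config):
        # born 1991-08-06: turns 30 during 2021
        birth = dt.date(1991, 8, 6)
        weeks = self._weeks(2021, 1, 52) + self._weeks(2022, 1, 30)
        group, kept = assign_age_group(birth, weeks, config)
        # 2021 weeks 1..31 start before the birthday (age 29), rest age 30
        n_29 = sum(
            1
            for (y, w) in weeks
            if (dt.date(y, 1, 1) + dt.timedelta(days=7 * (w - 1))) < birth.replace(year=2021)
        )
        assert n_29 < len(weeks) - n_29
        assert group == "30-39"
        assert len(kept) == len(weeks) - n_29
        assert all(
            dt.date(y, 1, 1) + dt.timedelta(days=7 * (w - 1)) >= birth.replace(year=2021)
            for (y, w) in kept
        )

    def test_single_group_nothing_dropped(self, config):
        birth = dt.date(1980, 1, 1)
        weeks = self._weeks(2021, 1, 40)
        group, kept = assign_age_group(birth, weeks, config)
        assert group == "40-49"
        assert kept == sorted(weeks)

    def test_tie_breaks_to_older_group(self, config):
        # equal valid weeks on each side of a 30th birthday
        birth = dt.date(1991, 7, 2)  # week 27 of 2021 starts 2021-07-02
        weeks = self._weeks(2021, 1, 52)
        by_age = {}
        for (y, w) in weeks:
            start = dt.date(y, 1, 1) + dt.timedelta(days=7 * (w - 1))
            age = 30 if start >= dt.date(2021, 7, 2) else 29
            by_age[age] = by_age.get(age, 0) + 1
        assert by_age[29] == by_age[30] == 26
        group, _ = assign_age_group(birth, weeks, config)
        assert group == "30-39"


class TestClassifyBmi:
    WINDOW = (dt.date(2021, 1, 1), dt.date(2021, 12, 31))

    def test_mean_boundary_overweight(self, config):
        category, mean = classify_bmi(
            [(dt.date(2021, 2, 1), 24.0), (dt.date(2021, 3, 1), 26.0)],
            *self.WINDOW,
            config,
        )
        assert mean == pytest.approx(25.0)
        assert category == "overweight"

    def test_outlier_removed(self, config):
        category, mean = classify_bmi(
            [(dt.date(2021, 2, 1), 200.0), (dt.date(2021, 3, 1), 24.0)],
            *self.WINDOW,
            config,
        )
        assert mean == pytest.approx(24.0)
        assert category == "normal"

    def test_underweight_grouped_other(self, config):
        category, mean = classify_bmi(
            [(dt.date(2021, 2, 1), 17.0)], *self.WINDOW, config
        )
        assert category == "other_or_not_specified"
        assert mean == pytest.approx(17.0)

    def test_out_of_window_ignored(self, config):
        category, mean = classify_bmi(
            [(dt.date(2019, 2, 1), 24.0)], *self.WINDOW, config
        )
        assert category == "other_or_not_specified"
        assert np.isnan(mean)

    @pytest.mark.parametrize(
        "value,category",
        [
            (18.5, "normal"),
            (24.99, "normal"),
            (25.0, "overweight"),
            (29.99, "overweight"),
            (30.0, "obese"),
            (35.0, "severely_obese"),
            (80.0, "severely_obese"),
        ],
    )
    def test_category_edges(self, value, category, config):
        got, _ = classify_bmi([(dt.date(2021, 2, 1), value)], *self.WINDOW, config)
        assert got == category


class TestGroupAdherenceTable:
    def _participants(self, n, adherent, level="female", factor="sex"):
        other = pd.DataFrame(
            {factor: [level] * n, "meets": [True] * adherent + [False] * (n - adherent)}
        )
        return other

    def test_published_female_proportion(self, config):
        frame = self._participants(9553, 1864)
        (row,) = group_adherence_table(frame, "meets", "sex", config)
        assert row.proportion == pytest.approx(0.1951, abs=5e-4)
        assert not row.suppressed

    def test_zero_adherent_truncated_and_suppressed(self, config):
        frame = self._participants(50, 0)
        (row,) = group_adherence_table(frame, "meets", "sex", config)
        assert row.proportion == 0.0
        assert row.wald_ci_low == 0.0
        assert row.suppressed  # adherent cell < 20

    def test_wald_ci_formula(self, config):
        frame = self._participants(60, 30)
        (row,) = group_adherence_table(frame, "meets", "sex", config)
        se = np.sqrt(0.25 / 60)
        assert row.proportion == pytest.approx(0.5)
        assert row.wald_se == pytest.approx(se)
        assert row.wald_ci_low == pytest.approx(0.5 - 1.96 * se)
        assert row.wald_ci_high == pytest.approx(0.5 + 1.96 * se)

    def test_empty_level_suppressed(self, config):
        frame = self._participants(30, 25)
        rows = group_adherence_table(
            frame, "meets", "sex", config, levels=["female", "male"]
        )
        assert rows[1].n_participants == 0
        assert rows[1].suppressed

    def test_suppression_never_alters_totals(self, config):
        frame = pd.concat(
            [
                self._participants(25, 5),
                self._participants(40, 30, level="male"),
            ],
            ignore_index=True,
        )
        rows = group_adherence_table(frame, "meets", "sex", config)
        assert sum(r.n_participants for r in rows) == len(frame)


class TestOddsRatio:
    def test_published_female_example(self):
        result = odds_ratio_from_counts(1864, 9553 - 1864, 1069, 4007 - 1069)
        assert result.odds_ratio == pytest.approx(0.67, abs=5e-3)
        assert result.ci_low == pytest.approx(0.61, abs=5e-3)
        assert result.ci_high == pytest.approx(0.73, abs=5e-3)

    def test_symmetry_gives_one(self):
        result = odds_ratio_from_counts(30, 70, 30, 70)
        assert result.odds_ratio == pytest.approx(1.0)

    def test_published_nh_black_example(self):
        result = odds_ratio_from_counts(87, 684 - 87, 2454, 11109 - 2454)
        assert result.odds_ratio == pytest.approx(0.51, abs=5e-3)

    def test_zero_cell_flagged(self):
        result = odds_ratio_from_counts(0, 10, 5, 5)
        assert not result.defined
        assert np.isnan(result.odds_ratio)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_from_counts(-1, 2, 3, 4)


def counts_to_frame(a, b, c, d):
    """Expand a 2x2 table into per-row outcome/exposure data."""
    rows = (
        [("exposed", True)] * a
        + [("exposed", False)] * b
        + [("ref", True)] * c
        + [("ref", False)] * d
    )
    frame = pd.DataFrame(rows, columns=["group", "outcome"])
    return frame


class TestFitLogistic:
    def test_univariate_matches_closed_form(self, config):
        frame = counts_to_frame(1864, 7689, 1069, 2938)
        fit = fit_logistic(frame, "outcome", ["group"], {"group": "ref"}, config)
        assert fit.converged
        closed = odds_ratio_from_counts(1864, 7689, 1069, 2938)
        got = fit.terms.loc[0, "odds_ratio"]
        assert got == pytest.approx(closed.odds_ratio, rel=1e-6)

    def test_null_simulation_betas_small(self, config):
        model = AdherenceModel(base_log_odds=-1.0)
        data = simulate_outcomes(
            2000, model, {"sex": {"male": 0.5, "female": 0.5}}, seed=7
        )
        fit = fit_logistic(data, "outcome", ["sex"], {"sex": "male"}, config)
        assert fit.converged
        assert abs(fit.terms.loc[0, "beta"]) < 0.5
        assert fit.terms.loc[0, "wald_p"] > 0.001

    def test_collinear_columns_flagged(self, config):
        # two factors that are copies of each other -> infinite VIF
        rng = np.random.default_rng(0)
        level = rng.choice(["a", "b"], size=200)
        frame = pd.DataFrame(
            {
                "f1": level,
                "f2": level,
                "outcome": rng.random(200) < 0.4,
            }
        )
        fit = fit_logistic(
            frame, "outcome", ["f1", "f2"], {"f1": "a", "f2": "a"}, config,
            mode="multivariate",
        )
        assert not fit.vif_ok
        assert any(np.isinf(v) or v >= 5 for v in fit.vif.values())

    def test_reference_must_be_observed(self, config):
        frame = counts_to_frame(5, 5, 5, 5)
        with pytest.raises(ValueError, match="reference"):
            fit_logistic(frame, "outcome", ["group"], {"group": "missing"}, config)

    def test_vif_near_one_for_balanced_single_factor(self, config):
        frame = counts_to_frame(50, 50, 50, 50)
        fit = fit_logistic(frame, "outcome", ["group"], {"group": "ref"}, config)
        assert all(v == pytest.approx(1.0) for v in fit.vif.values())
        assert fit.vif_ok


class TestPairwiseChisq:
    def test_identical_proportions_not_significant(self, config):
        out = pairwise_chisq({"a": (30, 100), "b": (30, 100)}, config)
        assert out.loc[0, "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)
        assert not out.loc[0, "significant"]

    def test_published_sex_difference_significant(self, config):
        out = pairwise_chisq(
            {"male": (1069, 4007), "female": (1864, 9553)}, config
        )
        assert out.loc[0, "p_value"] < 1e-4
        assert out.loc[0, "significant"]

    def test_matches_scipy_directly(self, config):
        counts = {"x": (12, 40), "y": (20, 45)}
        out = pairwise_chisq(counts, config)
        table = np.array([[12, 28], [20, 25]])
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        assert out.loc[0, "statistic"] == pytest.approx(stat)
        assert out.loc[0, "p_value"] == pytest.approx(p)

    def test_zero_margin_skipped(self, config):
        out = pairwise_chisq({"a": (0, 0), "b": (10, 30)}, config)
        assert out.loc[0, "skipped"].item() is True

    def test_all_pairs_enumerated(self, config):
        counts = {lvl: (10 + i, 50) for i, lvl in enumerate("abcd")}
        out = pairwise_chisq(counts, config)
        assert len(out) == 6


class TestMcNemar:
    def test_perfect_agreement(self, config):
        flags = np.array([True, False, True, False])
        res = mcnemar_compare_methods(flags, flags, config)
        assert res["statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_extreme_discordance(self, config):
        a = np.ones(100, dtype=bool)
        b = np.zeros(100, dtype=bool)
        res = mcnemar_compare_methods(a, b, config)
        assert res["statistic"] == pytest.approx(100.0)
        assert res["p_value"] < 1e-20
        assert res["significant"]

    def test_arithmetic_example(self, config):
        # b=12, c=8 -> (12-8)^2/20 = 0.8
        a = np.array([True] * 12 + [False] * 8 + [True] * 30 + [False] * 30)
        b = np.array([False] * 12 + [True] * 8 + [True] * 30 + [False] * 30)
        res = mcnemar_compare_methods(a, b, config)
        assert res["b_only_first"] == 12
        assert res["c_only_second"] == 8
        assert res["statistic"] == pytest.approx(0.8)

    def test_matches_statsmodels(self, config):
        rng = np.random.default_rng(5)
        a = rng.random(500) < 0.4
        b = rng.random(500) < 0.3
        res = mcnemar_compare_methods(a, b, config)
        table = pd.crosstab(a, b).reindex(
            index=[True, False], columns=[True, False]
        ).to_numpy()
        # statsmodels orders cells [ [tt, tf], [ft, ff] ]
        reference = sm_mcnemar(table, exact=False, correction=False)
        assert res["statistic"] == pytest.approx(float(reference.statistic))
        assert res["p_value"] == pytest.approx(float(reference.pvalue))

    def test_length_mismatch_rejected(self, config):
        with pytest.raises(ValueError):
            mcnemar_compare_methods([True], [True, False], config)


class TestPublishedCounts:
    def test_counts_internally_consistent(self):
        for factor, spec in PUBLISHED_GROUP_COUNTS.items():
            assert spec["reference"] in spec["levels"]
            for level, (adherent, total) in spec["levels"].items():
                assert 0 <= adherent <= total
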