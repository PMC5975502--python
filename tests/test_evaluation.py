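"""Estimators: chart review, PPV, confirmed counts, prevalence, contrasts."""

import numpy as np
import pandas as pd
import pytest

from periscreen.evaluation import (compare_groups, estimate_confirmed,
                                   estimate_ppv, estimate_prevalence,
                                   flag_comorbidities, proportion_pct,
                                   round_half_up, simulate_chart_review)
from periscreen.lexicons import CodeLexicon

from conftest import make_fact


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (148.96, 0, 149.0), (145.8, 0, 146.0), (0.5, 0, 1.0),
        (2.755, 2, 2.76), (2.764999, 2, 2.76), (21.2041, 1, 21.2),
    ])
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected

    def test_proportion_pct(self):
        assert proportion_pct(486, 682) == 71.26
        with pytest.raises(ValueError):
            proportion_pct(1, 0)


class TestSimulateChartReview:
    def test_all_true_group_fully_confirmed(self):
        truth = pd.Series(True, index=[f"P{i}" for i in range(100)])
        rs = simulate_chart_review(truth.index, truth, 40, seed=1)
        assert rs.sample_size == 40 and rs.n_confirmed == 40

    def test_seed_determinism(self):
        truth = pd.Series([True, False] * 50,
                          index=[f"P{i}" for i in range(100)])
        a = simulate_chart_review(truth.index, truth, 30, seed=9)
        b = simulate_chart_review(truth.index, truth, 30, seed=9)
        assert a.labels.index.tolist() == b.labels.index.tolist()

    def test_small_group_reviewed_whole_with_warning(self):
        truth = pd.Series(True, index=["P0", "P1"])
        rs = simulate_chart_review(truth.index, truth, 10, seed=0)
        assert rs.sample_size == 2 and rs.warnings

    def test_empty_group_warns(self):
        rs = simulate_chart_review([], pd.Series(dtype=bool), 10, seed=0)
        assert rs.sample_size == 0 and rs.warnings
        with pytest.raises(ValueError):
            estimate_ppv(rs)

    def test_binomial_recovery_of_planted_rate(self):
        """Mean confirmed fraction over replicates tracks the planted 0.3."""
        rng = np.random.default_rng(12)
        ids = [f"P{i}" for i in range(1000)]
        truth = pd.Series(rng.random(1000) < 0.3, index=ids)
        planted = truth.mean()
        fracs = [simulate_chart_review(ids, truth, 100, seed=s).n_confirmed / 100
                 for s in range(200)]
        se = np.sqrt(planted * (1 - planted) / 100) / np.sqrt(200)
        assert abs(np.mean(fracs) - planted) <= 3 * se


class TestPPVEstimators:
    def test_reviewed_38_of_50(self):
        rs = simulate_chart_review(
            [f"P{i}" for i in range(50)],
            pd.Series([True] * 38 + [False] * 12,
                      index=[f"P{i}" for i in range(50)]), 50, seed=0)
        p, (lo, hi) = estimate_ppv(rs)
        assert p == 0.76 and lo < 0.76 < hi

    def test_reviewed_30_of_100(self):
        ids = [f"P{i}" for i in range(100)]
        rs = simulate_chart_review(
            ids, pd.Series([True] * 30 + [False] * 70, index=ids), 100, seed=0)
        p, _ = estimate_ppv(rs)
        assert p == 0.30

    def test_zero_confirmed_ci_floor(self):
        ids = [f"P{i}" for i in range(100)]
        rs = simulate_chart_review(ids, pd.Series(False, index=ids), 100,
                                   seed=0)
        p, (lo, hi) = estimate_ppv(rs)
        assert p == 0.0 and lo == 0.0 and hi > 0.0

    @pytest.mark.parametrize("n,ppv,expected", [
        (196, 0.76, 149),     # 148.96 rounds up
        (486, 0.30, 146),     # 145.8 rounds up
        (1000, 0.0, 0),
        (10, 0.05, 1),        # 0.5 rounds half-up
    ])
    def test_estimate_confirmed(self, n, ppv, expected):
        assert estimate_confirmed(n, ppv) == expected

    def test_estimate_confirmed_exact_when_whole_group_reviewed(self):
        ids = [f"P{i}" for i in range(60)]
        truth = pd.Series([i % 3 == 0 for i in range(60)], index=ids)
        rs = simulate_chart_review(ids, truth, 60, seed=0)
        p, _ = estimate_ppv(rs)
        assert estimate_confirmed(60, p) == int(truth.sum())

    @pytest.mark.parametrize("n,ppv,denom,expected", [
        (486, 0.3, 5282, 2.76),
        (0, 0.5, 100, 0.00),
        (100, 0.5, 1000, 5.00),
    ])
    def test_estimate_prevalence(self, n, ppv, denom, expected):
        assert estimate_prevalence(n, ppv, denom) == expected

    def test_estimator_input_validation(self):
        with pytest.raises(ValueError):
            estimate_confirmed(10, 1.5)
        with pytest.raises(ValueError):
            estimate_prevalence(10, 0.5, 0)


class TestCompareGroups:
    def test_chi_square_equals_hand_formula_2x2(self):
        a = pd.DataFrame({"x": ["u"] * 30 + ["v"] * 10})
        b = pd.DataFrame({"x": ["u"] * 20 + ["v"] * 25})
        out = compare_groups(a, b, {"x": "categorical"})
        obs = np.array([[30, 10], [20, 25]])
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        exp = row * col / obs.sum()
        hand = ((obs - exp) ** 2 / exp).sum()
        assert abs(out.loc[0, "statistic"] - hand) < 1e-9

    def test_insurance_table_reproduces_p_003(self):
        """Printed insurance counts for the two screen-positive groups."""
        cats = ["Medicaid", "Medicare", "Private", "Self-pay", "Other"]
        a = pd.DataFrame({"insurance": np.repeat(cats, [97, 18, 63, 8, 10])})
        b = pd.DataFrame({"insurance": np.repeat(cats, [210, 30, 217, 11, 18])})
        out = compare_groups(a, b, {"insurance": "categorical"})
        assert out.loc[0, "p_value_2dp"] == 0.03

    def test_identical_distributions_p_one(self):
        a = pd.DataFrame({"x": ["u"] * 10 + ["v"] * 10})
        out = compare_groups(a, a.copy(), {"x": "categorical"})
        assert out.loc[0, "p_value_2dp"] == 1.00

    def test_continuous_t_test(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"age": rng.normal(26.8, 6.9, 196)})
        b = pd.DataFrame({"age": rng.normal(26.4, 6.2, 486)})
        out = compare_groups(a, b, {"age": "continuous"})
        from scipy import stats
        t, p = stats.ttest_ind(a["age"], b["age"], equal_var=True)
        assert out.loc[0, "p_value"] == pytest.approx(p)

    def test_degenerate_table_skipped_with_note(self):
        a = pd.DataFrame({"x": ["u"] * 5})
        out = compare_groups(a, a.copy(), {"x": "categorical"})
        assert out.loc[0, "note"].startswith("skipped")


class TestFlagComorbidities:
    LEX = {"depression": CodeLexicon.from_entries(
        "depression", [("ICD9", "311"), ("ICD10", "F32.*")])}

    def _flags(self, fact_date, index_date):
        facts = pd.DataFrame([make_fact("A", fact_date, "ICD9", "311")])
        idx = pd.Series([pd.Timestamp(index_date)] if index_date else [pd.NaT],
                        index=pd.Index(["A"], name="patient_id"))
        return flag_comorbidities(facts, self.LEX, idx, ["A"])

    def test_code_after_index_not_flagged(self):
        out = self._flags("2010-06-02", "2010-06-01")
        assert not out.loc[0, "depression"]

    def test_code_on_index_date_flagged(self):
        out = self._flags("2010-06-01", "2010-06-01")
        assert out.loc[0, "depression"]

    def test_no_index_date_uses_full_history(self):
        out = self._flags("2019-01-01", None)
        assert out.loc[0, "depression"] and out.loc[0, "full_history"]

    def test_empty_lexicon_all_false(self):
        facts = pd.DataFrame([make_fact("A", "2010-01-01", "ICD9", "311")])
        idx = pd.Series([pd.Timestamp("2011-01-01")],
                        index=pd.Index(["A"], name="patient_id"))
        lex = {"depression": CodeLexicon.from_entries("depression", [])}
        out = flag_comorbidities(facts, lex, idx, ["A"])
        assert not out.loc[0, "depression"]
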