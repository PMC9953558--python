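"""Tie-aware ROC/AUC, panel combination and nonparametric statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ddscreen.diagnostics import (
    combine_panel,
    evaluate_cohort,
    fisher_exact,
    linearity_r2,
    mann_whitney,
    paired_wilcoxon,
    roc_auc,
    sensitivity_specificity,
    spearman,
)


def _brute_force_auc(cases, controls):
    wins = ties = 0
    for c in cases:
        for k in controls:
            wins += c > k
            ties += c == k
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1.0], [0.0]) == 1.0

    def test_small_tied_example(self):
        assert roc_auc([1, 0, 0], [0, 0]) == pytest.approx(4 / 6)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=50),
        st.lists(st.integers(0, 5), min_size=1, max_size=50),
    )
    def test_matches_brute_force_pair_count(self, cases, controls):
        assert roc_auc(cases, controls) == pytest.approx(
            _brute_force_auc(cases, controls)
        )

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 50, allow_nan=False), min_size=2, max_size=30),
        st.lists(st.floats(0, 50, allow_nan=False), min_size=2, max_size=30),
    )
    def test_equals_mann_whitney_u_normalised(self, x, y):
        u = mann_whitney(x, y).statistic
        assert roc_auc(x, y) == pytest.approx(u / (len(x) * len(y)))

    @pytest.mark.parametrize("sens", [0.2, 25 / 70, 40 / 70, 47 / 70, 1.0])
    def test_zero_controls_identity(self, sens):
        """With all negatives at 0, AUC = (1 + sensitivity) / 2 exactly."""
        n = 70
        k = round(sens * n)
        cases = np.r_[np.full(k, 7.7), np.zeros(n - k)]
        auc = roc_auc(cases, np.zeros(72))
        assert auc == pytest.approx((1 + k / n) / 2)

    def test_score_magnitudes_irrelevant_under_full_specificity(self, rng):
        positives = rng.uniform(0.1, 90, size=25)
        cases = np.r_[positives, np.zeros(45)]
        assert roc_auc(cases, np.zeros(72)) == pytest.approx(
            roc_auc(np.r_[np.ones(25), np.zeros(45)], np.zeros(72))
        )

    def test_roc_points_returned(self):
        auc, points = roc_auc([3, 2, 0], [0, 1], return_points=True)
        assert {"fpr", "tpr", "threshold"} <= set(points.columns)
        assert points["tpr"].iloc[-1] == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


class TestSensitivitySpecificity:
    def test_published_count_scenario(self):
        calls = np.r_[np.ones(25), np.zeros(45), np.zeros(72)].astype(bool)
        is_case = np.r_[np.ones(70), np.zeros(72)].astype(bool)
        sens, spec = sensitivity_specificity(calls, is_case)
        assert sens == pytest.approx(100 * 25 / 70)
        assert spec == 100.0

    def test_all_correct(self):
        sens, spec = sensitivity_specificity([True, False], [True, False])
        assert (sens, spec) == (100.0, 100.0)

    def test_no_positive_calls(self):
        sens, spec = sensitivity_specificity([False, False], [True, False])
        assert (sens, spec) == (0.0, 100.0)

    def test_missing_stratum_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_specificity([True], [True])


class TestCombinePanel:
    @staticmethod
    def _calls(n, positive_ids):
        return {f"s{i}": i in positive_ids for i in range(n)}

    def test_union_with_overlap(self):
        """Marginals 25 and 40 with overlap 18 give a union of 47 in 70."""
        a = set(range(25))
        b = set(range(7, 47))  # overlaps a in 7..24 (18 samples)
        assert len(a & b) == 18
        out = combine_panel({"A": self._calls(70, a), "B": self._calls(70, b)})
        assert out["n_union"] == 47
        assert out["n_intersection"] == 18
        assert out["n_union"] / out["n_samples"] == pytest.approx(0.671, abs=0.001)

    def test_disjoint_positives_add(self):
        out = combine_panel(
            {"A": self._calls(10, {0, 1}), "B": self._calls(10, {5, 6, 7})}
        )
        assert out["n_union"] == 5 and out["n_intersection"] == 0

    def test_all_negative(self):
        out = combine_panel({"A": self._calls(4, set()), "B": self._calls(4, set())})
        assert out["n_union"] == 0

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValueError):
            combine_panel({"A": {"s1": True}, "B": {"s2": True}})


class TestPairedWilcoxon:
    def test_identical_pairs_flagged_degenerate(self):
        res = paired_wilcoxon([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate

    def test_dominating_shift_exact_p(self):
        """All-positive distinct differences at n=10: the signed-rank sum is
        extreme and exact enumeration gives two-sided p = 2/2^10."""
        x = np.arange(10, dtype=float)
        res = paired_wilcoxon(x + np.linspace(1, 2, 10), x)
        assert res.p_value == pytest.approx(2 / 1024)

    def test_swap_symmetry(self):
        x = [1.0, 4.0, 2.5, 7.0, 3.0, 9.0]
        y = [2.0, 1.0, 4.0, 6.0, 8.0, 5.0]
        a, b = paired_wilcoxon(x, y), paired_wilcoxon(y, x)
        assert a.p_value == pytest.approx(b.p_value)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1.0], [1.0, 2.0])


class TestMannWhitney:
    def test_identical_singletons_tie_convention(self):
        res = mann_whitney([1.0], [1.0])
        assert res.statistic == 0.5
        assert res.p_value == 1.0

    def test_separated_triples_exact(self):
        """All 20 orderings equally likely: two-sided p = 2/20 = 0.1."""
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman(x, [2.0, 4.0, 9.0, 11.0]).statistic == pytest.approx(1.0)
        assert spearman(x, [5.0, 4.0, 2.0, 1.0]).statistic == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        oracle = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert spearman(x, y).statistic == pytest.approx(oracle)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFisherExact:
    def test_diagonal_table(self):
        res = fisher_exact([[5, 0], [0, 5]])
        assert res.p_value == pytest.approx(2 / 252)

    def test_identical_rows(self):
        assert fisher_exact([[4, 6], [4, 6]]).p_value == pytest.approx(1.0)

    def test_row_swap_invariance(self):
        a = fisher_exact([[8, 2], [3, 9]])
        b = fisher_exact([[3, 9], [8, 2]])
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [1, 2]])


class TestLinearityR2:
    def test_identity_and_affine_are_perfect(self):
        x = [0.5, 1.0, 5.0, 20.0, 50.0]
        assert linearity_r2(x, x) == pytest.approx(1.0)
        assert linearity_r2(x, [2 * v + 3 for v in x]) == pytest.approx(1.0)

    def test_three_point_closed_form(self):
        """R^2 equals squared Pearson correlation for simple OLS."""
        x = [1.0, 2.0, 3.0]
        y = [1.0, 3.0, 4.0]
        r = sps.pearsonr(x, y).statistic
        assert linearity_r2(x, y) == pytest.approx(r**2)

    def test_constant_expected_rejected(self):
        with pytest.raises(ValueError):
            linearity_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def _cohort_frame(gpr_pos, tert_pos, n_cases=70, n_controls=72):
    """Calibrated-results frame from detection-count scenario."""
    rows = []
    rng = np.random.default_rng(0)
    for i in range(n_cases):
        sid = f"UBC_{i:03d}"
        for marker, positive_ids in (("GPR126", gpr_pos), ("TERT", tert_pos)):
            positive = i in positive_ids
            maf = float(rng.uniform(1, 60)) if positive else 0.0
            rows.append(
                {"sample_id": sid, "group": "UBC", "assay": marker,
                 "corrected_maf": maf, "call": positive}
            )
    for i in range(n_controls):
        group = "control" if i < 50 else "cystitis"
        sid = f"{group}_{i:03d}"
        for marker in ("GPR126", "TERT"):
            rows.append(
                {"sample_id": sid, "group": group, "assay": marker,
                 "corrected_maf": 0.0, "call": False}
            )
    return pd.DataFrame(rows)


class TestEvaluateCohort:
    def test_published_count_scenario_reproduces_auc_triple(self):
        """25/70 and 40/70 positives with overlap 18 give the AUC triple."""
        gpr = set(range(25))
        tert = set(range(7, 47))
        report = evaluate_cohort(_cohort_frame(gpr, tert))
        assert report.markers["GPR126"].auc == pytest.approx(0.679, abs=0.001)
        assert report.markers["TERT"].auc == pytest.approx(0.786, abs=0.001)
        assert report.combined.auc == pytest.approx(0.836, abs=0.001)
        assert report.combined.n_detected == 47
        assert report.overlap["both"] == 18
        assert report.markers["GPR126"].specificity == 100.0

    def test_no_positive_cases_gives_chance_auc(self):
        report = evaluate_cohort(_cohort_frame(set(), set()))
        assert report.markers["GPR126"].auc == pytest.approx(0.5)
        assert report.combined.auc == pytest.approx(0.5)

    def test_paired_comparison_on_dual_positives(self):
        gpr = set(range(25))
        tert = set(range(7, 47))
        report = evaluate_cohort(_cohort_frame(gpr, tert))
        assert report.paired_comparison is not None
        assert report.paired_comparison.n["pairs"] == 18

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            evaluate_cohort(pd.DataFrame({"sample_id": [], "group": []}))
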