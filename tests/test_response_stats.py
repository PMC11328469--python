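"""Response classification, concordance, correlations, group tests, AUC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from cylmre import (
    ConcordanceTable,
    auc_cutpoint,
    classify_histo_response,
    classify_recist,
    cohort_proportions,
    compare_groups,
    concordance,
)
from cylmre.errors import InvalidGradeError, InvalidInputError
from cylmre.response_stats import round_half_up, spearman


class TestHistoResponse:
    @pytest.mark.parametrize("grade,expected", [
        (1, "major"), (2, "major"), (3, "partial"), (4, "none"), (5, "none"),
    ])
    def test_grade_mapping(self, grade, expected):
        assert classify_histo_response(grade) == expected

    @pytest.mark.parametrize("grade", [0, 6, -1, 2.5])
    def test_invalid_grade(self, grade):
        with pytest.raises(InvalidGradeError):
            classify_histo_response(grade)

    def test_mapping_surjective(self):
        assert {classify_histo_response(g) for g in range(1, 6)} == \
            {"major", "partial", "none"}


class TestRecist:
    @pytest.mark.parametrize("base,follow,expected", [
        (50.0, 35.0, "rPR"),    # exactly -30%: inclusive
        (50.0, 60.0, "rPD"),    # exactly +20%: inclusive
        (50.0, 45.0, "rSD"),
        (50.0, 34.0, "rPR"),
        (50.0, 61.0, "rPD"),
        (50.0, 50.0, "rSD"),
    ])
    def test_thresholds(self, base, follow, expected):
        assert classify_recist(base, follow) == expected

    def test_invalid_diameters(self):
        with pytest.raises(InvalidInputError):
            classify_recist(0.0, 10.0)
        with pytest.raises(InvalidInputError):
            classify_recist(10.0, -1.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(base=st.floats(1.0, 200.0), follow=st.floats(1.0, 200.0))
    def test_always_one_of_three_classes(self, base, follow):
        assert classify_recist(base, follow) in ("rPR", "rSD", "rPD")


class TestConcordance:
    def test_study_contingency(self):
        """The study's 2x2 table (16/1/6/4 of 27) gives 74% concordant,
        25.9% discordant, 14.8% both-present, 22.2% radiological-only."""
        t = ConcordanceTable(both_absent=16, patho_only=1, radio_only=6,
                             both_present=4)
        assert t.n == 27
        assert t.concordant == 20
        assert round(t.concordant / t.n * 100) == 74
        pct = t.percentages()
        assert pct["discordant"] == 25.9
        assert pct["both_present"] == 14.8
        assert pct["radio_only"] == 22.2
        assert pct["both_absent"] == 59.3

    def test_from_records(self):
        histo = ["major", "major", "none", "partial", "major"]
        recist = ["rPR", "rSD", "rSD", "rPR", "missing"]
        t = concordance(histo, recist)
        assert t.n == 4
        assert t.both_present == 1
        assert t.patho_only == 1
        assert t.radio_only == 1
        assert t.both_absent == 1

    def test_all_concordant(self):
        t = concordance(["major", "none"], ["rPR", "rSD"])
        pct = t.percentages()
        assert pct["concordant"] == 100.0
        assert pct["discordant"] == 0.0

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        histo = rng.choice(["major", "partial", "none"], 50).tolist()
        rec = rng.choice(["rPR", "rSD", "rPD"], 50).tolist()
        t = concordance(histo, rec)
        assert t.both_absent + t.patho_only + t.radio_only + t.both_present == 50
        pct = t.percentages()
        assert pct["concordant"] + pct["discordant"] == pytest.approx(100.0, abs=0.2)

    def test_empty_raises(self):
        with pytest.raises(InvalidInputError):
            concordance(["major"], ["missing"])


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman([5, 4, 3, 2, 1], [1, 2, 3, 4, 5])
        assert res.coefficient == pytest.approx(-1.0)

    def test_hand_computed_six_rows(self):
        """rho = 1 - 6 sum d^2 / (n(n^2-1)) on a worked 6-row table with
        distinct ranks."""
        x = [3.1, 1.2, 5.6, 2.2, 4.4, 6.0]   # ranks 3 1 5 2 4 6
        y = [2.0, 1.0, 4.0, 6.0, 3.0, 5.0]   # ranks 2 1 4 6 3 5
        d2 = sum((rx - ry) ** 2 for rx, ry in zip([3, 1, 5, 2, 4, 6],
                                                  [2, 1, 4, 6, 3, 5]))
        expected = 1 - 6 * d2 / (6 * 35)
        res = spearman(x, y)
        assert res.coefficient == pytest.approx(expected, rel=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = spearman(x, y).coefficient
        r2 = spearman(np.exp(x), y).coefficient
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_constant_input_flagged(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert not res.defined
        assert math.isnan(res.coefficient)

    def test_permutation_null_centred(self):
        """Permuted labels: mean correlation within +/-0.05 of zero over 50
        replicates at n = 200."""
        rng = np.random.default_rng(2)
        vals = rng.normal(size=200)
        coefs = []
        for _ in range(50):
            labs = rng.permutation(np.repeat([1, 2, 3, 4, 5], 40))
            coefs.append(spearman(vals, labs).coefficient)
        assert abs(np.mean(coefs)) < 0.05


class TestCompareGroups:
    def test_identical_groups(self):
        g = {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        res = compare_groups(g)
        assert res.kruskal_p == pytest.approx(1.0, abs=0.05)
        assert res.groups["a"].median == res.groups["b"].median

    def test_shifted_groups_detected(self, rng):
        """Medians 0.43 vs 0.51, sd 0.06, n = 300: the shift is detected
        (p < 0.001) and the medians are recovered within +/-0.01."""
        g = {"major": rng.normal(0.43, 0.06, 300),
             "none": rng.normal(0.51, 0.06, 300)}
        res = compare_groups(g)
        assert res.kruskal_p < 1e-3
        assert res.groups["major"].median == pytest.approx(0.43, abs=0.01)
        assert res.groups["none"].median == pytest.approx(0.51, abs=0.01)

    def test_quartiles_type7(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups({"a": vals, "b": vals})
        assert res.groups["a"].q1 == pytest.approx(np.quantile(vals, 0.25))
        assert res.groups["a"].q3 == pytest.approx(np.quantile(vals, 0.75))

    def test_singleton_groups_degenerate(self):
        res = compare_groups({"a": [1.0], "b": [2.0], "c": [3.0]})
        assert res.degenerate
        assert res.kruskal_p is None

    def test_empty_group_dropped(self):
        res = compare_groups({"a": [1.0, 2.0, 3.0], "b": [], "c": [2.0, 3.0, 4.0]})
        assert set(res.groups) == {"a", "c"}

    def test_fewer_than_two_groups_raises(self):
        with pytest.raises(InvalidInputError):
            compare_groups({"a": [1.0, 2.0]})

    def test_fdr_adjustment_monotone(self, rng):
        g = {k: rng.normal(loc, 1.0, 40) for k, loc in
             [("a", 0.0), ("b", 0.2), ("c", 1.5)]}
        raw = compare_groups(g, fdr=False).pairwise
        adj = compare_groups(g, fdr=True).pairwise
        for key in raw:
            assert adj[key] >= raw[key] - 1e-12


def auc_by_pair_counting(values, labels):
    """Exhaustive concordant-pair count with half-credit ties."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        res = auc_cutpoint([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_eight_point_toy_set_matches_pair_counting(self):
        values = [1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 5.0, 5.0]
        labels = [False, False, True, False, True, True, False, True]
        res = auc_cutpoint(values, labels)
        assert res.auc == pytest.approx(auc_by_pair_counting(values, labels))

    def test_oracle_equivalence_100_random_instances(self):
        """Rank-statistic AUC equals exhaustive pair counting, ties included."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(4, 31))
            values = rng.integers(0, 8, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            res = auc_cutpoint(values, labels)
            brute = auc_by_pair_counting(values, labels)
            oriented = max(brute, 1.0 - brute)
            assert res.auc == pytest.approx(oriented, rel=1e-12)

    def test_null_simulation_centred_at_half(self):
        rng = np.random.default_rng(13)
        aucs = []
        for _ in range(50):
            values = rng.normal(size=500)
            labels = rng.integers(0, 2, 500).astype(bool)
            aucs.append(auc_cutpoint(values, labels).auc)
        # oriented AUC is >= 0.5 by construction; folded null mean is close
        folded = [a if rng.uniform() < 0.5 else 1.0 - a for a in aucs]
        assert abs(np.mean(folded) - 0.5) < 0.03

    def test_youden_cutpoint_on_known_mixture(self):
        rng = np.random.default_rng(17)
        neg = rng.normal(0.0, 1.0, 400)
        pos = rng.normal(2.0, 1.0, 400)
        values = np.concatenate([neg, pos])
        labels = np.array([False] * 400 + [True] * 400)
        res = auc_cutpoint(values, labels)
        assert res.direction == ">="
        assert res.cutpoint == pytest.approx(1.0, abs=0.35)
        assert res.sensitivity + res.specificity - 1.0 > 0.5

    def test_single_class_raises(self):
        with pytest.raises(InvalidInputError):
            auc_cutpoint([1.0, 2.0], [True, True])


class TestProportions:
    def test_study_grade_counts(self):
        """Grades (3,2,6,15,8) -> 5 major (14.7%), 6 partial (17.6%),
        23 none (67.6%)."""
        grades = [1] * 3 + [2] * 2 + [3] * 6 + [4] * 15 + [5] * 8
        props = cohort_proportions([classify_histo_response(g) for g in grades])
        assert props["major"] == (5, 14.7)
        assert props["partial"] == (6, 17.6)
        assert props["none"] == (23, 67.6)

    def test_single_record(self):
        assert cohort_proportions(["partial"])["partial"] == (1, 100.0)

    def test_empty_raises(self):
        with pytest.raises(InvalidInputError):
            cohort_proportions([])


class TestRounding:
    def test_half_up(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(14.705, 1) == 14.7
        assert round_half_up(67.647, 1) == 67.6
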