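import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from sepscore.roc_analysis import (
    auc_ci,
    auc_mann_whitney,
    compare_scores,
    delong_variance,
    roc_points,
    split_by_outcome,
    trapezoidal_auc,
)

from conftest import random_resolved
from table_oracle import auc_pair_count

scores_list = st.lists(st.integers(0, 27), min_size=1, max_size=60)


class TestAucMannWhitney:
    def test_small_example_matches_pair_enumeration(self):
        assert auc_mann_whitney([3, 4], [1, 2, 3]) == pytest.approx(5.5 / 6)

    def test_identical_multisets_give_half(self):
        assert auc_mann_whitney([1, 2, 3], [3, 2, 1]) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        assert auc_mann_whitney([4, 5], [1, 2, 3]) == 1.0

    @given(pos=scores_list, neg=scores_list)
    def test_matches_exhaustive_pair_count(self, pos, neg):
        assert auc_mann_whitney(pos, neg) == pytest.approx(
            auc_pair_count(pos, neg), abs=1e-12)

    @given(pos=scores_list, neg=scores_list)
    def test_label_flip_antisymmetry(self, pos, neg):
        assert auc_mann_whitney(pos, neg) + auc_mann_whitney(neg, pos) \
            == pytest.approx(1.0, abs=1e-12)

    @given(pos=scores_list, neg=scores_list, shift=st.integers(-50, 50))
    def test_translation_invariance(self, pos, neg, shift):
        shifted = auc_mann_whitney([p + shift for p in pos],
                                   [n + shift for n in neg])
        assert shifted == pytest.approx(auc_mann_whitney(pos, neg), abs=1e-12)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(3)
        pos = rng.integers(0, 28, 80)
        neg = rng.integers(0, 20, 120)
        y = np.r_[np.ones(80), np.zeros(120)]
        assert auc_mann_whitney(pos, neg) == pytest.approx(
            roc_auc_score(y, np.r_[pos, neg]), abs=1e-12)

    def test_empty_class_error_names_class(self):
        with pytest.raises(ValueError, match="positive"):
            auc_mann_whitney([], [1])
        with pytest.raises(ValueError, match="negative"):
            auc_mann_whitney([1], [])


class TestRocPoints:
    def test_trapezoid_equals_pair_count_small(self):
        pts = roc_points([3, 4], [1, 2, 3])
        assert trapezoidal_auc(pts) == pytest.approx(5.5 / 6, abs=1e-12)

    def test_binary_score_three_points(self):
        pts = roc_points([1, 1, 0], [0, 0, 1])
        assert len(pts) == 3

    def test_constant_scores_area_half(self):
        pts = roc_points([2, 2], [2, 2, 2])
        assert trapezoidal_auc(pts) == pytest.approx(0.5, abs=1e-12)

    def test_endpoints_span_roc_space(self):
        pts = roc_points([3, 4], [1, 2])
        _, sens, spec = pts[0]
        assert (sens, spec) == (0.0, 1.0)
        _, sens, spec = pts[-1]
        assert (sens, spec) == (1.0, 0.0)

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        pts = roc_points(rng.integers(0, 10, 40), rng.integers(0, 10, 60))
        sens = [s for _, s, _ in pts]  # thresholds descending
        assert sens == sorted(sens)

    def test_trapezoid_equals_pair_count_random(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_pos = int(rng.integers(1, 100))
            n_neg = int(rng.integers(1, 100))
            pos = rng.integers(0, 28, n_pos)
            neg = rng.integers(0, 28, n_neg)
            assert trapezoidal_auc(roc_points(pos, neg)) == pytest.approx(
                auc_mann_whitney(pos, neg), abs=1e-12)


# fixture frozen against R pROC (DeLong method) as an independent oracle
_PROC_POS = [3, 4, 4, 5, 2, 6, 3, 4]
_PROC_NEG = [1, 2, 2, 3, 1, 0, 2, 3, 4, 1, 2]
_PROC_AUC = 0.880681818182
_PROC_VAR = 0.005678128689
_PROC_CI_LOW = 0.732991948728


class TestAucCi:
    def test_delong_matches_proc_reference(self):
        assert auc_mann_whitney(_PROC_POS, _PROC_NEG) == pytest.approx(
            _PROC_AUC, abs=1e-10)
        assert delong_variance(_PROC_POS, _PROC_NEG) == pytest.approx(
            _PROC_VAR, abs=1e-10)
        res = auc_ci(_PROC_POS, _PROC_NEG, method="delong")
        assert res.ci_low == pytest.approx(_PROC_CI_LOW, abs=1e-9)
        assert res.ci_high == 1.0  # truncated

    def test_perfect_separation_truncates_at_one(self):
        res = auc_ci([4, 5, 6], [1, 2, 3], method="delong")
        assert res.auc == 1.0
        assert res.ci_high == 1.0

    def test_delong_requires_two_per_class(self):
        with pytest.raises(ValueError, match=">= 2"):
            auc_ci([3], [1, 2], method="delong")

    def test_bootstrap_reproducible_and_covers_point(self):
        a = auc_ci([3, 4], [1, 2, 3], method="bootstrap", seed=5)
        b = auc_ci([3, 4], [1, 2, 3], method="bootstrap", seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= 5.5 / 6 <= a.ci_high
        # on a sample large enough for rich resampling variation, a
        # different seed yields a different percentile interval
        rng = np.random.default_rng(1)
        pos, neg = rng.integers(5, 25, 60), rng.integers(0, 20, 90)
        c = auc_ci(pos, neg, method="bootstrap", seed=6)
        d = auc_ci(pos, neg, method="bootstrap", seed=7)
        assert (c.ci_low, c.ci_high) != (d.ci_low, d.ci_high)

    def test_bootstrap_requires_seed_and_enough_reps(self):
        with pytest.raises(ValueError, match="seed"):
            auc_ci([3, 4], [1, 2], method="bootstrap")
        with pytest.raises(ValueError, match="n_boot"):
            auc_ci([3, 4], [1, 2], method="bootstrap", seed=1, n_boot=10)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            auc_ci([3, 4], [1, 2], method="jackknife")


class TestCompareScores:
    @pytest.fixture
    def cohort(self):
        rng = np.random.default_rng(21)
        return [random_resolved(rng) for _ in range(120)]

    def test_one_result_per_score_ranked(self, cohort):
        results = compare_scores(cohort, ["MEDS", "mREMS", "CURB65"])
        assert [r.score_name for r in results] != []
        aucs = [r.auc for r in results]
        assert aucs == sorted(aucs, reverse=True)
        assert len({r.score_name for r in results}) == 3
        assert all(r.n_pos + r.n_neg == 120 for r in results)

    def test_unknown_score_error(self, cohort):
        with pytest.raises(KeyError, match="APACHE"):
            compare_scores(cohort, ["APACHE"])

    def test_missing_outcome_error(self, cohort):
        cohort[0].survived_to_discharge = None
        with pytest.raises(ValueError, match="outcome"):
            compare_scores(cohort, ["MEDS"])

    def test_outcome_independent_scores_near_half(self, cohort):
        # random records: outcomes independent of all fields by construction
        results = compare_scores(cohort, ["MEDS", "mREMS", "CURB65"])
        for r in results:
            assert abs(r.auc - 0.5) < 0.2

    def test_deaths_are_positive_class(self, cohort):
        pos, neg = split_by_outcome(cohort, "MEDS")
        n_deaths = sum(not r.survived_to_discharge for r in cohort)
        assert len(pos) == n_deaths
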