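import numpy as np
import pytest
from scipy import stats

from covpattern import PhantomSpec, make_phantom_cohort
from covpattern.validation import (
    ttest_scores, roc_auc, pearson_r, loocv_disease, loocv_cognition,
)
from covpattern.cognition import zscore_tests, composite_scores


def mann_whitney_auc_oracle(scores, labels):
    """Exhaustive pairwise count, ties 1/2 — independent of the ROC path."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestTTest:
    def test_identical_groups(self):
        t, p = ttest_scores(np.array([1.0, 2, 3, 1, 2, 3]),
                            np.array([0, 0, 0, 1, 1, 1]))
        assert t == pytest.approx(0, abs=1e-12)
        assert p == pytest.approx(1, abs=1e-12)

    def test_hand_computed_toy(self):
        """{1,2,3} vs {4,5,6}: pooled SD 1, t = -3.6742 (disease minus
        control with disease = {1,2,3})."""
        scores = np.array([4.0, 5, 6, 1, 2, 3])
        labels = np.array([0, 0, 0, 1, 1, 1])
        t, p = ttest_scores(scores, labels)
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-10)
        assert t == pytest.approx(-3.6742, abs=1e-4)

    def test_scale_invariance(self, rng):
        s = rng.normal(size=12)
        l = np.repeat([0, 1], 6)
        t1, _ = ttest_scores(s, l)
        t2, _ = ttest_scores(5.0 * s, l)
        assert t1 == pytest.approx(t2, abs=1e-10)

    def test_matches_scipy_pooled(self, rng):
        s = rng.normal(size=15)
        l = np.array([0] * 7 + [1] * 8)
        t, p = ttest_scores(s, l)
        ref = stats.ttest_ind(s[l == 1], s[l == 0], equal_var=True)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="pooled variance"):
            ttest_scores(np.ones(6), np.repeat([0, 1], 3))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc, sens, spec, _ = roc_auc(
            np.array([1.0, 2, 10, 11, 12]), np.array([0, 0, 1, 1, 1]))
        assert (auc, sens, spec) == (1.0, 1.0, 1.0)

    def test_all_ties(self):
        _, auc, *_ = roc_auc(np.ones(8), np.repeat([0, 1], 4))
        assert auc == 0.5

    def test_counting_example(self):
        """HC {1, 2}, PD {1.5, 3}: 3 of 4 pairs concordant -> AUC 3/4."""
        _, auc, *_ = roc_auc(np.array([1.0, 2.0, 1.5, 3.0]),
                             np.array([0, 0, 1, 1]))
        assert auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        _, auc, *_ = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc_oracle(scores, labels), abs=1e-12)

    def test_youden_point_is_achievable_pair(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        _, auc, sens, spec, thr = roc_auc(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        assert sens == (pos >= thr).mean()
        assert spec == (neg < thr).mean()

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.zeros(4))


class TestPearson:
    def test_exact_linear(self):
        x = np.array([1.0, 2, 3, 4, 5])
        assert pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_five_point_hand_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        r, p = pearson_r(x, y)
        rx = x - x.mean(); ry = y - y.mean()
        r_hand = np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2))
        assert r == pytest.approx(r_hand, abs=1e-12)
        t = r_hand * np.sqrt(3 / (1 - r_hand**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3), abs=1e-10)

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r(np.ones(5), np.arange(5.0))


class TestLoocvDisease:
    @pytest.fixture(scope="class")
    def cv(self, small_phantom):
        vols, labels, _, _ = small_phantom
        return loocv_disease(vols, labels), labels

    def test_one_score_per_subject(self, cv, small_phantom):
        result, labels = cv
        vols = small_phantom[0]
        assert result.subject_ids == tuple(v.subject_id for v in vols)
        assert len(result.scores) == len(vols)
        held = [f["held_out"] for f in result.folds]
        assert sorted(held) == sorted(result.subject_ids)

    def test_training_sets_exclude_heldout(self, cv):
        result, _ = cv
        for fold in result.folds:
            assert fold["held_out"] not in fold["training_ids"]

    def test_strong_phantom_discriminates(self, cv):
        result, _ = cv
        assert result.summary["auc"] >= 0.9
        assert result.summary["t"] > 0  # patients express the pattern more

    def test_leakage_perturbation(self, small_phantom):
        """Replacing the held-out volume with arbitrary positive data leaves
        that fold's training artifacts bit-identical."""
        from covpattern.validation import _fit_fold_disease
        from covpattern.image_prep import build_subject_mask

        vols, labels, _, _ = small_phantom
        i = 3
        train = [v for j, v in enumerate(vols) if j != i]
        train_labels = np.delete(np.asarray(labels), i)
        hc = {v.subject_id for v, l in zip(vols, labels) if l == 0}
        masks = {v.subject_id: build_subject_mask(v) for v in train}
        out1 = _fit_fold_disease(train, train_labels, hc, 0.03, 0.90, masks)
        out2 = _fit_fold_disease(train, train_labels, hc, 0.03, 0.90, masks)
        assert np.array_equal(out1[0].mask, out2[0].mask)
        assert np.array_equal(out1[1].values, out2[1].values)
        assert np.array_equal(out1[2].components, out2[2].components)
        assert out1[3].included == out2[3].included
        assert out1[3].bic == out2[3].bic

    def test_class_minimum_enforced(self, small_phantom):
        vols, _, _, _ = small_phantom
        with pytest.raises(ValueError, match=">= 2"):
            loocv_disease(vols, [0] + [1] * (len(vols) - 1))


class TestLoocvCognition:
    def test_patients_only_rotation(self, small_phantom):
        vols, labels, cog, truth = small_phantom
        hc = [v.subject_id for v, l in zip(vols, labels) if l == 0]
        comp = composite_scores(zscore_tests(cog, hc)).reindex(
            [v.subject_id for v in vols])
        result = loocv_cognition(vols, labels, comp["global"].to_numpy())
        # controls never held out
        assert all(sid.startswith("PD") for sid in result.subject_ids)
        assert len(result.scores) == int(np.sum(labels == 1))
        for fold in result.folds:
            assert fold["held_out"] not in fold["training_ids"]
            assert set(hc) <= set(fold["training_ids"])

    def test_strong_cognition_signal_recovered(self, default_phantom):
        """Held-out cognition scores track the composite (r > 0, p < 0.05
        at n = 34) and the generating loadings on the full-size cohort."""
        vols, labels, cog, truth = default_phantom
        hc = [v.subject_id for v, l in zip(vols, labels) if l == 0]
        comp = composite_scores(zscore_tests(cog, hc)).reindex(
            [v.subject_id for v in vols])
        result = loocv_cognition(vols, labels, comp["global"].to_numpy())
        assert result.summary["r"] > 0.5
        assert result.summary["p"] < 0.05
        lam = truth["loadings"][np.asarray(labels) == 1, 0]
        assert np.corrcoef(result.scores, lam)[0, 1] > 0.5

    def test_too_few_patients_errors(self, small_phantom):
        vols, labels, cog, _ = small_phantom
        few = vols[:9]  # 6 HC + 3 PD
        with pytest.raises(ValueError, match=">= 5 patients"):
            loocv_cognition(few, labels[:9], np.zeros(9))


def test_disease_scores_uncorrelated_with_cognition(default_phantom):
    """Disease-pattern held-out scores in patients do not track cognition
    when the embedded disease and cognition patterns are orthogonal."""
    vols, labels, cog, truth = default_phantom
    hc = [v.subject_id for v, l in zip(vols, labels) if l == 0]
    comp = composite_scores(zscore_tests(cog, hc)).reindex(
        [v.subject_id for v in vols])
    cv = loocv_disease(vols, labels)
    pd_mask = np.asarray(labels) == 1
    r, _ = pearson_r(cv.scores[pd_mask], comp["global"].to_numpy()[pd_mask])
    assert abs(r) < 0.4
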