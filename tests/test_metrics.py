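"""Ranking metrics (RL / Cov / AP) and binary metrics (F1 / MCC / AUC).

Every metric is checked against an exhaustive brute-force oracle that
enumerates label pairs / threshold sets directly from the definitions, on
random instances that deliberately include tied scores.  On tie-free
instances the scikit-learn implementations serve as an independent
cross-check.
"""

import numpy as np
import pytest
from sklearn.metrics import (
    coverage_error,
    label_ranking_average_precision_score,
    label_ranking_loss,
    roc_auc_score,
)

from sublocnet.errors import ValidationError
from sublocnet.metrics import (
    auc,
    average_precision,
    binary_confusion,
    coverage,
    evaluate_all,
    f1_score,
    mcc,
    ranking_loss,
)

# ---- brute-force oracles straight from the definitions ---------------------


def brute_ranking_loss(y, s):
    vals = []
    for yi, si in zip(y, s):
        pos = [j for j in range(len(yi)) if yi[j] == 1]
        neg = [j for j in range(len(yi)) if yi[j] == 0]
        viol = sum(1 for k in pos for l in neg if si[k] <= si[l])
        vals.append(viol / (len(pos) * len(neg)))
    return float(np.mean(vals))


def brute_coverage(y, s):
    vals = []
    for yi, si in zip(y, s):
        worst = 0
        for j in range(len(yi)):
            if yi[j] == 1:
                rank = sum(1 for k in range(len(yi)) if si[k] >= si[j])
                worst = max(worst, rank)
        vals.append(worst)
    return float(np.mean(vals))


def brute_average_precision(y, s):
    vals = []
    for yi, si in zip(y, s):
        terms = []
        for j in range(len(yi)):
            if yi[j] == 1:
                above = [k for k in range(len(yi)) if si[k] >= si[j]]
                terms.append(sum(yi[k] for k in above) / len(above))
        vals.append(float(np.mean(terms)))
    return float(np.mean(vals))


def brute_auc(y, s):
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(rng, tie_prone=True):
    n = int(rng.integers(1, 9))
    L = int(rng.integers(2, 7))
    y = np.zeros((n, L), dtype=int)
    for i in range(n):
        k = int(rng.integers(1, L))  # at least one positive, at least one negative
        y[i, rng.choice(L, size=k, replace=False)] = 1
    if tie_prone:
        s = rng.choice([0.0, 0.2, 0.4, 0.6, 0.8, 1.0], size=(n, L))
    else:
        s = rng.random((n, L))
    return y, s


class TestWorkedExamples:
    def test_ranking_loss_cases(self):
        assert ranking_loss([[1, 0, 0]], [[0.9, 0.5, 0.1]]) == 0.0
        assert ranking_loss([[1, 0, 0]], [[0.2, 0.9, 0.1]]) == 0.5
        assert ranking_loss([[0, 1]], [[0.9, 0.1]]) == 1.0

    def test_coverage_cases(self):
        assert coverage([[0, 1, 0]], [[0.1, 0.9, 0.2]]) == 1.0
        assert coverage([[1, 0, 1]], [[0.9, 0.8, 0.1]]) == 3.0
        # every label true -> coverage is L regardless of scores
        assert coverage([[1, 1, 1, 1]], [[0.4, 0.1, 0.9, 0.2]]) == 4.0
        assert coverage([[1, 0, 1]], [[0.9, 0.8, 0.1]], zero_based=True) == 2.0

    def test_average_precision_cases(self):
        assert average_precision([[1, 1, 0]], [[0.9, 0.8, 0.1]]) == 1.0
        assert average_precision([[1, 0, 1, 0]], [[0.9, 0.8, 0.7, 0.1]]) == pytest.approx(
            (1 + 2 / 3) / 2
        )
        # single true label at rank r among distinct scores -> 1/r
        assert average_precision([[0, 0, 1, 0]], [[0.9, 0.8, 0.7, 0.1]]) == pytest.approx(1 / 3)

    def test_confusion_and_f1_and_mcc(self):
        conf = binary_confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert conf == {"tp": 1, "tn": 1, "fp": 1, "fn": 1}
        assert f1_score(conf) == pytest.approx(0.5)
        assert f1_score({"tp": 3, "tn": 2, "fp": 0, "fn": 0}) == 1.0
        assert f1_score({"tp": 0, "tn": 1, "fp": 2, "fn": 3}) == 0.0
        assert mcc({"tp": 2, "tn": 2, "fp": 1, "fn": 1}) == pytest.approx(1 / 3)
        assert mcc({"tp": 2, "tn": 2, "fp": 0, "fn": 0}) == 1.0
        assert mcc({"tp": 0, "tn": 0, "fp": 2, "fn": 2}) == -1.0

    def test_undefined_binary_metrics_are_markers(self):
        assert f1_score({"tp": 0, "tn": 4, "fp": 0, "fn": 0}) is None
        assert mcc({"tp": 2, "tn": 0, "fp": 0, "fn": 2}) is None
        assert auc([1, 1, 1], [0.3, 0.2, 0.9]) is None

    def test_auc_cases(self):
        assert auc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2]) == 1.0
        assert auc([1, 0, 1, 0], [0.9, 0.8, 0.3, 0.2]) == 0.75
        assert auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_identical_and_complement_confusions(self):
        same = binary_confusion([1, 0, 1], [1, 0, 1])
        assert same["fp"] == same["fn"] == 0
        comp = binary_confusion([1, 0, 1], [0, 1, 0])
        assert comp["tp"] == comp["tn"] == 0


class TestOracleEquivalence:
    def test_ranking_metrics_match_brute_force(self):
        rng = np.random.default_rng(42)
        for trial in range(200):
            y, s = random_instance(rng, tie_prone=(trial % 2 == 0))
            assert ranking_loss(y, s) == pytest.approx(brute_ranking_loss(y, s), abs=1e-10)
            assert coverage(y, s) == pytest.approx(brute_coverage(y, s), abs=1e-10)
            assert average_precision(y, s) == pytest.approx(
                brute_average_precision(y, s), abs=1e-10
            )

    def test_auc_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 20))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            s = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            assert auc(y, s) == pytest.approx(brute_auc(y, s), abs=1e-10)
            assert auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-10)

    def test_tie_free_agreement_with_sklearn(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            y, s = random_instance(rng, tie_prone=False)
            assert ranking_loss(y, s) == pytest.approx(label_ranking_loss(y, s), abs=1e-10)
            assert coverage(y, s) == pytest.approx(coverage_error(y, s), abs=1e-10)
            assert average_precision(y, s) == pytest.approx(
                label_ranking_average_precision_score(y, s), abs=1e-10
            )


class TestProperties:
    def test_rl_plus_agreement_is_one_tie_free(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            y, s = random_instance(rng, tie_prone=False)
            rl = ranking_loss(y, s)
            per = []
            for yi, si in zip(y, s):
                pos = si[yi == 1]
                neg = si[yi == 0]
                wins = np.sum(pos[:, None] > neg[None, :]) / (len(pos) * len(neg))
                per.append(wins)
            assert rl + float(np.mean(per)) == pytest.approx(1.0, abs=1e-10)

    def test_raising_a_true_label_score_improves_all(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            y, s = random_instance(rng, tie_prone=False)
            i = int(rng.integers(y.shape[0]))
            true_cols = np.flatnonzero(y[i])
            j = int(rng.choice(true_cols))
            s2 = s.copy()
            s2[i, j] = min(1.0, s2[i, j] + rng.random() * (1 - s2[i, j]))
            assert ranking_loss(y, s2) <= ranking_loss(y, s) + 1e-12
            assert coverage(y, s2) <= coverage(y, s) + 1e-12
            assert average_precision(y, s2) >= average_precision(y, s) - 1e-12

    def test_joint_column_permutation_invariance(self):
        rng = np.random.default_rng(9)
        y, s = random_instance(rng, tie_prone=True)
        perm = rng.permutation(y.shape[1])
        assert ranking_loss(y[:, perm], s[:, perm]) == pytest.approx(ranking_loss(y, s))
        assert coverage(y[:, perm], s[:, perm]) == pytest.approx(coverage(y, s))
        assert average_precision(y[:, perm], s[:, perm]) == pytest.approx(
            average_precision(y, s)
        )

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        s = rng.random(30)
        for transform in (lambda x: 2 * x + 1, np.exp, lambda x: x**3):
            assert auc(y, transform(s)) == pytest.approx(auc(y, s), abs=1e-12)

    def test_degenerate_rows_are_errors(self):
        with pytest.raises(ValidationError):
            ranking_loss([[1, 1]], [[0.5, 0.5]])
        with pytest.raises(ValidationError):
            coverage([[0, 0]], [[0.5, 0.5]])
        with pytest.raises(ValidationError):
            average_precision([[0, 0, 0]], [[0.1, 0.2, 0.3]])


class TestEvaluateAll:
    def test_perfect_predictions(self):
        y = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]])
        s = np.where(y == 1, 0.9, 0.1).astype(float)
        rep = evaluate_all(y, s, threshold=0.5)
        assert rep.macro_f1 == 1.0
        assert rep.macro_mcc == 1.0
        assert rep.macro_auc == 1.0
        assert rep.average_precision == 1.0
        assert rep.ranking_loss == 0.0
        assert rep.coverage == pytest.approx(float(np.mean(y.sum(axis=1))))

    def test_composition_matches_individual_calls(self):
        rng = np.random.default_rng(21)
        y, s = random_instance(rng, tie_prone=False)
        rep = evaluate_all(y, s, threshold=0.5)
        assert rep.ranking_loss == pytest.approx(ranking_loss(y, s))
        assert rep.coverage == pytest.approx(coverage(y, s))
        assert rep.average_precision == pytest.approx(average_precision(y, s))
        s_bin = (s >= 0.5).astype(int)
        for j, d in enumerate(rep.per_label):
            conf = binary_confusion(y[:, j], s_bin[:, j])
            assert d["f1"] == f1_score(conf)
            assert d["auc"] == auc(y[:, j], s[:, j])

    def test_undefined_label_excluded_from_macro(self):
        # middle column has no positive example: AUC undefined, F1 undefined
        y = np.array([[1, 0, 0], [1, 0, 0], [0, 0, 1]])
        s = np.array([[0.9, 0.2, 0.1], [0.8, 0.1, 0.3], [0.2, 0.3, 0.9]])
        rep = evaluate_all(y, s, threshold=0.5)
        assert rep.per_label[1]["auc"] is None
        assert rep.per_label[1]["f1"] is None
        defined = [d["auc"] for j, d in enumerate(rep.per_label) if j != 1]
        assert rep.macro_auc == pytest.approx(float(np.mean(defined)))

    def test_mismatched_shapes_error(self):
        with pytest.raises(ValidationError):
            evaluate_all(np.ones((2, 3), dtype=int), np.ones((2, 4)))
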