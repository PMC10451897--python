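"""Cross-validation folds, dataset summaries, metrics and ROC/AUC."""

import numpy as np
import pandas as pd
import pytest

from milct.metrics import (compute_metrics, confusion_matrix, dataset_summary,
                           roc_auc)
from milct.train import Hyperparams, fit, stratified_kfold


def _manifest(n0, n1, split=None):
    rows = [{"path": f"img_{i}.png", "label": 0} for i in range(n0)]
    rows += [{"path": f"img_{n0 + i}.png", "label": 1} for i in range(n1)]
    df = pd.DataFrame(rows)
    if split is not None:
        df["split"] = split
    return df


# printed per-class train/test counts of the reference datasets
EALR_COUNTS = {"train": (815, 448), "test": (204, 112)}
KAGGLE_TRAIN = (23814, 2444, 5294, 873, 708)
KAGGLE_TEST = (39553, 3762, 7861, 1214, 1206)


def ealr_manifest():
    rows = []
    i = 0
    for split, (n0, n1) in EALR_COUNTS.items():
        for label, n in ((0, n0), (1, n1)):
            for _ in range(n):
                rows.append({"path": f"p{i}.png", "label": label,
                             "split": split})
                i += 1
    return pd.DataFrame(rows)


class TestDatasetSummary:
    def test_reference_proportions(self):
        summary = dataset_summary(ealr_manifest())
        assert summary["per_class"][0]["pct"] == 64.53
        assert summary["per_class"][1]["pct"] == 35.47
        assert summary["per_class"][0]["count"] == 1019
        assert summary["per_class"][1]["count"] == 560

    def test_single_class_manifest(self):
        summary = dataset_summary(_manifest(7, 0))
        assert summary["per_class"][0]["pct"] == 100.0

    def test_proportions_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n0, n1 = rng.integers(1, 500, 2)
            s = dataset_summary(_manifest(int(n0), int(n1)))
            total_pct = sum(v["pct"] for v in s["per_class"].values())
            assert abs(total_pct - 100.0) <= 0.01

    def test_empty_manifest_errors(self):
        with pytest.raises(ValueError):
            dataset_summary(pd.DataFrame(columns=["path", "label"]))


class TestStratifiedKFold:
    def test_five_by_five_gives_one_each_per_fold(self):
        folds = stratified_kfold(_manifest(5, 5), k=5, seed=0)
        df = _manifest(5, 5)
        for f in range(5):
            labels = df["label"][folds == f]
            assert len(labels) == 2 and set(labels) == {0, 1}

    def test_partition_is_exact_and_deterministic(self):
        df = _manifest(23, 11)
        f1 = stratified_kfold(df, k=5, seed=3)
        f2 = stratified_kfold(df, k=5, seed=3)
        np.testing.assert_array_equal(f1, f2)
        assert sorted(np.unique(f1)) == [0, 1, 2, 3, 4]
        assert len(f1) == 34

    def test_counts_match_proportional_ideal_within_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n0 = int(rng.integers(5, 26))
            n1 = int(rng.integers(5, 26))
            df = _manifest(n0, n1)
            folds = stratified_kfold(df, k=5, seed=int(rng.integers(100)))
            for f in range(5):
                sub = df["label"][folds == f]
                for cls, n_cls in ((0, n0), (1, n1)):
                    ideal = n_cls / 5
                    assert abs((sub == cls).sum() - ideal) <= 1

    def test_small_class_errors(self):
        with pytest.raises(ValueError):
            stratified_kfold(_manifest(10, 3), k=5, seed=0)


class TestComputeMetrics:
    def test_hand_arithmetic_on_fixed_matrix(self):
        report = compute_metrics(np.array([[90, 10], [5, 95]]))
        assert report.accuracy == pytest.approx(92.5)
        assert report.per_class[1]["SEN"] == pytest.approx(95.0)
        assert report.per_class[1]["SPE"] == pytest.approx(90.0)
        assert report.per_class[1]["PRE"] == pytest.approx(
            100 * 95 / 105)
        f1 = report.per_class[1]["F1"]
        pre, sen = 95 / 105, 95 / 100
        assert f1 == pytest.approx(100 * 2 * pre * sen / (pre + sen))
        assert report.per_class[1]["F1_arith"] == pytest.approx(
            100 * (pre + sen) / 2)

    def test_perfect_diagonal_all_hundred(self):
        report = compute_metrics(np.array([[40, 0], [0, 60]]))
        for c in (0, 1):
            for key in ("PRE", "SEN", "SPE", "F1"):
                assert report.per_class[c][key] == pytest.approx(100.0)
        assert report.accuracy == pytest.approx(100.0)

    def test_macro_is_mean_of_per_class(self):
        report = compute_metrics(np.array([[33, 7], [12, 48]]))
        for key, val in report.macro.items():
            assert val == pytest.approx(
                (report.per_class[0][key] + report.per_class[1][key]) / 2)

    def test_degenerate_prediction_warns_and_flags_nan(self):
        # everything predicted class 0: class-1 precision undefined
        with pytest.warns(RuntimeWarning):
            report = compute_metrics(np.array([[50, 0], [20, 0]]))
        assert np.isnan(report.per_class[1]["PRE"])
        assert not np.isnan(report.per_class[0]["PRE"])

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(np.zeros((2, 2), dtype=int))

    def test_confusion_matrix_layout(self):
        cm = confusion_matrix([0, 0, 1, 1, 1], [0, 1, 1, 1, 0])
        np.testing.assert_array_equal(cm, [[1, 1], [1, 2]])


def _pairwise_auc(scores, labels):
    """Oracle: P(score_pos > score_neg) with ties counted half."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_gives_auc_one(self):
        _, _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        _, _, auc = roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1])
        assert auc == pytest.approx(0.5)

    def test_matches_pairwise_ranking_oracle_on_hand_listed_scores(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.65, 0.2, 0.9]
        labels = [0, 0, 1, 1, 0, 1, 0, 1]
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(_pairwise_auc(scores, labels))

    def test_matches_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)),
                              replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 1)  # force ties
            _, _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(_pairwise_auc(scores, labels))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.2, 0.8], [1, 1])


class TestFitContracts:
    def test_two_runs_same_seed_identical_losses(self, tiny_model):
        from milct.model import build_model
        from milct.specs import MILHeadSpec, tiny_model_spec
        rng = np.random.default_rng(3)
        imgs = [rng.integers(0, 256, (96, 96, 3)).astype(np.uint8)
                for _ in range(8)]
        y = np.array([0, 1] * 4)
        finals = []
        for _ in range(2):
            model, _ = build_model(tiny_model_spec(96), MILHeadSpec(m=8, l=4),
                                   seed=7)
            xf, xc = model.prepare_inputs(imgs)
            hist = fit(model, xf, xc, y, Hyperparams(epochs=2, batch_size=4),
                       seed=7)
            finals.append(hist[-1])
        assert finals[0] == finals[1]

    def test_eta_one_leaves_mil_head_untouched_after_a_step(self):
        from milct.model import build_model
        from milct.specs import BranchSpec, MILHeadSpec, ModelSpec
        spec = ModelSpec(f_branch=BranchSpec(8, 32, 4, 1, 1),
                         c_branch=BranchSpec(16, 32, 8, 1, 2), T=1, eta=1.0)
        model, _ = build_model(spec, MILHeadSpec(m=4, l=2), seed=8)
        before = {k: v.copy() for k, v in model.mil.state_dict().items()}
        rng = np.random.default_rng(8)
        imgs = [rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
                for _ in range(4)]
        xf, xc = model.prepare_inputs(imgs)
        fit(model, xf, xc, np.array([0, 1, 0, 1]),
            Hyperparams(epochs=1, batch_size=4), seed=8)
        after = model.mil.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
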