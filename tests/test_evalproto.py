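"""Patient-level splitting, metrics, aggregation and bootstrap behavior."""

import numpy as np
import pandas as pd
import pytest

from mammofuse.evalproto import (BootstrapInterval, ConfusionMatrix, auprc, auroc,
                                 bootstrap_ci, confusion, cv_aggregate,
                                 dataset_summary, evaluate_predictions,
                                 metrics_from_confusion, patient_labels,
                                 patient_level_split, split_with_folds,
                                 stratified_kfold_patients)


def make_table(n_patients, malignant_frac=0.3, seed=0, images_per_patient=(1, 2, 3)):
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n_patients):
        label = int(rng.random() < malignant_frac)
        for _ in range(rng.choice(images_per_patient)):
            rows.append({"patient_id": f"P{pid}", "label": label})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ splitting
def test_split_counts_and_no_image_leakage():
    table = make_table(10, 0.5, seed=1)
    split = patient_level_split(table, 0.2, seed=0)
    assert len(split.test_patients) == 2
    assert split.test_patients & split.dev_patients == frozenset()
    test_images = table[table["patient_id"].isin(split.test_patients)]
    dev_images = table[table["patient_id"].isin(split.dev_patients)]
    assert len(test_images) + len(dev_images) == len(table)
    assert set(test_images["patient_id"]) & set(dev_images["patient_id"]) == set()


def test_split_stratification_tolerance_on_large_cohort():
    table = make_table(1000, 0.3, seed=2)
    split = patient_level_split(table, 0.2, seed=3)
    plabels = patient_labels(table)
    test_frac_malignant = plabels[list(split.test_patients)].mean()
    assert abs(test_frac_malignant - plabels.mean()) < 0.02


def test_split_rejects_underpopulated_classes():
    table = pd.DataFrame({
        "patient_id": ["a", "b", "c"], "label": [1, 0, 0],
    })
    with pytest.raises(ValueError):
        patient_level_split(table)


def test_kfold_partitions_dev_set_with_balanced_folds():
    table = make_table(500, 0.3, seed=4)
    fold_of = stratified_kfold_patients(table, 5, seed=5)
    patients = set(table["patient_id"])
    assert set(fold_of) == patients
    sizes = pd.Series(fold_of).value_counts()
    assert sorted(sizes.index) == [1, 2, 3, 4, 5]
    assert sizes.max() - sizes.min() <= 1
    plabels = patient_labels(table)
    overall = plabels.mean()
    for fold in range(1, 6):
        members = [p for p, f in fold_of.items() if f == fold]
        assert abs(plabels[members].mean() - overall) < 0.05


def test_kfold_rejects_infeasible_stratification():
    table = make_table(8, 0.25, seed=6)
    with pytest.raises(ValueError):
        stratified_kfold_patients(table, 5, seed=0)


def test_patient_label_majority_with_malignant_tiebreak():
    table = pd.DataFrame({
        "patient_id": ["a", "a", "b", "b", "c"],
        "label": [0, 1, 0, 0, 1],
    })
    lab = patient_labels(table)
    assert lab["a"] == 1  # tie resolves to malignant
    assert lab["b"] == 0
    assert lab["c"] == 1


# ------------------------------------------------------------------- metrics
def test_confusion_examples_and_hand_tally():
    y = np.array([1, 1, 0, 0])
    assert confusion(y, y) == ConfusionMatrix(tp=2, tn=2, fp=0, fn=0)
    cm = confusion(y, 1 - y)
    assert cm.tp == 0 and cm.tn == 0 and cm.fp == 2 and cm.fn == 2
    # 8-element hand case
    y_true = np.array([1, 0, 1, 1, 0, 0, 1, 0])
    y_pred = np.array([1, 0, 0, 1, 1, 0, 1, 1])
    cm = confusion(y_true, y_pred)
    assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 2, 2, 1)
    with pytest.raises(ValueError):
        confusion([0, 2], [0, 1])


def test_metrics_perfect_prediction_all_ones():
    m = metrics_from_confusion(ConfusionMatrix(tp=5, tn=5, fp=0, fn=0))
    for name in ("accuracy", "precision", "recall", "f1", "mcc", "kappa"):
        assert getattr(m, name) == pytest.approx(1.0), name


def test_f1_is_harmonic_mean_of_printed_precision_recall():
    precision, recall = 0.986, 0.985
    f1 = 2 * precision * recall / (precision + recall)
    assert round(100 * f1, 2) == 98.55


def test_metrics_formula_oracle_on_counted_case():
    cm = ConfusionMatrix(tp=45, tn=40, fp=5, fn=10)
    m = metrics_from_confusion(cm)
    assert m.accuracy == pytest.approx(0.85)
    assert m.precision == pytest.approx(45 / 50)
    assert m.recall == pytest.approx(45 / 55)
    f1 = 2 * (45 / 50) * (45 / 55) / ((45 / 50) + (45 / 55))
    assert m.f1 == pytest.approx(f1)
    mcc = (45 * 40 - 5 * 10) / np.sqrt(50 * 55 * 45 * 50)
    assert m.mcc == pytest.approx(mcc)
    po = 0.85
    pe = (50 * 55 + 50 * 45) / 100**2
    assert m.kappa == pytest.approx((po - pe) / (1 - pe))


def test_metrics_zero_division_conventions():
    # no predicted positives and no true positives
    m = metrics_from_confusion(ConfusionMatrix(tp=0, tn=10, fp=0, fn=0))
    assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0
    assert m.mcc == 0.0 and m.kappa == 0.0


def test_metrics_cross_checked_against_sklearn_on_random_cases():
    from sklearn import metrics as skm
    rng = np.random.default_rng(7)
    for _ in range(20):
        y_true = rng.integers(0, 2, 40)
        y_pred = rng.integers(0, 2, 40)
        if len(np.unique(y_true)) < 2 or len(np.unique(y_pred)) < 2:
            continue
        m = metrics_from_confusion(confusion(y_true, y_pred))
        assert m.precision == pytest.approx(skm.precision_score(y_true, y_pred))
        assert m.recall == pytest.approx(skm.recall_score(y_true, y_pred))
        assert m.f1 == pytest.approx(skm.f1_score(y_true, y_pred))
        assert m.mcc == pytest.approx(skm.matthews_corrcoef(y_true, y_pred))
        assert m.kappa == pytest.approx(skm.cohen_kappa_score(y_true, y_pred))


# --------------------------------------------------------------- ranking AUCs
def brute_force_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def test_auroc_separating_ties_and_brute_force_oracle():
    labels = np.array([0, 0, 1, 1])
    assert auroc([0.1, 0.2, 0.8, 0.9], labels) == pytest.approx(1.0)
    assert auroc([0.5, 0.5, 0.5, 0.5], labels) == pytest.approx(0.5)
    scores6 = [0.2, 0.7, 0.4, 0.4, 0.9, 0.1]
    labels6 = [0, 1, 1, 0, 1, 0]
    assert auroc(scores6, labels6) == pytest.approx(brute_force_auroc(scores6, labels6))
    rng = np.random.default_rng(8)
    for _ in range(15):
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            continue
        scores = np.round(rng.random(n), 2)  # coarse scores force ties
        assert auroc(scores, labels) == pytest.approx(brute_force_auroc(scores, labels))
    with pytest.raises(ValueError):
        auroc([0.1, 0.2], [1, 1])


def test_auprc_bounds_and_single_class_error():
    labels = np.array([0, 1, 0, 1, 1])
    assert auprc([0.1, 0.9, 0.2, 0.8, 0.7], labels) == pytest.approx(1.0)
    assert 0.0 < auprc([0.9, 0.1, 0.8, 0.2, 0.3], labels) < 1.0
    with pytest.raises(ValueError):
        auprc([0.5, 0.5], [0, 0])


def test_evaluate_predictions_combines_threshold_and_ranking_metrics():
    y = np.array([0, 1, 0, 1])
    m = evaluate_predictions(y, y, scores=[0.1, 0.9, 0.2, 0.8])
    assert m.accuracy == 1.0 and m.auroc == 1.0 and m.auprc == 1.0


# --------------------------------------------------------------- aggregation
def test_cv_aggregate_reproduces_mean_and_textbook_sd():
    df = pd.DataFrame({"accuracy": [1.0, 2.0, 3.0]})
    agg = cv_aggregate(df)
    assert agg.loc["accuracy", "mean"] == pytest.approx(2.0)
    assert agg.loc["accuracy", "sd"] == pytest.approx(1.0)
    same = cv_aggregate(pd.DataFrame({"f1": [0.9, 0.9, 0.9]}))
    assert same.loc["f1", "sd"] == pytest.approx(0.0)
    single = cv_aggregate(pd.DataFrame({"f1": [0.7]}))
    assert single.loc["f1", "sd"] == 0.0
    with pytest.raises(ValueError):
        cv_aggregate([])


# ------------------------------------------------------------------ bootstrap
def test_bootstrap_constant_values_and_determinism():
    ci = bootstrap_ci([3.0, 3.0, 3.0], iterations=500, seed=0)
    assert ci.lower == ci.upper == pytest.approx(3.0)
    a = bootstrap_ci([1.0, 2.0, 5.0], iterations=2000, seed=42)
    b = bootstrap_ci([1.0, 2.0, 5.0], iterations=2000, seed=42)
    assert (a.lower, a.upper) == (b.lower, b.upper)
    assert a.lower <= np.mean([1.0, 2.0, 5.0]) <= a.upper


def test_bootstrap_two_values_reaches_enumerated_extremes():
    # resamples of {0,1} have 4 equally likely draws with means {0, .5, .5, 1};
    # at large B both extremes occur, so the 95% interval spans (0, 1)
    ci = bootstrap_ci([0.0, 1.0], iterations=10_000, seed=1)
    assert ci.lower == pytest.approx(0.0)
    assert ci.upper == pytest.approx(1.0)


# ------------------------------------------------------------------- summary
def test_dataset_summary_counts_and_paper_scale_arithmetic():
    rng = np.random.default_rng(9)
    # 6775 patients totalling 10239 images
    n_patients, n_images = 6775, 10239
    extra = n_images - n_patients
    counts = np.ones(n_patients, dtype=int)
    idx = rng.choice(n_patients, extra)
    np.add.at(counts, idx, 1)
    rows = [{"patient_id": p, "label": 0} for p, c in enumerate(counts) for _ in range(c)]
    summary = dataset_summary(pd.DataFrame(rows))
    assert summary["n_patients"] == n_patients
    assert summary["n_images"] == n_images
    assert round(summary["images_per_patient_mean"], 2) == 1.51

    ones = pd.DataFrame({"patient_id": list("abcd"), "label": [0, 1, 0, 1]})
    s = dataset_summary(ones)
    assert s["images_per_patient_mean"] == 1.0 and s["images_per_patient_sd"] == 0.0
    two = pd.DataFrame({"patient_id": ["a", "b", "b", "b"], "label": [0] * 4})
    assert dataset_summary(two)["images_per_patient_mean"] == 2.0


def test_split_with_folds_has_no_cross_partition_overlap():
    table = make_table(120, 0.35, seed=10)
    split = split_with_folds(table, 0.2, 5, seed=11)
    assert set(split.fold_of) == set(split.dev_patients)
    assert not set(split.fold_of) & split.test_patients
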