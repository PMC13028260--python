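"""Patient-level evaluation protocol.

Splitting is always at the patient level: a patient's images all land in the
same partition, so no intra-patient information can leak between development
and test data or across cross-validation folds.  Stratification uses the
patient-level label (majority label over the patient's images; ties resolve
to malignant, the screening-conservative choice).

Metrics use malignant as the positive class throughout: accuracy, precision,
recall, F1, Matthews correlation coefficient, Cohen's kappa, AUROC (the rank
statistic P(s+ > s-) + 0.5 P(s+ = s-)) and AUPRC (precision-recall step
integration).  Fold aggregation reports the arithmetic mean and the sample
(n-1) standard deviation.  Uncertainty uses the percentile bootstrap:
resample the values with replacement B times (default 10,000) and take the
2.5th/97.5th percentiles of the resampled means.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold, train_test_split

METRIC_COLUMNS = ["precision", "recall", "f1", "accuracy", "mcc", "kappa", "auroc", "auprc"]

_LABEL_MAP = {"benign": 0, "malignant": 1, 0: 0, 1: 1, "0": 0, "1": 1}


def _normalize_labels(values) -> np.ndarray:
    out = []
    for v in values:
        key = v.lower() if isinstance(v, str) else v
        if key not in _LABEL_MAP:
            raise ValueError(f"label {v!r} is not binary benign/malignant")
        out.append(_LABEL_MAP[key])
    return np.asarray(out, dtype=int)


def patient_labels(table: pd.DataFrame) -> pd.Series:
    """Patient-level stratification label: majority image label, ties -> malignant."""
    lab = pd.Series(_normalize_labels(table["label"]), index=table.index)
    grouped = lab.groupby(table["patient_id"]).mean()
    return (grouped >= 0.5).astype(int)


@dataclass
class SplitAssignment:
    test_patients: frozenset
    dev_patients: frozenset
    fold_of: dict  # patient_id -> fold index 1..k

    def partition_of(self, patient_id) -> str:
        return "test" if patient_id in self.test_patients else "dev"


def patient_level_split(table: pd.DataFrame, test_frac: float = 0.2,
                        seed: int = 0) -> SplitAssignment:
    """Stratified patient-level development/test split (default 80/20)."""
    plabels = patient_labels(table)
    counts = plabels.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 patients per class for a stratified split")
    dev, test = train_test_split(
        plabels.index.to_numpy(), test_size=test_frac,
        stratify=plabels.to_numpy(), random_state=seed,
    )
    return SplitAssignment(frozenset(test), frozenset(dev), {})


def stratified_kfold_patients(dev_table: pd.DataFrame, k: int = 5,
                              seed: int = 0) -> dict:
    """Assign each development patient to exactly one of k stratified folds."""
    plabels = patient_labels(dev_table)
    if plabels.value_counts().min() < k:
        raise ValueError(f"stratification infeasible: need >= {k} patients per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    patients = plabels.index.to_numpy()
    fold_of = {}
    for fold, (_, idx) in enumerate(skf.split(patients, plabels.to_numpy()), start=1):
        for p in patients[idx]:
            fold_of[p] = fold
    return fold_of


def split_with_folds(table: pd.DataFrame, test_frac: float = 0.2, k: int = 5,
                     seed: int = 0) -> SplitAssignment:
    """80/20 patient split plus k folds inside the development part."""
    split = patient_level_split(table, test_frac, seed)
    dev_table = table[table["patient_id"].isin(split.dev_patients)]
    fold_of = stratified_kfold_patients(dev_table, k, seed)
    return SplitAssignment(split.test_patients, split.dev_patients, fold_of)


# ------------------------------------------------------------------- metrics
@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Exact counts with malignant (1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr in (y_true, y_pred):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must lie in {0, 1}")
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


@dataclass
class FoldMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    kappa: float
    auroc: float | None = None
    auprc: float | None = None

    def as_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        return {
            f.name: (None if getattr(self, f.name) is None else scale * getattr(self, f.name))
            for f in fields(self)
        }


def metrics_from_confusion(cm: ConfusionMatrix) -> FoldMetrics:
    """Threshold metrics with explicit zero-division conventions:
    precision/recall = 0 for empty denominators, MCC = 0 for a zero marginal,
    kappa = 0 when chance agreement equals 1."""
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    n = cm.total
    accuracy = (tp + tn) / n if n else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    po = accuracy
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n) if n else 1.0
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 0.0
    return FoldMetrics(accuracy, precision, recall, f1, float(mcc), kappa)


def auroc(scores, labels) -> float:
    """Area under the ROC curve; malignant scores ranked above benign."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined with a single class")
    return float(skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step integration), positive = malignant."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPRC undefined with a single class")
    return float(skm.average_precision_score(labels, np.asarray(scores, dtype=float)))


def evaluate_predictions(y_true, y_pred, scores=None) -> FoldMetrics:
    """Full metric record from hard predictions and optional malignant scores."""
    m = metrics_from_confusion(confusion(y_true, y_pred))
    if scores is not None:
        m.auroc = auroc(scores, y_true)
        m.auprc = auprc(scores, y_true)
    return m


def cv_aggregate(folds) -> pd.DataFrame:
    """Mean and sample SD per metric over folds.

    ``folds`` is a list of :class:`FoldMetrics` or a DataFrame with metric
    columns.  A single fold yields SD 0 by convention.
    """
    if isinstance(folds, pd.DataFrame):
        df = folds
    else:
        if len(folds) == 0:
            raise ValueError("cv_aggregate needs at least one fold")
        df = pd.DataFrame([f.as_dict() for f in folds])
    df = df.dropna(axis=1, how="all")
    if df.shape[0] == 0:
        raise ValueError("cv_aggregate needs at least one fold")
    mean = df.mean()
    sd = df.std(ddof=1) if df.shape[0] > 1 else pd.Series(0.0, index=df.columns)
    return pd.DataFrame({"mean": mean, "sd": sd})


@dataclass
class BootstrapInterval:
    lower: float
    upper: float
    iterations: int
    level: float


def bootstrap_ci(values, iterations: int = 10_000, level: float = 0.95,
                 seed: int = 0) -> BootstrapInterval:
    """Percentile bootstrap over resampled means; seed-reproducible."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or iterations < 1:
        raise ValueError("bootstrap_ci needs >= 1 value and >= 1 iteration")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(iterations, values.size))
    means = values[idx].mean(axis=1)
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [tail, 100.0 - tail])
    return BootstrapInterval(float(lo), float(hi), iterations, level)


def dataset_summary(table: pd.DataFrame) -> dict:
    """Patient/image counts and images-per-patient mean and sample SD."""
    if len(table) == 0:
        raise ValueError("empty patient table")
    counts = table.groupby("patient_id").size()
    return {
        "n_patients": int(counts.size),
        "n_images": int(len(table)),
        "images_per_patient_mean": float(counts.mean()),
        "images_per_patient_sd": float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
    }
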