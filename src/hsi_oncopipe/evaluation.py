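"""Class-weighted linear SVM, ROC/Youden analysis and per-patient
leave-one-patient-out cross-validation with Table-style aggregation.

Tumor is the positive class throughout; decision scores are oriented so
positive means tumor.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from hsi_oncopipe.errors import ContractError

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "auc", "mcc")

#: columns of a feature table that are not features
ID_COLUMNS = ("patient_id", "sample_id", "label")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ContractError("confusion-matrix counts must be >= 0")


def metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """sens/spec/PPV/NPV/MCC from a 2x2 confusion matrix.

    Any metric whose defining denominator is zero is None (rendered "-").
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "mcc": (tp * tn - fp * fn) / math.sqrt(mcc_den) if mcc_den else None,
    }


def class_weights(labels: np.ndarray) -> dict[str, float]:
    """Inverse-frequency class weights w_c = N / (K * n_c) with K = 2."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ContractError("cannot weight an empty label set")
    n = len(labels)
    out = {}
    for cls in ("non_tumor", "tumor"):
        n_c = int(np.sum(labels == cls))
        if n_c == 0:
            warnings.warn(f"class {cls!r} absent; omitted from weights", stacklevel=2)
            continue
        out[cls] = n / (2 * n_c)
    return out


@dataclass(frozen=True)
class LinearModel:
    """Affine decision rule s(x) = w.x + b; positive score means tumor."""

    weights: np.ndarray
    bias: float
    C: float
    class_weight: dict[str, float]

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias


def fit_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    weights: dict[str, float] | None = None,
    C: float = 1.0,
) -> LinearModel:
    """Fit a linear soft-margin SVM minimizing
    (1/2)||w||^2 + C * sum_i w_class(i) * hinge(y_i, s(x_i)).

    Uses the libsvm solver, which is deterministic for a fixed dataset.
    Features are expected to be standardized by the caller (the CV loop
    standardizes with training-fold statistics).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ContractError("SVM training requires both classes")
    if X.ndim != 2 or X.shape[1] < 1:
        raise ContractError("feature matrix must be 2-D with >= 1 feature")
    if np.all(np.ptp(X, axis=0) == 0):
        raise ContractError("degenerate training set: all feature rows identical")
    weights = weights if weights is not None else class_weights(y)
    svc = SVC(kernel="linear", C=C, class_weight=weights, tol=1e-8)
    svc.fit(X, y)
    w = svc.coef_.ravel().copy()
    b = float(svc.intercept_[0])
    # libsvm orients the score toward classes_[1]; flip if that is not tumor
    if svc.classes_[1] != "tumor":
        w, b = -w, -b
    return LinearModel(w, b, C, dict(weights))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC points at every distinct score threshold (predict tumor when
    score >= threshold), monotone in FPR and TPR, endpoints included.

    Returns a frame with columns fpr, tpr, threshold ordered from the
    (0, 0) corner (threshold +inf) to (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == "tumor"
    neg = labels == "non_tumor"
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("ROC requires both classes present")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    rows = []
    for t in thresholds:
        pred = scores >= t
        rows.append(
            {
                "fpr": np.sum(pred & neg) / n_neg,
                "tpr": np.sum(pred & pos) / n_pos,
                "threshold": t,
            }
        )
    return pd.DataFrame(rows)


def auc(roc: pd.DataFrame) -> float:
    """Trapezoidal area under the ROC curve (equals tie-adjusted U/(n+ n-))."""
    return float(np.trapezoid(roc["tpr"].to_numpy(), roc["fpr"].to_numpy()))


def youden_threshold(roc: pd.DataFrame) -> float:
    """Threshold maximizing J = TPR - FPR; ties resolve to the lowest FPR."""
    j = roc["tpr"].to_numpy() - roc["fpr"].to_numpy()
    best = sorted(
        range(len(roc)), key=lambda i: (-j[i], roc["fpr"].iloc[i], roc["tpr"].iloc[i])
    )[0]
    return float(roc["threshold"].iloc[best])


@dataclass
class PatientResult:
    patient_id: str
    n_tumor: int
    n_non_tumor: int
    cm: ConfusionMatrix
    threshold: float
    values: dict[str, float | None]  # METRIC_NAMES -> value or None
    roc: pd.DataFrame | None = None

    @property
    def has_tumor(self) -> bool:
        return self.n_tumor > 0


@dataclass
class MetricsReport:
    rows: list[PatientResult]
    mean: dict[str, float | None]
    fold_errors: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"patient": r.patient_id}
            rec.update(
                {m: ("-" if r.values[m] is None else round2(r.values[m])) for m in METRIC_NAMES}
            )
            rec["tumor_free"] = not r.has_tumor
            recs.append(rec)
        mean_rec = {"patient": "Mean", "tumor_free": ""}
        mean_rec.update(
            {m: ("-" if self.mean[m] is None else round2(self.mean[m])) for m in METRIC_NAMES}
        )
        recs.append(mean_rec)
        return pd.DataFrame(recs)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "fold_errors": self.fold_errors,
            "mean": self.mean,
            "patients": [
                {
                    "patient": r.patient_id,
                    "n_tumor": r.n_tumor,
                    "n_non_tumor": r.n_non_tumor,
                    "confusion": {"tp": r.cm.tp, "fp": r.cm.fp, "tn": r.cm.tn, "fn": r.cm.fn},
                    "threshold": r.threshold,
                    "metrics": r.values,
                    "roc": None if r.roc is None else r.roc.to_dict(orient="list"),
                }
                for r in self.rows
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def round2(x: float) -> float:
    """2-decimal display rounding, half away from zero (0.805 -> 0.81)."""
    return math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)


def aggregate_mean(
    rows: list[PatientResult], fold_errors: list[str] | None = None, config: dict | None = None
) -> MetricsReport:
    """Cohort mean row: each metric averaged over patients where it is
    defined, except that tumor-free patients contribute only to the
    specificity mean.
    """
    mean: dict[str, float | None] = {}
    for m in METRIC_NAMES:
        vals = [
            r.values[m]
            for r in rows
            if r.values[m] is not None and (r.has_tumor or m == "specificity")
        ]
        mean[m] = float(np.mean(vals)) if vals else None
    return MetricsReport(rows, mean, fold_errors or [], config or {})


def _evaluate_patient(
    patient_id: str,
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float | None,
) -> PatientResult:
    """Confusion matrix and metrics for one held-out patient.

    If ``threshold`` is None, the Youden threshold of the patient's own
    ROC is used (requires both classes); tumor-free patients fall back to
    the SVM decision boundary at 0.
    """
    labels = np.asarray(labels)
    n_tumor = int(np.sum(labels == "tumor"))
    n_non = int(np.sum(labels == "non_tumor"))
    roc = None
    values: dict[str, float | None] = dict.fromkeys(METRIC_NAMES)
    if n_tumor and n_non:
        roc = roc_points(scores, labels)
        values["auc"] = auc(roc)
        if threshold is None:
            threshold = youden_threshold(roc)
    if threshold is None:
        threshold = 0.0
    pred = scores >= threshold
    cm = ConfusionMatrix(
        tp=int(np.sum(pred & (labels == "tumor"))),
        fp=int(np.sum(pred & (labels == "non_tumor"))),
        tn=int(np.sum(~pred & (labels == "non_tumor"))),
        fn=int(np.sum(~pred & (labels == "tumor"))),
    )
    values.update(metrics(cm))
    if not (n_tumor and n_non):
        values["auc"] = None
    return PatientResult(patient_id, n_tumor, n_non, cm, float(threshold), values, roc)


def lopo_cv(
    features: pd.DataFrame,
    C: float = 1.0,
    threshold_mode: str = "test_youden",
) -> MetricsReport:
    """Leave-one-patient-out cross-validation of the weighted linear SVM.

    Per fold: standardize features with training-fold statistics, fit the
    class-weighted SVM on all other patients, score the held-out
    patient's patches, and derive the operating point.
    ``threshold_mode='test_youden'`` (default) picks the Youden threshold
    on the held-out patient's own ROC; ``'train_youden'`` picks it on the
    pooled training scores.  Folds whose training data has one class are
    skipped and recorded in ``fold_errors``.
    """
    if threshold_mode not in {"test_youden", "train_youden"}:
        raise ContractError(f"unknown threshold_mode {threshold_mode!r}")
    patients = list(dict.fromkeys(features["patient_id"]))
    if len(patients) < 2:
        raise ContractError("LOPO-CV needs >= 2 patients")
    feature_cols = [c for c in features.columns if c not in ID_COLUMNS]
    X_all = features[feature_cols].to_numpy(dtype=float)
    y_all = features["label"].to_numpy()
    pid = features["patient_id"].to_numpy()
    rows, errors = [], []
    for patient in patients:
        test = pid == patient
        X_tr, y_tr = X_all[~test], y_all[~test]
        X_te, y_te = X_all[test], y_all[test]
        if len(np.unique(y_tr)) < 2:
            errors.append(f"patient {patient}: training fold has a single class")
            continue
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        model = fit_linear_svm((X_tr - mu) / sd, y_tr, class_weights(y_tr), C=C)
        scores = model.decision((X_te - mu) / sd)
        threshold = None
        if threshold_mode == "train_youden":
            train_roc = roc_points(model.decision((X_tr - mu) / sd), y_tr)
            threshold = youden_threshold(train_roc)
        rows.append(_evaluate_patient(str(patient), scores, y_te, threshold))
    return aggregate_mean(
        rows, errors, {"C": C, "threshold_mode": threshold_mode, "features": feature_cols}
    )
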