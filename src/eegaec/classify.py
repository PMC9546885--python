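"""Leave-one-out RBF-SVM evaluation of connectivity features.

The diagnostic question: do the four sgACC–DLPFC AEC values separate
patients from controls at the single-subject level?  Each subject is
predicted by a soft-margin SVM with Gaussian kernel

    k(u, v) = exp(-||u - v||^2 / (2 * kernel_scale^2))

trained on all remaining subjects (leave-one-out cross-validation), and
the pooled predictions are summarized as sensitivity, specificity and
accuracy.  The evaluation harness is the contribution here; the quadratic
program itself is solved by scikit-learn's SVC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

#: Feature order for the diagnostic model: the four sgACC-DLPFC pairs.
FEATURE_PAIRS: tuple[tuple[str, str], ...] = (
    ("sgACC_L", "DLPFC_L"),
    ("sgACC_L", "DLPFC_R"),
    ("sgACC_R", "DLPFC_L"),
    ("sgACC_R", "DLPFC_R"),
)


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM settings: soft-margin C, Gaussian kernel width, standardization."""

    box_constraint: float = 3.0
    kernel_scale: float = 1.0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.box_constraint <= 0 or self.kernel_scale <= 0:
            raise ValueError("box_constraint and kernel_scale must be positive")


def features_from_tensor(tensor, band: str = "beta1") -> np.ndarray:
    """Subjects x 4 matrix of the sgACC-DLPFC AEC values in one band."""
    cols = [tensor.cell(a, b, band) for a, b in FEATURE_PAIRS]
    return np.column_stack(cols)


def loocv_svm(
    features: np.ndarray,
    labels: np.ndarray,
    cfg: ClassifierConfig = ClassifierConfig(),
) -> np.ndarray:
    """Leave-one-out predictions of an RBF-SVM.

    Deterministic for fixed inputs: the SVC decision function is evaluated
    directly and exact zeros are broken toward the negative (control)
    class.  Subject order does not affect any individual prediction, since
    every training fold is the full sample minus that subject.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features must be (n_subjects, n_features) matching labels")
    classes = np.unique(labels)
    if classes.size != 2 or np.min(np.bincount(np.searchsorted(classes, labels))) < 2:
        raise ValueError("need two classes with at least 2 subjects each")

    gamma = 1.0 / (2.0 * cfg.kernel_scale**2)
    n = features.shape[0]
    preds = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_tr, y_tr = features[mask], labels[mask]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"training fold without subject {i} is single-class")
        mu = x_tr.mean(axis=0)
        sd = x_tr.std(axis=0, ddof=1) if cfg.standardize else np.ones(x_tr.shape[1])
        sd = np.where(sd == 0, 1.0, sd)
        if cfg.standardize:
            x_tr = (x_tr - mu) / sd
        svm = SVC(C=cfg.box_constraint, kernel="rbf", gamma=gamma, tol=1e-6)
        svm.fit(x_tr, y_tr)
        x_te = (features[i : i + 1] - mu) / sd if cfg.standardize else features[i : i + 1]
        score = float(svm.decision_function(x_te)[0])
        # decision_function > 0 -> second class in sorted order; exact ties
        # fall to the first (negative/control) class
        preds[i] = svm.classes_[1] if score > 0 else svm.classes_[0]
    return preds


def classification_metrics(
    predicted: np.ndarray, true: np.ndarray, positive_class
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of binary predictions.

    Sensitivity = TP/(TP+FN) over true positives; specificity = TN/(TN+FP)
    over true negatives; accuracy over everyone.  Accuracy is identically
    the prevalence-weighted mean of the other two.
    """
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ValueError("predicted and true must be equal-length, non-empty")
    if positive_class not in true:
        raise ValueError("positive_class absent from true labels")
    pos = true == positive_class
    tp = np.count_nonzero(pos & (predicted == positive_class))
    fn = np.count_nonzero(pos) - tp
    tn = np.count_nonzero(~pos & (predicted != positive_class))
    fp = np.count_nonzero(~pos) - tn
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    accuracy = (tp + tn) / true.size
    return float(sensitivity), float(specificity), float(accuracy)


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """Metrics directly from a confusion matrix (counts)."""
    pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
    true = np.array([1] * (tp + fn) + [0] * (tn + fp))
    return classification_metrics(pred, true, positive_class=1)
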