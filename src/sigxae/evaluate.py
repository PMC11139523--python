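"""Benchmarking metrics for signature recovery and exposure usefulness.

Two evaluation harnesses:

* **Signature recovery.**  Extracted profiles are matched one-to-one to the
  known ground-truth profiles with the Hungarian algorithm, maximizing
  total cosine similarity.  A matched pair with similarity at or above a
  threshold counts as a true positive; unmatched or below-threshold truth
  is a false negative, surplus or below-threshold estimates are false
  positives.  Precision, sensitivity and F1 are reported on a threshold
  grid over [0.8, 1] together with the normalized (trapezoidal) area under
  each metric-vs-threshold curve.

* **Exposure-based classification.**  How discriminative exposures are for
  tumour type is measured by feeding them to a class-balanced random
  forest under stratified 5-fold cross-validation, after dropping classes
  with fewer than 10 samples, and reporting Matthews correlation, Cohen's
  kappa and balanced accuracy (mean and SD over folds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    balanced_accuracy_score,
    cohen_kappa_score,
    matthews_corrcoef,
)
from sklearn.model_selection import StratifiedKFold

from .catalogue import ExposureMatrix, SignatureMatrix

__all__ = [
    "MatchResult",
    "PRFTable",
    "ClassificationReport",
    "cosine_similarity",
    "match_signatures",
    "confusion_at_threshold",
    "prf_curve",
    "classify_exposures",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity a.b / (|a||b|); in [0, 1] for non-negative input."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


@dataclass
class MatchResult:
    """One-to-one matching between estimated and true signatures."""

    pairs: list[tuple[int, int, float]]  # (estimated idx, true idx, cosine)
    unmatched_estimated: list[int]
    unmatched_true: list[int]
    k_est: int
    k_true: int


def match_signatures(S_est: SignatureMatrix, S_true: SignatureMatrix) -> MatchResult:
    """Hungarian matching of estimated to true profiles by cosine similarity.

    Produces ``min(k_est, k_true)`` pairs maximizing the total cosine
    similarity; the leftover columns of the larger matrix are unmatched.
    """
    A = S_est.profiles
    B = S_true.profiles
    norm_a = np.linalg.norm(A, axis=0)
    norm_b = np.linalg.norm(B, axis=0)
    if (norm_a == 0).any() or (norm_b == 0).any():
        raise ValueError("cannot match all-zero signature columns")
    sim = (A / norm_a).T @ (B / norm_b)  # k_est x k_true
    rows, cols = linear_sum_assignment(-sim)
    pairs = [(int(i), int(j), float(sim[i, j])) for i, j in zip(rows, cols)]
    matched_est = {i for i, _, _ in pairs}
    matched_true = {j for _, j, _ in pairs}
    return MatchResult(
        pairs=pairs,
        unmatched_estimated=[i for i in range(A.shape[1]) if i not in matched_est],
        unmatched_true=[j for j in range(B.shape[1]) if j not in matched_true],
        k_est=A.shape[1],
        k_true=B.shape[1],
    )


def confusion_at_threshold(match: MatchResult, threshold: float
                           ) -> tuple[int, int, int]:
    """(TP, FP, FN) at one cosine threshold.

    TP are matched pairs with similarity >= threshold; every other true
    signature is a FN and every other estimated signature a FP, so
    ``TP + FN = k_true`` and ``TP + FP = k_est``.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    # tolerance keeps an exact match (cosine 1 up to rounding) a TP at 1.0
    tp = sum(1 for _, _, c in match.pairs if c >= threshold - 1e-12)
    return tp, match.k_est - tp, match.k_true - tp


@dataclass
class PRFTable:
    """Precision/sensitivity/F1 across cosine thresholds, with AUCs."""

    table: pd.DataFrame  # threshold, TP, FP, FN, precision, sensitivity, f1
    auc: dict[str, float]  # normalized area under each metric curve

    @property
    def thresholds(self) -> np.ndarray:
        return self.table["threshold"].to_numpy()


def prf_curve(
    S_est: SignatureMatrix,
    S_true: SignatureMatrix,
    thresholds: Sequence[float] | None = None,
) -> PRFTable:
    """Recovery metrics on a cosine-threshold grid (default 0.8..1, step 0.01).

    The normalized AUC is the trapezoidal area of each metric over the grid
    divided by the grid width, so perfect recovery at every threshold gives
    exactly 1.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.80, 1.0001, 0.01), 10)
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    if len(thresholds) < 2:
        raise ValueError("need at least two thresholds for an AUC")
    match = match_signatures(S_est, S_true)
    rows = []
    for thr in thresholds:
        tp, fp, fn = confusion_at_threshold(match, thr)
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = (2 * precision * sensitivity / (precision + sensitivity)
              if (precision + sensitivity) else 0.0)
        rows.append({
            "threshold": thr, "TP": tp, "FP": fp, "FN": fn,
            "precision": precision, "sensitivity": sensitivity, "f1": f1,
        })
    table = pd.DataFrame(rows)
    width = thresholds[-1] - thresholds[0]
    auc = {
        metric: float(np.trapezoid(table[metric], thresholds) / width)
        for metric in ("precision", "sensitivity", "f1")
    }
    return PRFTable(table=table, auc=auc)


@dataclass
class ClassificationReport:
    """Cross-validated tumour-type classification from exposures."""

    per_fold: pd.DataFrame  # fold, mcc, kappa, balanced_accuracy
    dropped_classes: list[str]
    n_samples: int
    classes: list[str]

    @property
    def mean(self) -> pd.Series:
        return self.per_fold[["mcc", "kappa", "balanced_accuracy"]].mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_fold[["mcc", "kappa", "balanced_accuracy"]].std(ddof=1)

    def summary(self) -> str:
        m, s = self.mean, self.sd
        lines = [
            "Exposure-based classification (stratified 5-fold CV)",
            "=" * 52,
            f"classes: {len(self.classes)}   samples: {self.n_samples}",
            f"dropped (fewer than minimum samples): {self.dropped_classes or 'none'}",
            f"Matthews correlation : {m['mcc']:.2f} ({s['mcc']:.2f})",
            f"Cohen's kappa        : {m['kappa']:.2f} ({s['kappa']:.2f})",
            f"balanced accuracy    : {m['balanced_accuracy']:.2f} "
            f"({s['balanced_accuracy']:.2f})",
        ]
        return "\n".join(lines)


def classify_exposures(
    exposures: ExposureMatrix,
    labels: Sequence[str],
    min_class_size: int = 10,
    seed: int = 0,
    n_estimators: int = 500,
    n_splits: int = 5,
) -> ClassificationReport:
    """Classify tumour type from exposures with a balanced random forest.

    Classes with fewer than ``min_class_size`` samples are dropped before
    cross-validation.  Requires at least two surviving classes.
    """
    Z = exposures.values
    y = np.asarray([str(l) for l in labels])
    if len(y) != Z.shape[0]:
        raise ValueError("labels must align with exposure rows")
    counts = pd.Series(y).value_counts()
    dropped = sorted(counts[counts < min_class_size].index)
    keep = ~np.isin(y, dropped)
    Z, y = Z[keep], y[keep]
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError(
            f"fewer than 2 classes remain after dropping {dropped} "
            f"(min_class_size={min_class_size})"
        )
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    rows = []
    for fold, (train, test) in enumerate(cv.split(Z, y)):
        clf = RandomForestClassifier(
            n_estimators=n_estimators, class_weight="balanced",
            random_state=seed + fold, n_jobs=1,
        )
        clf.fit(Z[train], y[train])
        pred = clf.predict(Z[test])
        rows.append({
            "fold": fold,
            "mcc": matthews_corrcoef(y[test], pred),
            "kappa": cohen_kappa_score(y[test], pred),
            "balanced_accuracy": balanced_accuracy_score(y[test], pred),
        })
    return ClassificationReport(
        per_fold=pd.DataFrame(rows), dropped_classes=[str(d) for d in dropped],
        n_samples=int(Z.shape[0]), classes=classes,
    )
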