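"""Model evaluation: accuracies, ROC/PR curves, feature ablation, and the
band rule for combining the structural model with an external predictor.

Rankings use the recognized pathogenicity score — larger scores mean
stronger risk.  ROC and PR curves come from a threshold sweep over the
unique scores; both AUCs are trapezoidal.  Class calls use threshold 0.5.

The combination rule: an external pathogenicity score in [0, 1] with its own
decision threshold (default 0.611) decides a variant outright unless the
score falls inside the uncertainty band (default [0.45, 0.772], endpoints
inclusive), in which case the structural model's call is used instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import precision_recall_curve, roc_curve

from .encoding import FEATURE_CHANNELS

__all__ = [
    "EvalReport",
    "CombinationRule",
    "evaluate",
    "feature_ablation",
    "select_feature_channels",
    "combine_with_external",
]


@dataclass
class EvalReport:
    """Scores of one prediction set against binary labels."""

    n_pos: int
    n_neg: int
    overall_accuracy: float
    tpr_accuracy: float        # accuracy on positives (sensitivity)
    tnr_accuracy: float        # accuracy on negatives (specificity)
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_auc: float
    pr_recall: np.ndarray
    pr_precision: np.ndarray
    pr_auc: float

    def to_dict(self) -> dict:
        return dict(n_pos=self.n_pos, n_neg=self.n_neg,
                    overall_accuracy=self.overall_accuracy,
                    tpr_accuracy=self.tpr_accuracy,
                    tnr_accuracy=self.tnr_accuracy,
                    roc_auc=self.roc_auc, pr_auc=self.pr_auc)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def curves_to_csv(self, path_prefix: str | Path) -> None:
        import pandas as pd

        prefix = Path(path_prefix)
        pd.DataFrame({"fpr": self.roc_fpr, "tpr": self.roc_tpr}).to_csv(
            f"{prefix}.roc.csv", index=False)
        pd.DataFrame({"recall": self.pr_recall,
                      "precision": self.pr_precision}).to_csv(
            f"{prefix}.pr.csv", index=False)


def evaluate(probs: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> EvalReport:
    """Score per-example pathogenicity probabilities against binary labels.

    With a single label class present, accuracies are still computed and the
    AUCs are reported as NaN (undefined).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(probs) != len(labels) or len(probs) == 0:
        raise ValueError("probs and labels must be equal-length and non-empty")
    calls = (probs >= threshold).astype(int)
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    overall = float((calls == labels).mean())
    tpr_acc = float((calls[pos] == 1).mean()) if n_pos else float("nan")
    tnr_acc = float((calls[neg] == 0).mean()) if n_neg else float("nan")

    if n_pos and n_neg:
        fpr, tpr, _ = roc_curve(labels, probs)
        roc_auc = float(np.trapezoid(tpr, fpr))
        precision, recall, _ = precision_recall_curve(labels, probs)
        # recall is monotonically decreasing in curve order; trapezoid over
        # it keeps zero-width segments at tied recall levels weightless
        pr_auc = float(sk_auc(recall, precision))
        pr_recall, pr_precision = recall[::-1], precision[::-1]
    else:
        fpr = tpr = pr_recall = pr_precision = np.array([])
        roc_auc = pr_auc = float("nan")
    return EvalReport(n_pos, n_neg, overall, tpr_acc, tnr_acc,
                      fpr, tpr, roc_auc, pr_recall, pr_precision, pr_auc)


def select_feature_channels(X: np.ndarray, feature: str) -> np.ndarray:
    """Copy of X with all channels outside the named feature set zeroed."""
    if feature not in FEATURE_CHANNELS:
        raise ValueError(f"unknown feature {feature!r}; "
                         f"choose from {sorted(FEATURE_CHANNELS)}")
    keep = FEATURE_CHANNELS[feature]
    out = np.zeros_like(X)
    out[..., keep] = X[..., keep]
    return out


def feature_ablation(train_X: np.ndarray, train_y: np.ndarray,
                     test_X: np.ndarray, test_y: np.ndarray,
                     features: tuple[str, ...] = ("all", "cnt", "hbond", "ovl", "combi"),
                     make_estimator=None, random_state: int = 0) -> dict[str, EvalReport]:
    """Train one model per feature configuration and score each on the test set.

    Non-selected channels are zeroed in both the training and the test
    matrices; every configuration uses the same estimator settings, seeds
    (hence identical undersampling/validation splits) and labels, so the
    comparison isolates the feature's contribution.
    """
    if not features:
        raise ValueError("feature set must not be empty")
    if make_estimator is None:
        from .model import ResNetClassifier2D, UndersampleEnsembleClassifier

        def make_estimator():
            return UndersampleEnsembleClassifier(
                ResNetClassifier2D(widths="tiny"), random_state=random_state)

    reports: dict[str, EvalReport] = {}
    for feat in features:
        model = make_estimator()
        model.fit(select_feature_channels(train_X, feat), train_y)
        probs = model.predict_proba(select_feature_channels(test_X, feat))[:, 1]
        reports[feat] = evaluate(probs, test_y)
    return reports


@dataclass(frozen=True)
class CombinationRule:
    """External-score decision rule with an uncertainty band."""

    external_threshold: float = 0.611
    band: tuple[float, float] = (0.45, 0.772)

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo <= self.external_threshold <= hi:
            raise ValueError("band must contain the external threshold")

    def in_band(self, score: float | np.ndarray) -> np.ndarray:
        lo, hi = self.band
        return (np.asarray(score) >= lo) & (np.asarray(score) <= hi)


def combine_with_external(model_probs: np.ndarray, external_scores: np.ndarray,
                          rule: CombinationRule | None = None):
    """Combine model probabilities with an external predictor's scores.

    Outside the uncertainty band the external score decides
    (call = score >= threshold); inside the band (endpoints inclusive) the
    structural model decides (call = prob >= 0.5).  Returns
    ``(calls, decided_by, rank_score)`` where ``decided_by`` is
    ``"external"`` or ``"model"`` per variant and ``rank_score`` is the
    deciding source's score (usable for ranked curves).
    """
    rule = rule or CombinationRule()
    model_probs = np.asarray(model_probs, dtype=float)
    external = np.asarray(external_scores, dtype=float)
    if model_probs.shape != external.shape:
        raise ValueError("model and external score vectors must align")
    if external.min() < 0 or external.max() > 1:
        bad = external[(external < 0) | (external > 1)][0]
        raise ValueError(f"external score {bad} outside [0, 1]")
    inside = rule.in_band(external)
    calls = np.where(inside, model_probs >= 0.5,
                     external >= rule.external_threshold).astype(int)
    decided_by = np.where(inside, "model", "external")
    rank_score = np.where(inside, model_probs, external)
    return calls, decided_by, rank_score
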