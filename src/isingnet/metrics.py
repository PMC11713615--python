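"""Evaluation of inferred structure against ground truth or data.

Neuron-type classification is scored with TPR/TNR (sensitivity/specificity)
and PPV/NPV (precision of each predicted class), with excitatory as the
positive class, against the prior-based random guess implied by the
excitatory fraction γ. Link identification is scored as TPR/FPR over ordered
pairs (self-links excluded by default — inferred diagonals encode
refractoriness, not anatomy). Activity prediction is scored by the Pearson
correlation between predicted and observed covariance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import roc_curve as _sk_roc_curve

from .model import CovariancePair

__all__ = [
    "TypeClassificationReport",
    "LinkReport",
    "type_metrics",
    "link_metrics",
    "roc_curve",
    "covariance_agreement",
]


@dataclass
class TypeClassificationReport:
    TPR: float
    TNR: float
    PPV: float
    NPV: float
    overall_precision: float
    random_TPR: float
    random_TNR: float
    random_PPV: float
    random_NPV: float
    random_overall: float
    undefined: list[str]

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "TPR", "TNR", "PPV", "NPV", "overall_precision", "random_TPR",
            "random_TNR", "random_PPV", "random_NPV", "random_overall",
            "undefined")}


@dataclass
class LinkReport:
    TPR: float
    FPR: float
    TP: int
    FP: int
    TN: int
    FN: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("TPR", "FPR", "TP", "FP", "TN", "FN")}


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def type_metrics(z_true: np.ndarray, z_hat: np.ndarray,
                 gamma: float) -> TypeClassificationReport:
    """Neuron-type confusion metrics with excitatory (+1) as positive.

    ``overall_precision`` is P(ẑ=+)·PPV + P(ẑ=−)·NPV, i.e. the overall
    accuracy; random baselines are the prior-guess values γ (positive
    metrics), 1−γ (negative) and γ² + (1−γ)² (overall). An empty predicted
    class makes its precision undefined (NaN, flagged)."""
    z_true = np.asarray(z_true)
    z_hat = np.asarray(z_hat)
    if z_true.shape != z_hat.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((z_hat > 0) & (z_true > 0)))
    fn = int(np.sum((z_hat < 0) & (z_true > 0)))
    fp = int(np.sum((z_hat > 0) & (z_true < 0)))
    tn = int(np.sum((z_hat < 0) & (z_true < 0)))
    n = z_true.size
    tpr = _safe_div(tp, tp + fn)
    tnr = _safe_div(tn, tn + fp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    undefined = [name for name, v in (("TPR", tpr), ("TNR", tnr),
                                      ("PPV", ppv), ("NPV", npv))
                 if not np.isfinite(v)]
    p_pos = (tp + fp) / n
    p_neg = (tn + fn) / n
    overall = (p_pos * ppv if p_pos > 0 else 0.0) + (p_neg * npv if p_neg > 0 else 0.0)
    return TypeClassificationReport(
        TPR=tpr, TNR=tnr, PPV=ppv, NPV=npv, overall_precision=overall,
        random_TPR=gamma, random_TNR=1.0 - gamma, random_PPV=gamma,
        random_NPV=1.0 - gamma, random_overall=gamma ** 2 + (1.0 - gamma) ** 2,
        undefined=undefined)


def link_metrics(W_true: np.ndarray, phi_hat: np.ndarray,
                 include_diagonal: bool = False) -> LinkReport:
    """Link-identification TPR/FPR: positives are the ordered pairs with a
    nonzero true weight."""
    W_true = np.asarray(W_true)
    phi_hat = np.asarray(phi_hat)
    if W_true.shape != phi_hat.shape:
        raise ValueError("shape mismatch")
    mask = np.ones(W_true.shape, dtype=bool)
    if not include_diagonal:
        np.fill_diagonal(mask, False)
    pos = (W_true != 0) & mask
    pred = (phi_hat != 0) & mask
    tp = int(np.sum(pos & pred))
    fn = int(np.sum(pos & ~pred))
    fp = int(np.sum(~pos & pred & mask))
    tn = int(np.sum(~pos & ~pred & mask))
    return LinkReport(TPR=_safe_div(tp, tp + fn), FPR=_safe_div(fp, fp + tn),
                      TP=tp, FP=fp, TN=tn, FN=fn)


def roc_curve(scores: np.ndarray, W_true: np.ndarray,
              include_diagonal: bool = False) -> np.ndarray:
    """Full threshold sweep of link identification for a score matrix
    (e.g. |J| from MLE, or a transfer-entropy score). Returns an array of
    (FPR, TPR) rows from (0, 0) to (1, 1), ties grouped."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    mask = np.ones(scores.shape, dtype=bool)
    if not include_diagonal:
        np.fill_diagonal(mask, False)
    y = (np.asarray(W_true)[mask] != 0).astype(int)
    fpr, tpr, _ = _sk_roc_curve(y, scores[mask])
    return np.column_stack([fpr, tpr])


def covariance_agreement(pred: CovariancePair, true: CovariancePair,
                         ) -> tuple[float, float]:
    """Pearson correlation between predicted and observed second moments:
    off-diagonal entries of C (diagonal is identically 1), all entries of D.
    Zero variance on either side yields NaN."""
    if pred.C.shape != true.C.shape or pred.D.shape != true.D.shape:
        raise ValueError("shape mismatch")
    n = pred.C.shape[0]
    od = ~np.eye(n, dtype=bool)

    def _corr(x: np.ndarray, y: np.ndarray) -> float:
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan")
        return float(pearsonr(x, y).statistic)

    return (_corr(pred.C[od], true.C[od]),
            _corr(pred.D.ravel(), true.D.ravel()))
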