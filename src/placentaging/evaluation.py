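"""Evaluation metrics: Dice overlap, agreement statistics, ROC/AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["dice", "agreement_stats", "roc_auc", "AgreementStats", "RocResult"]


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); two empty masks score 1.0."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


@dataclass(frozen=True)
class AgreementStats:
    """Pairwise method-agreement summary.

    ``bias`` and the limits of agreement follow the Bland-Altman convention
    on differences ``x - y`` (first argument minus second):
    ``bias +/- 1.96 * SD(diff)``. ``pearson_r`` is NaN (``r_defined=False``)
    when either input has zero variance.
    """

    pearson_r: float
    rmse: float
    bias: float
    loa_lower: float
    loa_upper: float
    r_defined: bool
    diff_convention: str = "x - y"


def agreement_stats(x, y) -> AgreementStats:
    """Pearson r, RMSE and Bland-Altman limits of agreement between x and y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1D vectors with at least 3 entries")
    diff = x - y
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if x.std() == 0 or y.std() == 0:
        r, r_defined = float("nan"), False
    else:
        r, r_defined = float(stats.pearsonr(x, y).statistic), True
    return AgreementStats(
        pearson_r=r,
        rmse=rmse,
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        r_defined=r_defined,
    )


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels, positive: str = "high_risk") -> RocResult:
    """ROC curve and AUC for separating ``positive`` from the rest.

    Higher scores must indicate the positive (abnormal) class — use the
    accelerated-aging probability, or equivalently ``-Z``. The AUC equals the
    Mann-Whitney probability ``P(score_pos > score_neg) + 0.5 P(tie)``, which
    is how ties are handled.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive).astype(int)
    if y.min() == y.max():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)
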