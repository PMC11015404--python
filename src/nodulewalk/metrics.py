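"""Evaluation metrics derived from 2x2 confusion counts.

All rate-type fields of :class:`MetricsReport` (accuracy, error,
sensitivity, specificity, precision, F1, the FPR/FNR variants) are
reported on the percent scale; overlap (Jaccard), Matthews correlation
and Cohen's kappa are plain ratios.

Two false-rate conventions are exposed side by side: the standard rates
``fpr = FP/(FP+TN)`` and ``fnr = FN/(FN+TP)`` (so fpr + specificity = 100
exactly), and the alternative forms ``fpr_alt = FP/(TP+TN)`` and
``fnr_alt = FN/(TP+TN)`` that normalise by the total number of correct
decisions.  Both carry information; reports default to the standard
rates and name the alternative explicitly.

Ratios with a zero denominator are reported as NaN and listed in the
report's ``degenerate`` field rather than raising, so batch evaluation
never aborts on an edge case.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ContractError, FormatError


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a two-class confusion matrix."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ContractError(f"{name} must be >= 0")
        if self.total < 1:
            raise ContractError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """The metric suite computed from one set of confusion counts.

    Percent-scaled: accuracy, error, sensitivity, specificity, precision,
    f1, fpr, fnr, fpr_alt, fnr_alt.  Ratio-scaled: overlap, mcc, kappa.
    ``degenerate`` lists the fields whose denominator was zero.
    """

    accuracy: float
    error: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    fpr: float
    fnr: float
    fpr_alt: float
    fnr_alt: float
    overlap: float
    mcc: float
    kappa: float
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = asdict(self)
        d["degenerate"] = list(self.degenerate)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.as_dict(), **kwargs)


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Tabulate two label sequences against the stated positive class."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise FormatError(
            f"label sequences must be 1-D and equal length, got {yt.shape} "
            f"and {yp.shape}"
        )
    if yt.size < 1:
        raise FormatError("label sequences must be non-empty")
    pos_t = yt == positive_class
    pos_p = yp == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def _ratio(num: float, den: float, degenerate: list[str], name: str) -> float:
    if den == 0:
        degenerate.append(name)
        return math.nan
    return num / den


def compute_metrics(cc: ConfusionCounts) -> MetricsReport:
    """All metrics of the suite from one 2x2 table.

    accuracy    = (TP + TN) / (TP + FP + TN + FN)        [percent]
    sensitivity = TP / (TP + FN)                          [percent]
    specificity = TN / (TN + FP)                          [percent]
    precision   = TP / (TP + FP)                          [percent]
    f1          = 2 * precision * sensitivity / (precision + sensitivity)
    fpr_alt     = FP / (TP + TN); fnr_alt = FN / (TP + TN)   [percent]
    overlap     = TP / (TP + FP + FN)                     [ratio]
    mcc, kappa  : standard 2x2 formulas                   [ratio]

    ``error`` is defined as 100 - accuracy and ``fpr`` as
    100 - specificity (``fnr`` as 100 - sensitivity), so the
    complementarity identities hold exactly in floating point.
    """
    deg: list[str] = []
    tp, fp, fn, tn = float(cc.tp), float(cc.fp), float(cc.fn), float(cc.tn)
    n = tp + fp + fn + tn

    accuracy = 100.0 * (tp + tn) / n
    sensitivity = 100.0 * _ratio(tp, tp + fn, deg, "sensitivity")
    specificity = 100.0 * _ratio(tn, tn + fp, deg, "specificity")
    precision = 100.0 * _ratio(tp, tp + fp, deg, "precision")
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        deg.append("f1")
        f1 = math.nan
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    fpr_alt = 100.0 * _ratio(fp, tp + tn, deg, "fpr_alt")
    fnr_alt = 100.0 * _ratio(fn, tp + tn, deg, "fnr_alt")
    overlap = _ratio(tp, tp + fp + fn, deg, "overlap")

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        deg.append("mcc")
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / mcc_den

    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / (n * n)
    if pe == 1.0:
        deg.append("kappa")
        kappa = math.nan
    else:
        kappa = (po - pe) / (1.0 - pe)

    return MetricsReport(
        accuracy=accuracy,
        error=100.0 - accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        fpr=100.0 - specificity,
        fnr=100.0 - sensitivity,
        fpr_alt=fpr_alt,
        fnr_alt=fnr_alt,
        overlap=overlap,
        mcc=mcc,
        kappa=kappa,
        degenerate=tuple(deg),
    )


def confusion_percentages(cc: ConfusionCounts, ndigits: int = 1) -> dict[str, float]:
    """Each confusion cell as a rounded percentage of the total count.

    Mirrors the per-cell percent annotation of a standard confusion-matrix
    chart (count and share of all observations in each cell).
    """
    n = cc.total
    return {
        "tp": round(100.0 * cc.tp / n, ndigits),
        "fp": round(100.0 * cc.fp / n, ndigits),
        "fn": round(100.0 * cc.fn / n, ndigits),
        "tn": round(100.0 * cc.tn / n, ndigits),
    }


def _mask_pair(mask_pred, mask_true) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(getattr(mask_pred, "mask", mask_pred), dtype=bool)
    b = np.asarray(getattr(mask_true, "mask", mask_true), dtype=bool)
    if a.shape != b.shape:
        raise FormatError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def confusion_from_masks(mask_pred, mask_true) -> ConfusionCounts:
    """Pixelwise confusion counts of a predicted vs ground-truth mask."""
    a, b = _mask_pair(mask_pred, mask_true)
    return ConfusionCounts(
        tp=int(np.sum(a & b)),
        fp=int(np.sum(a & ~b)),
        fn=int(np.sum(~a & b)),
        tn=int(np.sum(~a & ~b)),
    )


def overlap_pixels(mask_pred, mask_true) -> float:
    """Jaccard overlap TP / (TP + FP + FN) of two binary masks."""
    a, b = _mask_pair(mask_pred, mask_true)
    union = np.sum(a | b)
    if union == 0:
        raise ContractError("overlap of two empty masks is undefined")
    return float(np.sum(a & b) / union)


def dice(mask_pred, mask_true) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) of two binary masks."""
    a, b = _mask_pair(mask_pred, mask_true)
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ContractError("Dice of two empty masks is undefined")
    return float(2.0 * np.sum(a & b) / denom)
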