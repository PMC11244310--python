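"""Confusion-matrix evaluation of vessel masks against a manual gold standard.

Vessel pixels are the positive class.  When a field-of-view (FOV) mask is
supplied, only FOV pixels are counted — the convention for fundus datasets
that ship camera-aperture masks.  Undefined ratios (zero denominator) are
reported as NaN, never raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["Acc", "Se", "Sp", "Pr", "F1", "JC"]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Six derived scores; NaN marks a metric whose denominator was zero.

    Se = TP/(TP+FN)        sensitivity / recall
    Sp = TN/(TN+FP)        specificity
    Acc = (TP+TN)/total    accuracy
    Pr = TP/(TP+FP)        precision
    F1 = 2TP/(FP+FN+2TP)   harmonic mean of precision and recall
    JC = TP/(TP+FP+FN)     Jaccard overlap; identically F1/(2-F1) when defined
    """

    Se: float
    Sp: float
    Acc: float
    Pr: float
    F1: float
    JC: float
    counts: ConfusionCounts
    image_id: str = ""


def confusion(pred, truth, fov=None) -> ConfusionCounts:
    """Pixel confusion counts, restricted to the FOV when one is given."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if fov is not None:
        f = np.asarray(fov).astype(bool)
        if f.shape != p.shape:
            raise ValueError(f"shape mismatch: fov {f.shape} vs pred {p.shape}")
        p, t = p[f], t[f]
    return ConfusionCounts(
        TP=int(np.count_nonzero(p & t)),
        TN=int(np.count_nonzero(~p & ~t)),
        FP=int(np.count_nonzero(p & ~t)),
        FN=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics(counts: ConfusionCounts, image_id: str = "") -> MetricsReport:
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    return MetricsReport(
        Se=_ratio(tp, tp + fn),
        Sp=_ratio(tn, tn + fp),
        Acc=_ratio(tp + tn, counts.total),
        Pr=_ratio(tp, tp + fp),
        F1=_ratio(2 * tp, fp + fn + 2 * tp),
        JC=_ratio(tp, tp + fp + fn),
        counts=counts,
        image_id=image_id,
    )


def batch_report(pairs) -> pd.DataFrame:
    """Per-image metric rows plus an unweighted "Average" row.

    ``pairs`` is an iterable of (pred, truth, fov-or-None, id).  Undefined
    (NaN) metrics are excluded from that column's mean with a logged notice.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("batch_report requires at least one (pred, truth, fov, id)")
    rows = []
    for pred, truth, fov, image_id in pairs:
        rep = metrics(confusion(pred, truth, fov), image_id=str(image_id))
        rows.append(
            {
                "image": rep.image_id,
                "TP": rep.counts.TP,
                "TN": rep.counts.TN,
                "FP": rep.counts.FP,
                "FN": rep.counts.FN,
                "Acc": rep.Acc,
                "Se": rep.Se,
                "Sp": rep.Sp,
                "Pr": rep.Pr,
                "F1": rep.F1,
                "JC": rep.JC,
            }
        )
    df = pd.DataFrame(rows)
    avg = {"image": "Average", "TP": "", "TN": "", "FP": "", "FN": ""}
    for col in METRIC_COLUMNS:
        vals = df[col]
        if vals.isna().any():
            logger.info(
                "column %s: %d undefined value(s) excluded from the average",
                col,
                int(vals.isna().sum()),
            )
        avg[col] = float(vals.mean(skipna=True))
    return pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
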