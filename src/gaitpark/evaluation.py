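"""Confusion counts, accuracy/precision/recall/F-measure and report
tables.

Binary metrics follow the usual count definitions: accuracy
``(Tp+Tn)/total``; per-class precision ``Tp/(Tp+Fp)`` and recall
``Tp/(Tp+Fn)`` with each class in turn as positive; the reported
precision/recall are macro averages (unweighted mean of the two
per-class values, both always emitted alongside); and

    F_beta = (1 + beta^2) * P * R / (beta^2 * P + R)

computed from the macro precision and recall, with beta = 1 by default
so precision and recall weigh equally.  Confusion matrices are also
emitted row-normalized (rows = true classes, each row summing to 100%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import PredictionSet
from .types import ValidationError

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics", "f_measure", "report_study"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: object
    negative_class: object

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def row_normalized(self) -> pd.DataFrame:
        """2x2 percentage matrix, rows = true classes (positive first),
        each row summing to 100."""
        pos_tot = self.tp + self.fn
        neg_tot = self.tn + self.fp
        rows = {
            str(self.positive_class): [100.0 * self.tp / pos_tot, 100.0 * self.fn / pos_tot]
            if pos_tot else [np.nan, np.nan],
            str(self.negative_class): [100.0 * self.fp / neg_tot, 100.0 * self.tn / neg_tot]
            if neg_tot else [np.nan, np.nan],
        }
        return pd.DataFrame.from_dict(
            rows, orient="index",
            columns=[str(self.positive_class), str(self.negative_class)],
        )


def confusion(preds: PredictionSet, positive_class: object) -> ConfusionCounts:
    """Count Tp/Tn/Fp/Fn with the given class as positive."""
    labels = set(np.unique(preds.y_true)) | set(np.unique(preds.y_pred))
    if positive_class not in labels:
        raise ValidationError(f"unseen label {positive_class!r}")
    others = sorted(l for l in labels if l != positive_class)
    if len(others) != 1:
        raise ValidationError(f"confusion requires binary labels, got {sorted(labels)}")
    neg = others[0]
    yt_pos = preds.y_true == positive_class
    yp_pos = preds.y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(yt_pos & yp_pos)),
        tn=int(np.sum(~yt_pos & ~yp_pos)),
        fp=int(np.sum(~yt_pos & yp_pos)),
        fn=int(np.sum(yt_pos & ~yp_pos)),
        positive_class=positive_class,
        negative_class=neg,
    )


def f_measure(precision: float, recall: float, beta: float = 1.0) -> float:
    """F_beta from precision and recall (all in percent)."""
    if beta <= 0:
        raise ValidationError("beta must be positive")
    if precision + recall == 0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * precision * recall / (b2 * precision + recall)


@dataclass
class MetricReport:
    accuracy: float
    precision: float          # macro, %
    recall: float             # macro, %
    f: float                  # F_beta from macro precision/recall, %
    beta: float
    per_class: dict = field(default_factory=dict)  # class -> {precision, recall}
    confusion_pct: pd.DataFrame | None = None
    undefined: list = field(default_factory=list)  # classes with 0-denominator metrics


def metrics(counts: ConfusionCounts, beta: float = 1.0) -> MetricReport:
    """Accuracy plus macro precision/recall/F from confusion counts.

    A per-class precision or recall with a zero denominator is flagged
    undefined and excluded from the macro mean rather than treated as 0.
    """
    if counts.total == 0:
        raise ValidationError("empty prediction set")
    acc = 100.0 * (counts.tp + counts.tn) / counts.total

    per_class: dict = {}
    undefined: list = []
    # positive class
    for cls, tp, fp, fn in (
        (counts.positive_class, counts.tp, counts.fp, counts.fn),
        (counts.negative_class, counts.tn, counts.fn, counts.fp),
    ):
        prec = 100.0 * tp / (tp + fp) if (tp + fp) else np.nan
        rec = 100.0 * tp / (tp + fn) if (tp + fn) else np.nan
        if np.isnan(prec) or np.isnan(rec):
            undefined.append(cls)
        per_class[cls] = {"precision": prec, "recall": rec}

    macro_p = float(np.nanmean([v["precision"] for v in per_class.values()]))
    macro_r = float(np.nanmean([v["recall"] for v in per_class.values()]))
    return MetricReport(
        accuracy=acc,
        precision=macro_p,
        recall=macro_r,
        f=f_measure(macro_p, macro_r, beta),
        beta=beta,
        per_class=per_class,
        confusion_pct=counts.row_normalized(),
        undefined=undefined,
    )


def report_study(
    predictions: dict[str, dict[str, PredictionSet]],
    positive_class: object,
    beta: float = 1.0,
    baseline: dict[str, dict[str, PredictionSet]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Aggregate tables over datasets x classifiers.

    ``predictions[dataset][classifier]`` holds the (with-selection)
    LOOCV predictions; ``baseline`` optionally holds the
    without-selection arm.  Returns a dict of DataFrames:

    * ``"metrics"`` — accuracy/precision/recall/F per dataset & model;
    * ``"accuracy"`` — with/without-selection accuracy comparison
      (when a baseline is given);
    * ``"confusion"`` — row-normalized confusion rows, long form.
    """
    metric_rows, acc_rows, conf_rows = [], [], []
    for ds, by_model in predictions.items():
        for model, preds in by_model.items():
            rep = metrics(confusion(preds, positive_class), beta=beta)
            metric_rows.append({
                "dataset": ds, "classifier": model,
                "accuracy": rep.accuracy, "precision": rep.precision,
                "recall": rep.recall, "f_measure": rep.f,
            })
            acc_row = {"dataset": ds, "classifier": model, "with_selection": rep.accuracy}
            if baseline and model in baseline.get(ds, {}):
                base = metrics(confusion(baseline[ds][model], positive_class), beta=beta)
                acc_row["without_selection"] = base.accuracy
            acc_rows.append(acc_row)
            cm = rep.confusion_pct
            for true_cls in cm.index:
                row = {"dataset": ds, "classifier": model, "true_class": true_cls}
                row.update({f"pred_{c}": cm.loc[true_cls, c] for c in cm.columns})
                conf_rows.append(row)
    out = {
        "metrics": pd.DataFrame(metric_rows),
        "accuracy": pd.DataFrame(acc_rows),
        "confusion": pd.DataFrame(conf_rows),
    }
    return out
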