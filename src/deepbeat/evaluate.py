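"""Classification metrics: one-vs-rest confusion counts, per-class
sensitivity/specificity/FPR/FNR/precision/F1, and support-weighted macro
averages, with optional filtering to excellent-quality windows and
per-individual aggregation.

Zero-denominator convention: an undefined metric is reported as 0 and a
warning is logged (F1 with no predicted and no true positives is 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .types import QaClass, ValidationError

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "fpr", "fnr", "precision", "f1")


@dataclass
class ConfusionCounts:
    """One-vs-rest integer counts per class."""

    classes: list
    tp: dict
    fp: dict
    tn: dict
    fn: dict
    n_windows: int

    def for_class(self, c) -> tuple[int, int, int, int]:
        return self.tp[c], self.fp[c], self.tn[c], self.fn[c]


@dataclass
class MetricsReport:
    per_class: dict
    aggregate: dict
    supports: dict
    weighting: str
    retained: int | None = None
    retention_fraction: float | None = None


def confusion(y_true, y_pred, classes) -> ConfusionCounts:
    """Exact one-vs-rest counts for each class."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    class_set = set(classes)
    for lab in set(y_true) | set(y_pred):
        if lab not in class_set:
            raise ValidationError(f"label {lab!r} not in classes {classes}")
    yt = np.asarray(y_true, dtype=object)
    yp = np.asarray(y_pred, dtype=object)
    tp, fp, tn, fn = {}, {}, {}, {}
    for c in classes:
        t = yt == c
        p = yp == c
        tp[c] = int(np.sum(t & p))
        fp[c] = int(np.sum(~t & p))
        fn[c] = int(np.sum(t & ~p))
        tn[c] = int(np.sum(~t & ~p))
    return ConfusionCounts(classes=list(classes), tp=tp, fp=fp, tn=tn, fn=fn,
                           n_windows=len(y_true))


_warned_undefined: set[str] = set()


def _safe_ratio(num: int, den: int, name: str) -> Fraction:
    if den == 0:
        # warn once per metric name per process; repeats go to debug
        if name not in _warned_undefined:
            _warned_undefined.add(name)
            logger.warning("metric %s undefined (0/0); reported as 0", name)
        else:
            logger.debug("metric %s undefined (0/0); reported as 0", name)
        return Fraction(0)
    return Fraction(num, den)


def metrics_from_counts(counts: ConfusionCounts) -> dict:
    """Per-class metrics as exact rationals (converted to float on report).

    sens = TP/(TP+FN); spec = TN/(TN+FP); fpr = FP/(FP+TN);
    fnr = FN/(FN+TP); precision = TP/(TP+FP); f1 = harmonic mean of
    precision and sensitivity.  Exact-rational arithmetic makes the
    identities sens+fnr = 1 and spec+fpr = 1 hold exactly.
    """
    per_class = {}
    for c in counts.classes:
        tp, fp, tn, fn = counts.for_class(c)
        sens = _safe_ratio(tp, tp + fn, f"sensitivity[{c}]")
        spec = _safe_ratio(tn, tn + fp, f"specificity[{c}]")
        fpr = _safe_ratio(fp, fp + tn, f"fpr[{c}]")
        fnr = _safe_ratio(fn, fn + tp, f"fnr[{c}]")
        prec = _safe_ratio(tp, tp + fp, f"precision[{c}]")
        if prec + sens > 0:
            f1 = 2 * prec * sens / (prec + sens)
        else:
            f1 = Fraction(0)
        per_class[c] = {"sensitivity": sens, "specificity": spec, "fpr": fpr,
                        "fnr": fnr, "precision": prec, "f1": f1,
                        "support": tp + fn}
    return per_class


def weighted_macro(per_class: dict, supports: dict) -> MetricsReport:
    """Support-weighted average of per-class metrics."""
    total = sum(supports.values())
    if total <= 0:
        raise ValidationError("supports must not all be zero")
    aggregate = {}
    for m in METRIC_NAMES:
        s = sum(Fraction(supports[c]) * Fraction(per_class[c][m])
                for c in per_class)
        aggregate[m] = float(s / total)
    return MetricsReport(
        per_class={c: {k: (float(v) if k != "support" else int(v))
                       for k, v in d.items()} for c, d in per_class.items()},
        aggregate=aggregate,
        supports={c: int(supports[c]) for c in supports},
        weighting="WEIGHTED_MACRO")


def evaluate_labels(y_true, y_pred, classes) -> MetricsReport:
    """Convenience: confusion -> per-class metrics -> weighted macro."""
    counts = confusion(y_true, y_pred, classes)
    per_class = metrics_from_counts(counts)
    supports = {c: int(per_class[c]["support"]) for c in classes}
    return weighted_macro(per_class, supports)


def qa_filtered_eval(y_true, y_pred, qa_labels, classes,
                     keep: QaClass = QaClass.EXCELLENT,
                     ) -> tuple[MetricsReport, int]:
    """Metrics over windows whose quality label equals ``keep``.

    Returns (report, retained count); raises if nothing is retained.
    """
    y_true, y_pred, qa_labels = list(y_true), list(y_pred), list(qa_labels)
    if not len(y_true) == len(y_pred) == len(qa_labels):
        raise ValidationError("predictions and QA labels must align")
    mask = [q == keep for q in qa_labels]
    retained = int(np.sum(mask))
    if retained == 0:
        raise ValidationError(
            f"no windows with quality {keep.name}; cannot compute a "
            "filtered report")
    yt = [t for t, m in zip(y_true, mask) if m]
    yp = [p for p, m in zip(y_pred, mask) if m]
    report = evaluate_labels(yt, yp, classes)
    report.retained = retained
    report.retention_fraction = retained / len(y_true)
    logger.info("quality filter retained %d/%d windows (%.1f%%)",
                retained, len(y_true), 100 * retained / len(y_true))
    return report, retained


def per_individual_aggregate(y_true, y_pred, subject_ids, classes) -> MetricsReport:
    """Per-subject metrics, then support-weighted across subjects.

    Window counts are the subject supports.  Subjects whose windows contain
    a single true class have undefined one-vs-rest metrics for the absent
    classes; those undefined entries follow the zero convention and are
    excluded via zero support per class.
    """
    df = pd.DataFrame({"true": list(y_true), "pred": list(y_pred),
                       "subject": list(subject_ids)})
    if df.empty:
        raise ValidationError("no predictions to aggregate")
    agg_num = {m: Fraction(0) for m in METRIC_NAMES}
    total_windows = 0
    per_subject = {}
    for subject, grp in df.groupby("subject", sort=True):
        counts = confusion(grp["true"], grp["pred"], classes)
        per_class = metrics_from_counts(counts)
        supports = {c: int(per_class[c]["support"]) for c in classes}
        stotal = sum(supports.values())
        subj_metrics = {}
        for m in METRIC_NAMES:
            s = sum(Fraction(supports[c]) * Fraction(per_class[c][m])
                    for c in classes)
            subj_metrics[m] = s / stotal
        per_subject[subject] = {m: float(v) for m, v in subj_metrics.items()}
        w = len(grp)
        for m in METRIC_NAMES:
            agg_num[m] += w * subj_metrics[m]
        total_windows += w
    aggregate = {m: float(agg_num[m] / total_windows) for m in METRIC_NAMES}
    return MetricsReport(per_class=per_subject, aggregate=aggregate,
                         supports={s: int((df["subject"] == s).sum())
                                   for s in per_subject},
                         weighting="PER_INDIVIDUAL")


def report_to_dict(report: MetricsReport) -> dict:
    out = {
        "weighting": report.weighting,
        "aggregate": report.aggregate,
        "per_class": {str(k): v for k, v in report.per_class.items()},
        "supports": {str(k): v for k, v in report.supports.items()},
    }
    if report.retained is not None:
        out["retained"] = report.retained
        out["retention_fraction"] = report.retention_fraction
    return out
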