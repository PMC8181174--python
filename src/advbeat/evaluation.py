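"""Confusion matrices, per-class Sen/Pre/F1, overall Acc and pat_F1.

Per-class rates are one-vs-rest on the 5 AAMI classes:
Sen = TP/(TP+FN), Pre = TP/(TP+FP), F1 = 2*Pre*Sen/(Pre+Sen); overall
accuracy is trace/total (the fraction of correctly classified beats;
the one-vs-rest accuracy (TP+TN)/total is also reported per class).
pat_F1 = (F1_S + F1_V)/2 summarises performance on the two pathological
classes, which the overall accuracy — dominated by class N — hides.
0/0 cases (a class absent from both truth and predictions) are reported
as 0 and flagged undefined; the record-level table prints them as "—".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mitdb import AAMI_CLASSES, N_CLASSES


@dataclass(frozen=True)
class ClassMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    f1: float
    ovr_accuracy: float
    undefined: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    accuracy: float
    pat_f1: float
    confusion: np.ndarray
    n_beats: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "pat_f1": self.pat_f1,
            "n_beats": self.n_beats,
            "confusion": self.confusion.tolist(),
            "per_class": {
                c: {
                    "TP": m.tp, "TN": m.tn, "FP": m.fp, "FN": m.fn,
                    "sensitivity": m.sensitivity, "precision": m.precision,
                    "f1": m.f1, "ovr_accuracy": m.ovr_accuracy,
                    "undefined": sorted(m.undefined),
                }
                for c, m in self.per_class.items()
            },
        }


def confusion(true_labels, predicted_labels, n_classes: int = N_CLASSES) -> np.ndarray:
    """Exact count matrix, rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted labels differ in length")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise ValueError("labels out of range")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (t, p), 1)
    return m


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def per_class_metrics(m: np.ndarray) -> MetricsReport:
    """One-vs-rest metrics for every class plus overall Acc and pat_F1."""
    m = np.asarray(m, dtype=np.int64)
    total = int(m.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    per: dict[str, ClassMetrics] = {}
    for k, name in enumerate(AAMI_CLASSES[: m.shape[0]]):
        tp = int(m[k, k])
        fn = int(m[k].sum() - tp)
        fp = int(m[:, k].sum() - tp)
        tn = total - tp - fn - fp
        undef = set()
        sen, u = _safe_div(tp, tp + fn)
        if u:
            undef.add("sensitivity")
        pre, u = _safe_div(tp, tp + fp)
        if u:
            undef.add("precision")
        f1, u = _safe_div(2 * pre * sen, pre + sen)
        if u:
            undef.add("f1")
        per[name] = ClassMetrics(tp, tn, fp, fn, sen, pre, f1,
                                 (tp + tn) / total, frozenset(undef))
    acc = float(np.trace(m)) / total
    return MetricsReport(per, acc, pat_f1(per["S"].f1, per["V"].f1), m, total)


def pat_f1(f1_s: float, f1_v: float) -> float:
    """Mean F1 of the pathological classes S and V (fractions or percent,
    consistently)."""
    return (f1_s + f1_v) / 2.0


def record_level_report(
    record_ids, true_labels, predicted_labels
) -> pd.DataFrame:
    """Per-record beat counts, per-class Sen/Pre and Acc, plus a pooled
    "Total" row. Rates for classes absent from a record are NaN (printed
    as "—" by `format_record_report`)."""
    rid = np.asarray(record_ids)
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if not (len(rid) == len(t) == len(p)):
        raise ValueError("record_ids, labels and predictions must align")
    rows = []

    def one(name: str, mask: np.ndarray) -> dict:
        rep = per_class_metrics(confusion(t[mask], p[mask]))
        row: dict = {"record": name, "all": int(mask.sum())}
        for c in ("N", "S", "V"):
            cm = rep.per_class[c]
            n_true = cm.tp + cm.fn
            row[f"n_{c}"] = n_true
            row[f"sen_{c}"] = np.nan if "sensitivity" in cm.undefined else cm.sensitivity
            row[f"pre_{c}"] = (np.nan if ("precision" in cm.undefined
                                          and n_true == 0) else cm.precision)
        row["acc"] = rep.accuracy
        return row

    for name in sorted(np.unique(rid)):
        rows.append(one(str(name), rid == name))
    rows.append(one("Total", np.ones(len(t), dtype=bool)))
    return pd.DataFrame(rows)


def format_record_report(df: pd.DataFrame) -> pd.DataFrame:
    """Percent formatting with one decimal; NaN rates become em dashes."""
    out = df.copy()
    for col in out.columns:
        if col.startswith(("sen_", "pre_")) or col == "acc":
            out[col] = [
                "—" if (isinstance(v, float) and np.isnan(v)) else f"{100 * v:.1f}%"
                for v in out[col]
            ]
    return out
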