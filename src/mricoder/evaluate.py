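"""Multi-output evaluation: label descriptors, micro/macro metrics,
subset accuracy, and the coding-economics analyses.

Counting convention for count-valued labels (code charged 0..K_j times
per exam): each charged unit is a slot.  With truth count t and
predicted count p for a code, TP = min(t, p), FP = max(0, p - t),
FN = max(0, t - p), and TN fills the remaining K_j - max(t, p) slots.
Precision, recall and F1 ignore TN, so the slot convention for TN is
inert but kept for completeness.

Micro averaging pools TP/FP/FN across codes before applying the binary
metric; macro averaging computes the metric per code and averages the
per-code values with equal weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .labels import CodeDefinition, Labelset

__all__ = [
    "LabelConfusion",
    "EvalReport",
    "label_cardinality",
    "label_density",
    "label_diversity",
    "count_confusion",
    "aggregate_confusion",
    "micro_metrics",
    "macro_metrics",
    "subset_accuracy",
    "prevalence_f1_correlation",
    "reimbursement_delta",
    "paired_comparison",
    "evaluate_predictions",
]


@dataclass
class LabelConfusion:
    """Per-code unit-slot confusion counts."""

    tp: dict = field(default_factory=dict)
    fp: dict = field(default_factory=dict)
    fn: dict = field(default_factory=dict)
    tn: dict = field(default_factory=dict)

    def codes(self):
        return sorted(set(self.tp) | set(self.fp) | set(self.fn) | set(self.tn))

    def add(self, other: "LabelConfusion") -> "LabelConfusion":
        for attr in ("tp", "fp", "fn", "tn"):
            mine = getattr(self, attr)
            for code, n in getattr(other, attr).items():
                mine[code] = mine.get(code, 0) + n
        return self


def label_cardinality(labelsets: Sequence[Labelset]) -> float:
    """Mean number of charged code units per exam (a code charged twice
    contributes two)."""
    if not labelsets:
        raise ValueError("label_cardinality needs a nonempty dataset")
    return sum(ls.total_units for ls in labelsets) / len(labelsets)


def label_density(labelsets: Sequence[Labelset], n_codes: int) -> float:
    """Cardinality normalized by the number of possible codes.

    The normalizing code count is an explicit argument: depending on
    whether pruned codes count as "possible", different denominators are
    defensible, so the caller decides.
    """
    if n_codes < 1:
        raise ValueError("n_codes must be >= 1")
    if not labelsets:
        return 0.0
    return label_cardinality(labelsets) / n_codes


def label_diversity(labelsets: Sequence[Labelset]) -> int:
    """Number of distinct labelsets (full code->count maps)."""
    return len({ls for ls in labelsets})


def count_confusion(
    truth: Labelset,
    pred: Labelset,
    code_defs: Mapping[str, CodeDefinition],
) -> LabelConfusion:
    """Unit-slot confusion of one exam over the given code space."""
    conf = LabelConfusion()
    for code, d in code_defs.items():
        t = truth.get(code, 0)
        p = pred.get(code, 0)
        conf.tp[code] = min(t, p)
        conf.fp[code] = max(0, p - t)
        conf.fn[code] = max(0, t - p)
        conf.tn[code] = max(0, d.max_count - max(t, p))
    return conf


def aggregate_confusion(
    truths: Sequence[Labelset],
    preds: Sequence[Labelset],
    code_defs: Mapping[str, CodeDefinition],
) -> LabelConfusion:
    if len(truths) != len(preds):
        raise ValueError("truth and prediction lists differ in length")
    total = LabelConfusion()
    for t, p in zip(truths, preds):
        total.add(count_confusion(t, p, code_defs))
    return total


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    if tp + fp == 0:
        warnings.warn("precision undefined (no predicted units); reporting 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("recall undefined (no true units); reporting 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def micro_metrics(conf: LabelConfusion) -> tuple[float, float, float]:
    """Pooled (micro-averaged) precision, recall, F1."""
    tp = sum(conf.tp.values())
    fp = sum(conf.fp.values())
    fn = sum(conf.fn.values())
    return _prf(tp, fp, fn)


def macro_metrics(conf: LabelConfusion) -> tuple[float, float, float]:
    """Equal-weight per-code average of precision, recall, F1."""
    codes = conf.codes()
    if not codes:
        raise ValueError("empty confusion")
    ps, rs, fs = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for code in codes:
            p, r, f = _prf(
                conf.tp.get(code, 0), conf.fp.get(code, 0), conf.fn.get(code, 0)
            )
            ps.append(p)
            rs.append(r)
            fs.append(f)
    return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(fs))


def subset_accuracy(truths: Sequence[Labelset], preds: Sequence[Labelset]) -> float:
    """Fraction of exams whose entire predicted labelset matches exactly
    (every code, every count)."""
    if len(truths) != len(preds):
        raise ValueError("truth and prediction lists differ in length")
    if not truths:
        raise ValueError("subset_accuracy needs a nonempty dataset")
    hits = sum(1 for t, p in zip(truths, preds) if t == p)
    return hits / len(truths)


def per_code_table(
    conf: LabelConfusion,
    truths: Sequence[Labelset],
) -> pd.DataFrame:
    """Per-code prevalence (fraction of exams charging the code) and F1."""
    m = len(truths)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for code in conf.codes():
            p, r, f = _prf(
                conf.tp.get(code, 0), conf.fp.get(code, 0), conf.fn.get(code, 0)
            )
            prevalence = sum(1 for t in truths if t.get(code, 0) > 0) / m if m else 0.0
            rows.append(
                {"code_id": code, "prevalence": prevalence,
                 "precision": p, "recall": r, "f1": f}
            )
    return pd.DataFrame(rows).set_index("code_id")


def prevalence_f1_correlation(
    table: pd.DataFrame, imperfect_only: bool = True
) -> tuple[float, float]:
    """Spearman rank correlation between code prevalence and F1.

    Restricted by default to codes with imperfect F1 (< 1.0): a strong
    positive correlation indicates performance is limited by training
    prevalence and would improve with more data.
    """
    sub = table[table["f1"] < 1.0] if imperfect_only else table
    if len(sub) < 2:
        raise ValueError("need at least two codes for a rank correlation")
    res = stats.spearmanr(sub["prevalence"], sub["f1"])
    return float(res.statistic), float(res.pvalue)


def reimbursement_delta(
    truths: Sequence[Labelset],
    coded: Sequence[Labelset],
    code_defs: Mapping[str, CodeDefinition],
) -> tuple[float, float]:
    """(undercoding_loss_frac, overcoding_excess_frac) in tariff points.

    Undercoding: points of truth units the coder missed, as a fraction
    of total truth points (lost reimbursement).  Overcoding: points of
    units the coder charged beyond the truth, same denominator (falsely
    charged reimbursement).
    """
    total = 0.0
    missed = 0.0
    excess = 0.0
    for t, c in zip(truths, coded):
        for code in set(t) | set(c):
            if code not in code_defs:
                raise KeyError(f"code {code} has no definition")
            pts = code_defs[code].tariff_points
            tn = t.get(code, 0)
            cn = c.get(code, 0)
            total += pts * tn
            if cn < tn:
                missed += pts * (tn - cn)
            elif cn > tn:
                excess += pts * (cn - tn)
    if total == 0:
        return 0.0, 0.0
    return missed / total, excess / total


def paired_comparison(
    truths: Sequence[Labelset],
    pred_auto: Sequence[Labelset],
    pred_manual: Sequence[Labelset],
) -> dict:
    """Exam-wise exact-match comparison of two coders against truth.

    Returns the fractions both_correct / auto_only / manual_only /
    neither (they partition the test set).
    """
    if not (len(truths) == len(pred_auto) == len(pred_manual)):
        raise ValueError("all three lists must have equal length")
    m = len(truths)
    if m == 0:
        raise ValueError("empty dataset")
    counts = {"both_correct": 0, "auto_only": 0, "manual_only": 0, "neither": 0}
    for t, a, man in zip(truths, pred_auto, pred_manual):
        a_ok = t == a
        m_ok = t == man
        if a_ok and m_ok:
            counts["both_correct"] += 1
        elif a_ok:
            counts["auto_only"] += 1
        elif m_ok:
            counts["manual_only"] += 1
        else:
            counts["neither"] += 1
    return {k: v / m for k, v in counts.items()}


@dataclass
class EvalReport:
    """Evaluation summary for one prediction run."""

    micro_precision: float
    micro_recall: float
    micro_f1: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    subset_accuracy: float
    label_cardinality: float
    label_density: float
    label_diversity: int
    n_exams: int
    per_code: pd.DataFrame = field(repr=False, default=None)

    def to_json_obj(self) -> dict:
        obj = {
            "micro_precision": round(self.micro_precision, 10),
            "micro_recall": round(self.micro_recall, 10),
            "micro_f1": round(self.micro_f1, 10),
            "macro_precision": round(self.macro_precision, 10),
            "macro_recall": round(self.macro_recall, 10),
            "macro_f1": round(self.macro_f1, 10),
            "subset_accuracy": round(self.subset_accuracy, 10),
            "label_cardinality": round(self.label_cardinality, 10),
            "label_density": round(self.label_density, 10),
            "label_diversity": self.label_diversity,
            "n_exams": self.n_exams,
        }
        return obj

    def summary(self) -> str:
        lines = [
            "Evaluation report",
            "-----------------",
            f"exams evaluated        {self.n_exams}",
            f"micro precision        {self.micro_precision:.3f}",
            f"micro recall           {self.micro_recall:.3f}",
            f"micro F1               {self.micro_f1:.3f}",
            f"macro F1               {self.macro_f1:.3f}",
            f"subset accuracy        {self.subset_accuracy:.3f}",
            f"label cardinality      {self.label_cardinality:.2f}",
            f"label density          {self.label_density:.3f}",
            f"label diversity        {self.label_diversity}",
        ]
        return "\n".join(lines)


def evaluate_predictions(
    truths: Sequence[Labelset],
    preds: Sequence[Labelset],
    code_defs: Mapping[str, CodeDefinition],
    n_codes: int | None = None,
) -> EvalReport:
    """Full report of metrics over predictions.

    Cardinality/density/diversity describe the *predicted* labelsets
    (so drifts in predicted code volume are visible next to the truth's
    descriptors).
    """
    conf = aggregate_confusion(truths, preds, code_defs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mi_p, mi_r, mi_f = micro_metrics(conf)
    ma_p, ma_r, ma_f = macro_metrics(conf)
    n_codes = n_codes if n_codes is not None else len(code_defs)
    return EvalReport(
        micro_precision=mi_p,
        micro_recall=mi_r,
        micro_f1=mi_f,
        macro_precision=ma_p,
        macro_recall=ma_r,
        macro_f1=ma_f,
        subset_accuracy=subset_accuracy(truths, preds),
        label_cardinality=label_cardinality(list(preds)),
        label_density=label_density(list(preds), n_codes),
        label_diversity=label_diversity(list(preds)),
        n_exams=len(truths),
        per_code=per_code_table(conf, truths),
    )
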