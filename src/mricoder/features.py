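"""Exam-level feature extraction.

Each exam becomes a fixed-length numeric vector: counts of executed
standardized sequence names over a vocabulary fitted on training exams,
timing features (total acquisition time ACQ, user-operating/idle time
UOP, and their ratio — the UOP-to-ACQ ratio separates MR-guided
biopsies, where acquisition is a small share of the exam, from
diagnostic exams), scanner-table movement features, contrast flag,
approximate patient age and coarse coil-group indicators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd

from .logmodel import ExamInstance
from .standardize import RuleTable, standardize_sequence

__all__ = [
    "COIL_GROUPS",
    "Vocabulary",
    "compute_timing",
    "table_features",
    "fit_vocabulary",
    "featurize",
    "feature_matrix",
]

#: Coarse coil groups keyed by substrings of coil ids; keeps feature
#: dimensionality stable across scanners with different coil inventories.
COIL_GROUPS: dict[str, tuple] = {
    "head": ("head", "neck20", "hn"),
    "spine": ("spine",),
    "body": ("body", "abdomen", "torso"),
    "extremity": ("flex", "knee", "shoulder", "extremity", "foot", "hand"),
    "breast": ("breast",),
}

OVERFLOW_BIN = "__unseen__"


@dataclass(frozen=True)
class Vocabulary:
    """Fitted standardized-name vocabulary (training exams only)."""

    names: tuple
    rules: RuleTable = RuleTable()

    def to_json(self, stream: IO[str]) -> None:
        json.dump({"names": list(self.names)}, stream, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, stream: IO[str], rules: RuleTable = RuleTable()) -> "Vocabulary":
        data = json.load(stream)
        return cls(names=tuple(data["names"]), rules=rules)


def compute_timing(exam: ExamInstance) -> tuple[float, float, float]:
    """(acq_s, uop_s, uop_acq_ratio) for one exam.

    ACQ is the summed sequence execution time (value-added time); UOP is
    the remainder of the exam span (idle, non-value-added time), clipped
    at zero.  An aborted exam (no sequences) has ACQ 0; the ratio is
    then reported as 0 and the aborted flag carries the signal instead
    of an infinity.
    """
    acq = sum(s.duration_s for s in exam.sequences)
    span = exam.span_s
    uop = max(0.0, span - acq)
    ratio = uop / acq if acq > 0 else 0.0
    return acq, uop, ratio


def table_features(exam: ExamInstance) -> tuple[float, float, float, float]:
    """(total_movement_mm, min_mm, max_mm, mean_step_mm).

    Total movement sums absolute position deltas over the time-ordered
    table trace; mean step averages the absolute position change between
    consecutive sequences' start positions.  An empty trace yields zeros.
    """
    positions = [p for _, p in exam.table_positions]
    if not positions:
        return 0.0, 0.0, 0.0, 0.0
    arr = np.asarray(positions, dtype=float)
    total = float(np.abs(np.diff(arr)).sum()) if len(arr) > 1 else 0.0
    seq_pos = [s.table_position_mm for s in exam.sequences]
    if len(seq_pos) > 1:
        mean_step = float(np.mean(np.abs(np.diff(np.asarray(seq_pos, dtype=float)))))
    else:
        mean_step = 0.0
    return total, float(arr.min()), float(arr.max()), mean_step


def _coil_indicators(exam: ExamInstance) -> dict:
    groups = {g: 0 for g in COIL_GROUPS}
    groups["other"] = 0
    for seq in exam.sequences:
        for coil in seq.coil_ids:
            low = coil.lower()
            hit = False
            for group, keys in COIL_GROUPS.items():
                if any(k in low for k in keys):
                    groups[group] = 1
                    hit = True
            if not hit:
                groups["other"] = 1
    return groups


def fit_vocabulary(
    train_exams: Sequence[ExamInstance], rules: RuleTable = RuleTable()
) -> Vocabulary:
    """Collect the standardized-name vocabulary from training exams."""
    names = set()
    for exam in train_exams:
        for seq in exam.sequences:
            names.add(standardize_sequence(seq, rules).rendered)
    return Vocabulary(names=tuple(sorted(names)), rules=rules)


def featurize(exam: ExamInstance, vocabulary: Vocabulary) -> dict:
    """One exam -> ordered feature dict (constant keys for a vocabulary).

    Standardized names outside the fitted vocabulary are tallied in a
    reserved overflow bin so the vector length never changes between
    fit and prediction time.
    """
    counts = {f"seq:{name}": 0 for name in vocabulary.names}
    counts[f"seq:{OVERFLOW_BIN}"] = 0
    for seq in exam.sequences:
        name = standardize_sequence(seq, vocabulary.rules).rendered
        key = f"seq:{name}"
        if key in counts:
            counts[key] += 1
        else:
            counts[f"seq:{OVERFLOW_BIN}"] += 1
    acq, uop, ratio = compute_timing(exam)
    total, tmin, tmax, step = table_features(exam)
    feats = dict(counts)
    feats.update(
        {
            "acq_s": acq,
            "uop_s": uop,
            "uop_acq_ratio": ratio,
            "aborted": 1 if exam.aborted else 0,
            "table_total_movement_mm": total,
            "table_min_mm": tmin,
            "table_max_mm": tmax,
            "table_mean_step_mm": step,
            "contrast_given": 1 if exam.contrast_given else 0,
            "approximate_age_years": float(exam.approximate_age_years),
            "n_sequences": len(exam.sequences),
        }
    )
    for group, flag in _coil_indicators(exam).items():
        feats[f"coil:{group}"] = flag
    return feats


def feature_matrix(
    exams: Sequence[ExamInstance], vocabulary: Vocabulary
) -> pd.DataFrame:
    """Feature DataFrame, one row per exam, indexed by exam id.

    No scaling happens here; standardization is owned by the model
    pipeline so cross-validation folds fit it on training folds only.
    """
    rows = [featurize(e, vocabulary) for e in exams]
    index = [e.exam_id for e in exams]
    df = pd.DataFrame(rows, index=index)
    return df.astype(float)
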