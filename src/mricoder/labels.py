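"""Count-valued billing labelsets and the target-data cleaning rules.

A labelset maps billing-code ids to charged counts (codes not listed are
implicitly 0).  Cleaning applies, in fixed order: exclusion of
non-imaging-related codes (not predictable from modality logs), capping
each code at its maximum chargeable count per exam, and pruning codes
too rare in the training data to be learnable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Labelset",
    "CodeDefinition",
    "Correction",
    "exclude_nonimaging",
    "enforce_max_counts",
    "prune_rare_codes",
    "restrict_labelset",
    "removed_reimbursement_share",
    "clean_labelsets",
    "default_code_definitions",
    "read_code_definitions",
    "write_code_definitions",
    "write_corrections",
]


class Labelset(Mapping):
    """Immutable map code_id -> positive count; absent codes count 0."""

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean = {}
        for code, n in (counts or {}).items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for code {code}")
            if n > 0:
                clean[str(code)] = n
        self._counts = dict(sorted(clean.items()))

    def __getitem__(self, code: str) -> int:
        return self._counts.get(code, 0)

    def get(self, code: str, default: int = 0) -> int:
        return self._counts.get(code, default)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self):
        return len(self._counts)

    def __contains__(self, code) -> bool:
        return code in self._counts

    def __eq__(self, other) -> bool:
        if isinstance(other, Labelset):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self):
        return hash(tuple(self._counts.items()))

    def __repr__(self):
        return f"Labelset({self._counts})"

    @property
    def total_units(self) -> int:
        return sum(self._counts.values())

    def as_dict(self) -> dict:
        return dict(self._counts)


@dataclass(frozen=True)
class CodeDefinition:
    """Per-code metadata: max chargeable count K_j, flags, tariff points."""

    code_id: str
    max_count: int = 1
    imaging_related: bool = True
    tariff_points: float = 0.0
    auxiliary: bool = False

    def __post_init__(self):
        if self.max_count < 1:
            raise ValueError("max_count must be >= 1")


@dataclass(frozen=True)
class Correction:
    exam_id: str
    code_id: str
    before: int
    after: int
    rule: str


def _check_known(labelset: Labelset, code_defs: Mapping[str, CodeDefinition]):
    unknown = [c for c in labelset if c not in code_defs]
    if unknown:
        raise KeyError(f"codes without a definition: {sorted(unknown)}")


def exclude_nonimaging(
    labelset: Labelset, code_defs: Mapping[str, CodeDefinition]
) -> Labelset:
    """Drop codes flagged imaging_related=False (e.g. establishing
    intravenous access); such services leave no trace in the scanner log."""
    _check_known(labelset, code_defs)
    return Labelset(
        {c: n for c, n in labelset.items() if code_defs[c].imaging_related}
    )


def enforce_max_counts(
    labelset: Labelset,
    code_defs: Mapping[str, CodeDefinition],
    exam_id: str = "",
) -> tuple[Labelset, list]:
    """Cap each code at its allowed per-exam maximum K_j.

    Returns the corrected labelset and a report with one entry per
    truncation (before/after counts).
    """
    _check_known(labelset, code_defs)
    corrections = []
    out = {}
    for code, n in labelset.items():
        cap = code_defs[code].max_count
        if n > cap:
            corrections.append(Correction(exam_id, code, n, cap, "max_count"))
            n = cap
        out[code] = n
    return Labelset(out), corrections


def prune_rare_codes(
    train_labelsets: Sequence[Labelset], min_instances: int = 20
) -> tuple[list, list]:
    """Split codes into (kept, removed) by training-set support.

    A code is kept iff it appears (count >= 1) in at least
    ``min_instances`` training exams; infrequent codes cannot be learned
    reliably and are discarded from the label space.  Must be fitted on
    training labelsets only.
    """
    if min_instances < 1:
        raise ValueError("min_instances must be >= 1")
    support: dict[str, int] = {}
    for ls in train_labelsets:
        for code in ls:
            support[code] = support.get(code, 0) + 1
    kept = sorted(c for c, n in support.items() if n >= min_instances)
    removed = sorted(c for c, n in support.items() if n < min_instances)
    return kept, removed


def restrict_labelset(labelset: Labelset, kept_codes: Iterable[str]) -> Labelset:
    keep = set(kept_codes)
    return Labelset({c: n for c, n in labelset.items() if c in keep})


def removed_reimbursement_share(
    removed_codes: Iterable[str],
    train_labelsets: Sequence[Labelset],
    code_defs: Mapping[str, CodeDefinition],
) -> float:
    """Tariff-point share of the pruned codes in the training corpus."""
    removed = set(removed_codes)
    lost = 0.0
    total = 0.0
    for ls in train_labelsets:
        for code, n in ls.items():
            if code not in code_defs:
                raise KeyError(f"code {code} has no definition")
            pts = code_defs[code].tariff_points * n
            total += pts
            if code in removed:
                lost += pts
    return lost / total if total > 0 else 0.0


def clean_labelsets(
    labelsets: Sequence[Labelset],
    code_defs: Mapping[str, CodeDefinition],
    min_instances: int = 20,
    exam_ids: Sequence[str] | None = None,
    apply_corrections: bool = True,
) -> dict:
    """Full cleaning pipeline: exclude non-imaging -> cap counts -> prune.

    Returns a dict with ``labelsets`` (cleaned, same order), ``kept``,
    ``removed``, ``corrections`` and ``removed_points_share``.
    Idempotent: running the pipeline on its own output is a no-op.
    """
    ids = exam_ids or [str(i) for i in range(len(labelsets))]
    staged = []
    corrections: list[Correction] = []
    for exam_id, ls in zip(ids, labelsets):
        ls = exclude_nonimaging(ls, code_defs)
        if apply_corrections:
            ls, corr = enforce_max_counts(ls, code_defs, exam_id=exam_id)
            corrections.extend(corr)
        staged.append(ls)
    kept, removed = prune_rare_codes(staged, min_instances=min_instances)
    share = removed_reimbursement_share(removed, staged, code_defs)
    cleaned = [restrict_labelset(ls, kept) for ls in staged]
    return {
        "labelsets": cleaned,
        "kept": kept,
        "removed": removed,
        "corrections": corrections,
        "removed_points_share": share,
    }


# ---------------------------------------------------------------------------
# Code catalogue


def default_code_definitions() -> dict:
    """Synthetic billing-code catalogue.

    Structural stand-in for a fee-for-service tariff: 22 imaging-related
    codes of which six may be charged twice and two more than twice per
    exam, plus three non-imaging codes (intravenous access, narcosis
    surcharge, physician service in absence) that billing data contain
    but modality logs cannot predict.  Tariff points are plausible
    magnitudes, not real tariff values.
    """
    defs = [
        # main procedure codes (K=1)
        CodeDefinition("39.0100", 1, True, 480.0),           # head MRI
        CodeDefinition("39.0200", 1, True, 460.0),           # neck soft tissue
        CodeDefinition("39.0600", 1, True, 500.0),           # abdomen
        CodeDefinition("39.0650", 1, True, 480.0),           # thorax
        CodeDefinition("39.0700", 1, True, 470.0),           # pelvis
        CodeDefinition("39.0800", 1, True, 620.0),           # whole body
        CodeDefinition("39.0900", 1, True, 560.0),           # cardiac
        CodeDefinition("39.0950", 1, True, 450.0),           # breast
        CodeDefinition("39.1000", 1, True, 540.0),           # MR-guided biopsy
        CodeDefinition("39.1100", 1, True, 430.0),           # intracranial vessels
        CodeDefinition("39.1200", 1, True, 520.0),           # functional imaging
        CodeDefinition("39.0460", 1, True, 420.0),           # extremity soft tissue
        CodeDefinition("39.5050", 1, True, 120.0, auxiliary=True),  # contrast admin
        CodeDefinition("39.5070", 1, True, 90.0, auxiliary=True),   # spectroscopy add-on
        # codes chargeable twice (K=2)
        CodeDefinition("39.0400", 2, True, 440.0),           # joint / extremity
        CodeDefinition("39.0450", 2, True, 440.0),           # hip
        CodeDefinition("39.0500", 2, True, 440.0),           # knee
        CodeDefinition("39.0410", 2, True, 150.0, auxiliary=True),  # arthrogram
        CodeDefinition("39.5020", 2, True, 140.0, auxiliary=True),  # angiography add-on
        CodeDefinition("39.5060", 2, True, 80.0, auxiliary=True),   # 3D reconstruction
        # codes chargeable more than twice (K=4)
        CodeDefinition("39.0300", 4, True, 430.0),           # spine, per segment
        CodeDefinition("39.5010", 4, True, 100.0, auxiliary=True),  # additional series
        # non-imaging-related codes (excluded before training)
        CodeDefinition("00.0510", 1, False, 35.0),           # intravenous access
        CodeDefinition("00.0520", 1, False, 110.0),          # narcotized patient surcharge
        CodeDefinition("00.0610", 1, False, 60.0),           # physician service in absence
    ]
    return {d.code_id: d for d in defs}


def read_code_definitions(stream: IO[str]) -> dict:
    """Load a code catalogue from YAML: list of CodeDefinition mappings."""
    data = yaml.safe_load(stream)
    defs = {}
    for row in data:
        d = CodeDefinition(
            code_id=str(row["code_id"]),
            max_count=int(row.get("max_count", 1)),
            imaging_related=bool(row.get("imaging_related", True)),
            tariff_points=float(row.get("tariff_points", 0.0)),
            auxiliary=bool(row.get("auxiliary", False)),
        )
        defs[d.code_id] = d
    return defs


def write_code_definitions(code_defs: Mapping[str, CodeDefinition], stream: IO[str]):
    rows = [
        {
            "code_id": d.code_id,
            "max_count": d.max_count,
            "imaging_related": d.imaging_related,
            "tariff_points": d.tariff_points,
            "auxiliary": d.auxiliary,
        }
        for d in code_defs.values()
    ]
    yaml.safe_dump(rows, stream, sort_keys=True)


def write_corrections(corrections: Sequence[Correction], stream: IO[str]):
    writer = csv.writer(stream)
    writer.writerow(["exam_id", "code_id", "before", "after", "rule"])
    for c in corrections:
        writer.writerow([c.exam_id, c.code_id, c.before, c.after, c.rule])
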