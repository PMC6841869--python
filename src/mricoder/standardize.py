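"""Heuristic MR sequence-name standardization.

User-editable protocol names ("t1_tse_tra_fs" vs "t1_tse_fs_tra", body
regions, slice thickness, post-contrast delays ...) make raw sequence
names incomparable across exams and scanners.  The standardizer derives
a canonical name from the acquisition parameters themselves (TR, TE,
TI, b-values, technique, orientation), so two executions of the same
physical sequence always map to the same token string regardless of how
the raw name was decorated.

Token order is fixed: weighting, technique, fat saturation, orientation,
breath hold — e.g. ``t2 haste fs tra bh``.  Diffusion EPI is rendered as
the fused token ``ep2d_diff`` with no separate weighting token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .logmodel import SequenceRecord

__all__ = [
    "RuleTable",
    "StandardizedName",
    "derive_weighting",
    "standardize_sequence",
    "vocabulary_stats",
]


@dataclass(frozen=True)
class RuleTable:
    """Weighting thresholds and technique vocabulary, all configurable.

    Defaults suit 1.5-3 T clinical protocols; thresholds are in ms.
    """

    t1_tr_max_ms: float = 800.0
    t1_te_max_ms: float = 30.0
    t2_tr_min_ms: float = 2000.0
    t2_te_min_ms: float = 60.0
    pd_tr_min_ms: float = 2000.0
    pd_te_max_ms: float = 30.0
    flair_ti_band_ms: tuple = (1800.0, 3000.0)
    stir_ti_band_ms: tuple = (100.0, 250.0)
    # techniques whose fused diffusion token retains the underscore
    diffusion_suffix: str = "_diff"
    technique_keywords: tuple = (
        "ep2d", "haste", "vibe", "trufi", "tirm", "tse", "gre", "se",
    )

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "RuleTable":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(cfg) - known
        if bad:
            raise KeyError(f"unknown rule-table keys: {sorted(bad)}")
        coerced = {}
        for k, v in cfg.items():
            coerced[k] = tuple(v) if isinstance(v, list) else v
        return cls(**coerced)


@dataclass(frozen=True)
class StandardizedName:
    """Ordered canonical tokens and their rendered single-space form."""

    tokens: tuple

    @property
    def rendered(self) -> str:
        return " ".join(self.tokens)

    def __str__(self) -> str:
        return self.rendered


def derive_weighting(seq: SequenceRecord, rules: RuleTable = RuleTable()) -> str:
    """Derive the weighting token from acquisition parameters.

    Returns one of ``t1, t2, pd, flair, stir, diff, none``.  Inversion
    recovery bands take precedence over plain TR/TE rules; diffusion
    (any b-values recorded) takes precedence over everything.
    """
    if seq.tr_ms <= 0 or seq.te_ms <= 0:
        raise ValueError(
            f"sequence {seq.raw_name!r}: TR and TE must be positive"
        )
    if seq.b_values:
        return "diff"
    if seq.ti_ms is not None:
        lo, hi = rules.flair_ti_band_ms
        if lo <= seq.ti_ms <= hi:
            return "flair"
        lo, hi = rules.stir_ti_band_ms
        if lo <= seq.ti_ms <= hi:
            return "stir"
    if seq.tr_ms < rules.t1_tr_max_ms and seq.te_ms < rules.t1_te_max_ms:
        return "t1"
    if seq.tr_ms >= rules.t2_tr_min_ms and seq.te_ms >= rules.t2_te_min_ms:
        return "t2"
    if seq.tr_ms >= rules.pd_tr_min_ms and seq.te_ms < rules.pd_te_max_ms:
        return "pd"
    return "none"


def _technique_token(seq: SequenceRecord, rules: RuleTable) -> str:
    if seq.technique != "other":
        return seq.technique
    # Last resort: the structured technique field is unreliable at some
    # sites, so scan the raw name for a known technique substring.
    raw = seq.raw_name.lower()
    for kw in rules.technique_keywords:
        if kw in raw.split("_") or kw in raw:
            return kw
    return "other"


def _orientation_token(seq: SequenceRecord) -> str:
    # Oblique slabs render as the dominant axis; without angulation info
    # in the log the tie-break is transverse.
    if seq.orientation == "oblique":
        return "tra"
    return seq.orientation


def standardize_sequence(
    seq: SequenceRecord, rules: RuleTable = RuleTable()
) -> StandardizedName:
    """Map a sequence record to its canonical name.

    Only intrinsic properties appear (weighting, technique, fat
    saturation, orientation, breath hold); site-specific decoration in
    the raw name (body region, slice thickness, post-contrast delay) is
    never carried over.  The raw name is consulted only as a technique
    fallback when the structured technique field is unusable.
    """
    weighting = derive_weighting(seq, rules)
    technique = _technique_token(seq, rules)
    tokens: list[str] = []
    if weighting == "diff":
        # Fused diffusion token, underscore retained: "ep2d_diff".
        tokens.append(f"{technique}{rules.diffusion_suffix}")
    else:
        if weighting != "none":
            tokens.append(weighting)
        tokens.append(technique)
        if seq.fat_saturation:
            tokens.append("fs")
    tokens.append(_orientation_token(seq))
    if weighting != "diff" and seq.breath_hold:
        tokens.append("bh")
    return StandardizedName(tokens=tuple(t.lower() for t in tokens))


def vocabulary_stats(
    sequences: Sequence[SequenceRecord], rules: RuleTable = RuleTable()
) -> tuple[int, int, float]:
    """(n_raw_unique, n_standardized_unique, reduction_fraction).

    The reduction fraction 1 - n_std/n_raw measures how much site
    decoration the standardizer collapses.
    """
    if not sequences:
        raise ValueError("vocabulary_stats needs a nonempty sequence list")
    raw = {s.raw_name for s in sequences}
    std = {standardize_sequence(s, rules).rendered for s in sequences}
    return len(raw), len(std), 1.0 - len(std) / len(raw)
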