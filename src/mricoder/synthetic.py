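"""Synthetic MRI modality-log generator.

Real scanner logs and billing exports are proprietary, so this module
emits datasets with the statistical structure the pipeline assumes:
per-exam sequence lists with acquisition parameters, scanner-table
traces, contrast events, approximate ages, and count-valued billing
labelsets in which auxiliary codes (additional series, contrast
administration, angiography add-on, arthrogram) arise only through
conditional rules given the main procedure codes.

Eight procedure templates span the discriminating axes of the feature
set: contrast use, the high idle-to-acquisition ratio of MR-guided
biopsies, the large table sweep of whole-body exams, and the many-code
labelsets of neck exams (about six codes on average).  Raw sequence
names are decorated with exactly the site-specific token classes the
standardizer removes (body region, slice thickness, post-contrast
delay, accelerator tags), so the standardization step is genuinely
exercised.

A technologist simulator degrades truth labelsets asymmetrically:
charged units are far more often forgotten than spurious ones entered,
with auxiliary codes forgotten at an elevated rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np

from .labels import CodeDefinition, Labelset, default_code_definitions
from .logmodel import BillingRecord, LogEvent

__all__ = [
    "SequenceArchetype",
    "ProcedureTemplate",
    "GeneratorConfig",
    "default_templates",
    "default_config",
    "expected_label_cardinality",
    "generate_exam",
    "generate_dataset",
    "simulate_technologist",
    "DatasetBundle",
]


@dataclass(frozen=True)
class SequenceArchetype:
    """Parameter-level description of one MR sequence type."""

    base_name: str
    technique: str
    tr_ms: float
    te_ms: float
    ti_ms: float | None = None
    orientation: str = "tra"
    fat_saturation: bool = False
    breath_hold: bool = False
    b_values: tuple = ()
    dimensionality: str = "2d"
    fov_mm: float = 250.0
    slice_thickness_mm: float = 4.0
    duration_s: tuple = (120, 300)


@dataclass(frozen=True)
class ProcedureTemplate:
    """One MRI procedure type with its sequences, timing, table motion
    and billing rules.

    Billing is a deterministic-given-observables rule set: the base
    labelset, a per-additional-series auxiliary code (count = executed
    sequences beyond ``free_series``, capped at the code's K), a
    contrast-administration code charged iff contrast was given, and —
    for segmented exams (spine) — a per-segment count on the segment
    code.  This ties every label to signals visible in the log, which
    is what makes a noise-free dataset learnable in principle.
    """

    name: str
    weight_archetypes: tuple  # ((weight, SequenceArchetype), ...)
    n_seq_range: tuple = (5, 8)        # total, or per-segment when segmented
    idle_s_range: tuple = (30, 90)
    setup_s_range: tuple = (180, 420)
    table_pattern: str = "static"      # static|stepped|whole_body_sweep|biopsy_cycles
    start_position_mm: float = -1100.0
    station_step_mm: float = 250.0
    contrast_prob: float = 0.0
    base_labels: Mapping[str, int] = field(default_factory=dict)
    extra_series_code: str | None = "39.5010"
    free_series: int = 4
    contrast_code: str | None = "39.5050"
    segments_range: tuple | None = None
    segment_code: str | None = None
    seqs_per_segment: int = 3
    extra_seq_range: tuple = (0, 2)    # only for segmented templates
    age_range: tuple = (20, 85)
    coil_ids: tuple = ("Body18",)


def _arch(**kw) -> SequenceArchetype:
    return SequenceArchetype(**kw)


def default_templates() -> dict:
    """The eight default procedure templates."""
    # (weight, archetype) pairs per template
    head = (
        (2.0, _arch(base_name="t1_se_sag", technique="se", tr_ms=500, te_ms=10,
                    orientation="sag")),
        (2.0, _arch(base_name="t2_tse_tra", technique="tse", tr_ms=4500, te_ms=95)),
        (1.5, _arch(base_name="t2_tirm_dark_fluid_tra", technique="tirm",
                    tr_ms=8000, te_ms=120, ti_ms=2400)),
        (1.0, _arch(base_name="t2_tse_cor", technique="tse", tr_ms=4200, te_ms=90,
                    orientation="cor")),
        (1.5, _arch(base_name="ep2d_diff", technique="ep2d", tr_ms=5000, te_ms=80,
                    b_values=(0.0, 1000.0), duration_s=(90, 180))),
        (1.0, _arch(base_name="t1_gre_3d_sag", technique="gre", tr_ms=9, te_ms=4,
                    orientation="sag", dimensionality="3d")),
    )
    knee = (
        (2.0, _arch(base_name="pd_tse_fs_sag", technique="tse", tr_ms=3200,
                    te_ms=25, orientation="sag", fat_saturation=True)),
        (1.5, _arch(base_name="pd_tse_fs_cor", technique="tse", tr_ms=3000,
                    te_ms=24, orientation="cor", fat_saturation=True)),
        (1.5, _arch(base_name="t1_se_cor", technique="se", tr_ms=550, te_ms=12,
                    orientation="cor")),
        (1.0, _arch(base_name="t2_tse_fs_tra", technique="tse", tr_ms=4000,
                    te_ms=70, fat_saturation=True)),
    )
    shoulder = (
        (2.0, _arch(base_name="t1_tse_fs_tra", technique="tse", tr_ms=600,
                    te_ms=15, fat_saturation=True)),
        (1.5, _arch(base_name="t1_tse_fs_cor", technique="tse", tr_ms=620,
                    te_ms=14, orientation="cor", fat_saturation=True)),
        (1.5, _arch(base_name="t2_tse_fs_sag", technique="tse", tr_ms=3800,
                    te_ms=75, orientation="sag", fat_saturation=True)),
        (1.0, _arch(base_name="t1_se_sag", technique="se", tr_ms=520, te_ms=11,
                    orientation="sag")),
    )
    spine = (
        (2.0, _arch(base_name="t2_tse_sag", technique="tse", tr_ms=3500,
                    te_ms=100, orientation="sag")),
        (2.0, _arch(base_name="t1_tse_sag", technique="tse", tr_ms=600, te_ms=12,
                    orientation="sag")),
        (1.5, _arch(base_name="t2_tse_tra", technique="tse", tr_ms=3600, te_ms=98)),
        (1.0, _arch(base_name="stir_tirm_sag", technique="tirm", tr_ms=4500,
                    te_ms=60, ti_ms=160, orientation="sag")),
    )
    abdomen = (
        (2.0, _arch(base_name="t2_haste_fs_tra", technique="haste", tr_ms=2200,
                    te_ms=95, fat_saturation=True, breath_hold=True,
                    duration_s=(60, 150))),
        (2.0, _arch(base_name="t1_vibe_fs_tra", technique="vibe", tr_ms=4.5,
                    te_ms=2.0, fat_saturation=True, breath_hold=True,
                    dimensionality="3d", duration_s=(60, 150))),
        (1.5, _arch(base_name="ep2d_diff", technique="ep2d", tr_ms=5500,
                    te_ms=70, b_values=(50.0, 400.0, 800.0),
                    duration_s=(120, 240))),
        (1.0, _arch(base_name="t2_tse_fs_cor", technique="tse", tr_ms=4100,
                    te_ms=88, orientation="cor", fat_saturation=True,
                    breath_hold=True)),
        (1.0, _arch(base_name="t1_vibe_fs_cor", technique="vibe", tr_ms=4.4,
                    te_ms=2.1, orientation="cor", fat_saturation=True,
                    breath_hold=True, dimensionality="3d", duration_s=(60, 120))),
    )
    neck = (
        (2.0, _arch(base_name="t1_tse_sag", technique="tse", tr_ms=640, te_ms=13,
                    orientation="sag")),
        (2.0, _arch(base_name="t2_tse_fs_tra", technique="tse", tr_ms=4200,
                    te_ms=80, fat_saturation=True)),
        (1.5, _arch(base_name="stir_tirm_cor", technique="tirm", tr_ms=4600,
                    te_ms=55, ti_ms=170, orientation="cor")),
        (1.5, _arch(base_name="t1_gre_angio_3d", technique="gre", tr_ms=25,
                    te_ms=3.5, dimensionality="3d", duration_s=(90, 180))),
    )
    whole_body = (
        (2.0, _arch(base_name="t1_gre_cor", technique="gre", tr_ms=250, te_ms=4,
                    orientation="cor", breath_hold=True, duration_s=(60, 140))),
        (2.0, _arch(base_name="t2_haste_cor", technique="haste", tr_ms=2100,
                    te_ms=92, orientation="cor", breath_hold=True,
                    duration_s=(60, 140))),
        (1.5, _arch(base_name="stir_tirm_cor", technique="tirm", tr_ms=4600,
                    te_ms=58, ti_ms=165, orientation="cor")),
        (1.0, _arch(base_name="ep2d_diff", technique="ep2d", tr_ms=5200,
                    te_ms=75, b_values=(50.0, 800.0), duration_s=(90, 200))),
    )
    biopsy = (
        (2.0, _arch(base_name="t1_gre_tra", technique="gre", tr_ms=300, te_ms=5,
                    duration_s=(25, 60))),
        (1.5, _arch(base_name="trufi_tra", technique="trufi", tr_ms=4.2,
                    te_ms=1.9, duration_s=(20, 50))),
        (1.0, _arch(base_name="t2_haste_tra", technique="haste", tr_ms=2300,
                    te_ms=90, duration_s=(30, 70))),
    )

    templates = [
        ProcedureTemplate(
            name="head", weight_archetypes=head, n_seq_range=(5, 8),
            free_series=4, contrast_prob=0.25,
            base_labels={"39.0100": 1}, coil_ids=("HeadNeck20",),
            start_position_mm=-1150.0,
        ),
        ProcedureTemplate(
            name="knee", weight_archetypes=knee, n_seq_range=(4, 7),
            free_series=4, contrast_prob=0.0,
            base_labels={"39.0500": 1}, coil_ids=("Knee15",),
            start_position_mm=-300.0,
        ),
        ProcedureTemplate(
            name="shoulder_arthro", weight_archetypes=shoulder,
            n_seq_range=(5, 8), free_series=4, contrast_prob=0.9,
            base_labels={"39.0400": 1, "39.0410": 1},
            coil_ids=("Shoulder16",), start_position_mm=-950.0,
        ),
        ProcedureTemplate(
            name="spine", weight_archetypes=spine, table_pattern="stepped",
            segments_range=(1, 3), segment_code="39.0300", seqs_per_segment=3,
            extra_seq_range=(0, 2), free_series=None, contrast_prob=0.45,
            base_labels={}, coil_ids=("Spine32",),
            start_position_mm=-800.0, station_step_mm=260.0,
        ),
        ProcedureTemplate(
            name="abdomen_cm", weight_archetypes=abdomen, n_seq_range=(6, 10),
            free_series=5, contrast_prob=0.95,
            base_labels={"39.0600": 1}, coil_ids=("Body18", "Spine32"),
            start_position_mm=-550.0,
        ),
        ProcedureTemplate(
            name="neck", weight_archetypes=neck, n_seq_range=(5, 7),
            free_series=4, contrast_prob=0.8,
            base_labels={"39.0200": 1, "39.0300": 1, "39.5020": 1},
            coil_ids=("HeadNeck20", "Spine32"), start_position_mm=-1000.0,
        ),
        ProcedureTemplate(
            name="whole_body", weight_archetypes=whole_body,
            n_seq_range=(8, 12), free_series=5, contrast_prob=0.2,
            table_pattern="whole_body_sweep",
            base_labels={"39.0800": 1},
            coil_ids=("Body18", "Spine32", "HeadNeck20"),
            start_position_mm=-1150.0, station_step_mm=420.0,
        ),
        ProcedureTemplate(
            name="mr_biopsy", weight_archetypes=biopsy, n_seq_range=(3, 5),
            idle_s_range=(300, 650), setup_s_range=(420, 900),
            table_pattern="biopsy_cycles", free_series=3, contrast_prob=0.1,
            base_labels={"39.1000": 1, "39.0600": 1},
            coil_ids=("Body18",), start_position_mm=-550.0,
        ),
    ]
    return {t.name: t for t in templates}


#: Default mix proportions over the templates above.
DEFAULT_MIX = {
    "head": 0.20,
    "knee": 0.13,
    "shoulder_arthro": 0.11,
    "spine": 0.14,
    "abdomen_cm": 0.13,
    "neck": 0.10,
    "whole_body": 0.08,
    "mr_biopsy": 0.11,
}

#: Site-decoration token classes injected into raw names (and removed by
#: the standardizer): body region, slice thickness, post-contrast delay,
#: accelerator/averaging tags.
REGION_TOKENS = {
    "head": ("Kopf", "Brain", "Schaedel"),
    "knee": ("Knie", "Knee_left", "Knee_right"),
    "shoulder_arthro": ("Schulter", "Shoulder_r", "Shoulder_l"),
    "spine": ("LWS", "HWS", "BWS"),
    "abdomen_cm": ("Abdomen", "Leber", "Oberbauch"),
    "neck": ("Hals", "Neck"),
    "whole_body": ("WB", "GanzKoerper"),
    "mr_biopsy": ("Biopsie", "Interv"),
}
THICKNESS_TOKENS = ("3mm", "4mm", "5mm")
DELAY_TOKENS = ("15 min", "5min", "portalvenoes")
ACCEL_TOKENS = ("p2", "p3", "caipi", "4Scan", "mbh", "2avg")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_exams: int = 2000
    mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    forget_rate: float = 0.0
    add_rate: float = 0.0
    aux_forget_multiplier: float = 2.5
    abort_rate: float = 0.01
    rare_code_prob: float = 0.005
    rare_code: str = "39.0950"
    nonimaging_code_prob: float = 0.15
    nonimaging_codes: tuple = ("00.0510", "00.0520")
    scanners: tuple = ("MR-A", "MR-B")
    start_time: str = "2024-01-08T07:00:00"
    decoration_prob: float = 0.9

    def __post_init__(self):
        total = sum(self.mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"template mix must sum to 1 (got {total})")
        for r in (self.forget_rate, self.add_rate, self.abort_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def default_config(**overrides) -> GeneratorConfig:
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


def _uniform_int_mean(lo: int, hi: int) -> float:
    return (lo + hi) / 2.0


def _expected_extra_series(lo: int, hi: int, free: int, cap: int = 4) -> float:
    vals = [min(max(n - free, 0), cap) for n in range(lo, hi + 1)]
    return float(np.mean(vals))


def expected_label_cardinality(
    config: GeneratorConfig, templates: Mapping[str, ProcedureTemplate] | None = None
) -> float:
    """Analytic mean charged units per (non-aborted) exam under the
    template mix — the generator's own expectation, used as the oracle
    for the empirical cardinality of generated datasets."""
    templates = templates or default_templates()
    total = 0.0
    for name, p in config.mix.items():
        t = templates[name]
        e = float(sum(t.base_labels.values()))
        if t.segments_range is not None:
            s_mean = _uniform_int_mean(*t.segments_range)
            e += s_mean  # segment code charged once per segment
            lo, hi = t.extra_seq_range
            e += _uniform_int_mean(lo, hi)  # extra series beyond segments
        elif t.extra_series_code is not None:
            lo, hi = t.n_seq_range
            e += _expected_extra_series(lo, hi, t.free_series)
        if t.contrast_code is not None:
            e += t.contrast_prob
        total += p * e
    total += config.rare_code_prob
    return total


# ---------------------------------------------------------------------------
# Exam generation


def _decorate(base: str, template: ProcedureTemplate, rng,
              decoration_prob: float) -> str:
    tokens = [base]
    if rng.random() < decoration_prob:
        tokens.append(str(rng.choice(REGION_TOKENS[template.name])))
    if rng.random() < 0.5:
        tokens.append(str(rng.choice(THICKNESS_TOKENS)))
    if rng.random() < 0.3:
        tokens.append(str(rng.choice(ACCEL_TOKENS)))
    if rng.random() < 0.15:
        tokens.append(str(rng.choice(DELAY_TOKENS)))
    return "_".join(tokens)


def _seq_payload(arch: SequenceArchetype, raw_name: str, position: float,
                 coil_ids: tuple) -> dict:
    return {
        "raw_name": raw_name,
        "tr_ms": arch.tr_ms,
        "te_ms": arch.te_ms,
        "ti_ms": arch.ti_ms,
        "technique": arch.technique,
        "dimensionality": arch.dimensionality,
        "orientation": arch.orientation,
        "fat_saturation": arch.fat_saturation,
        "breath_hold": arch.breath_hold,
        "b_values": list(arch.b_values),
        "fov_mm": arch.fov_mm,
        "slice_thickness_mm": arch.slice_thickness_mm,
        "coil_ids": list(coil_ids),
        "table_position_mm": round(position, 1),
    }


def generate_exam(
    template: ProcedureTemplate,
    rng: np.random.Generator,
    exam_id: str = "exam-1",
    scanner_id: str = "MR-A",
    t0: datetime | None = None,
    config: GeneratorConfig | None = None,
) -> tuple[list, Labelset]:
    """Generate one exam's events and its true labelset."""
    config = config or GeneratorConfig()
    t0 = t0 or datetime(2024, 1, 8, 7, 0, 0)
    events: list[LogEvent] = []
    age = float(rng.uniform(*template.age_range))
    events.append(
        LogEvent("registration", t0, scanner_id,
                 {"subject_token": f"subj-{exam_id}", "exam_id": exam_id,
                  "approximate_age_years": round(age, 1)})
    )

    # sequence plan
    if template.segments_range is not None:
        lo, hi = template.segments_range
        segments = int(rng.integers(lo, hi + 1))
        extra = int(rng.integers(template.extra_seq_range[0],
                                 template.extra_seq_range[1] + 1))
        n_seq = segments * template.seqs_per_segment + extra
    else:
        segments = 1
        extra = 0
        n_seq = int(rng.integers(template.n_seq_range[0],
                                 template.n_seq_range[1] + 1))

    weights = np.array([w for w, _ in template.weight_archetypes], dtype=float)
    weights /= weights.sum()
    archs = [a for _, a in template.weight_archetypes]

    contrast = rng.random() < template.contrast_prob
    # the event dialect is second-resolution, so clocks stay integral
    clock = t0 + timedelta(seconds=round(float(rng.uniform(*template.setup_s_range))))
    position = template.start_position_mm
    events.append(
        LogEvent("table_move", t0 + timedelta(seconds=30), scanner_id,
                 {"position_mm": round(position, 1)})
    )
    contrast_at = rng.integers(1, max(2, n_seq)) if contrast else -1

    for k in range(n_seq):
        # table pattern
        if template.table_pattern == "stepped":
            station = min(k // template.seqs_per_segment, segments - 1)
            new_pos = template.start_position_mm + station * template.station_step_mm
        elif template.table_pattern == "whole_body_sweep":
            new_pos = template.start_position_mm + k * template.station_step_mm
        elif template.table_pattern == "biopsy_cycles":
            # table driven out between acquisition cycles for needle work
            if k > 0:
                out_pos = template.start_position_mm + 600.0
                events.append(
                    LogEvent("table_move",
                             clock - timedelta(seconds=20), scanner_id,
                             {"position_mm": round(out_pos, 1)})
                )
            new_pos = template.start_position_mm
        else:
            new_pos = position
        if abs(new_pos - position) > 1e-9 or template.table_pattern == "biopsy_cycles":
            events.append(
                LogEvent("table_move", clock - timedelta(seconds=5), scanner_id,
                         {"position_mm": round(new_pos, 1)})
            )
        position = new_pos

        if k == contrast_at:
            events.append(
                LogEvent("contrast_injection", clock - timedelta(seconds=2),
                         scanner_id,
                         {"agent": "gadolinium", "volume_ml": float(rng.integers(8, 20))})
            )

        arch = archs[int(rng.choice(len(archs), p=weights))]
        raw = _decorate(arch.base_name, template, rng, config.decoration_prob)
        dur = float(rng.uniform(*arch.duration_s))
        start = clock
        end = start + timedelta(seconds=round(dur))
        payload = _seq_payload(arch, raw, position, template.coil_ids)
        events.append(LogEvent("sequence_start", start, scanner_id, payload))
        events.append(LogEvent("sequence_end", end, scanner_id,
                               {"raw_name": raw}))
        clock = end + timedelta(seconds=round(float(rng.uniform(*template.idle_s_range))))

    # billing truth
    counts = dict(template.base_labels)
    if template.segments_range is not None and template.segment_code:
        counts[template.segment_code] = (
            counts.get(template.segment_code, 0) + segments
        )
        n_free = segments * template.seqs_per_segment
    else:
        n_free = template.free_series or 0
    if template.extra_series_code is not None:
        extra_series = min(max(n_seq - n_free, 0), 4)
        if extra_series:
            counts[template.extra_series_code] = (
                counts.get(template.extra_series_code, 0) + extra_series
            )
    if contrast and template.contrast_code:
        counts[template.contrast_code] = counts.get(template.contrast_code, 0) + 1
    return events, Labelset(counts)


@dataclass
class DatasetBundle:
    """One generated dataset: events, truth billing, provenance."""

    events: list
    truth: list            # BillingRecord, keyed by exam_id
    labelsets: dict        # exam_id -> Labelset (truth, pre-noise)
    provenance: list       # (exam_id, template_name)
    config: GeneratorConfig


def generate_dataset(
    config: GeneratorConfig,
    seed: int,
    templates: Mapping[str, ProcedureTemplate] | None = None,
) -> DatasetBundle:
    """Generate a reproducible multi-scanner dataset.

    Exams are laid out on per-scanner clocks with inter-exam gaps, so
    spans on one scanner never overlap.  Aborted exams (registration
    without any completed sequence) occur at ``abort_rate`` and carry
    empty labelsets.  An occasional rare procedure code and non-imaging
    codes (intravenous access, narcosis surcharge) are injected into
    the billing stream to exercise the cleaning rules.
    """
    rng = np.random.default_rng(seed)
    templates = templates or default_templates()
    names = sorted(config.mix)
    probs = np.array([config.mix[n] for n in names])

    clocks = {s: datetime.fromisoformat(config.start_time) for s in config.scanners}
    events: list[LogEvent] = []
    truth: list[BillingRecord] = []
    labelsets: dict[str, Labelset] = {}
    provenance: list[tuple] = []

    for i in range(config.n_exams):
        scanner = config.scanners[i % len(config.scanners)]
        t0 = clocks[scanner]
        exam_id = f"E{i:05d}"
        if rng.random() < config.abort_rate:
            age = float(rng.uniform(18, 90))
            events.append(
                LogEvent("registration", t0, scanner,
                         {"subject_token": f"subj-{exam_id}", "exam_id": exam_id,
                          "approximate_age_years": round(age, 1)})
            )
            labelsets[exam_id] = Labelset({})
            provenance.append((exam_id, "aborted"))
            clocks[scanner] = t0 + timedelta(seconds=int(rng.integers(600, 1800)))
            continue
        name = names[int(rng.choice(len(names), p=probs))]
        ex_events, ls = generate_exam(
            templates[name], rng, exam_id=exam_id, scanner_id=scanner,
            t0=t0, config=config,
        )
        counts = ls.as_dict()
        if rng.random() < config.rare_code_prob:
            counts[config.rare_code] = 1
        if rng.random() < config.nonimaging_code_prob:
            code = str(rng.choice(config.nonimaging_codes))
            counts[code] = 1
        ls = Labelset(counts)
        events.extend(ex_events)
        labelsets[exam_id] = ls
        provenance.append((exam_id, name))
        for code, n in ls.items():
            truth.append(BillingRecord(code_id=code, count=n, exam_id=exam_id))
        end = max(e.timestamp for e in ex_events)
        clocks[scanner] = end + timedelta(seconds=int(rng.integers(600, 1800)))

    events.sort(key=lambda e: (e.timestamp, e.scanner_id,
                               0 if e.event_kind != "registration" else 1))
    return DatasetBundle(events=events, truth=truth, labelsets=labelsets,
                         provenance=provenance, config=config)


# ---------------------------------------------------------------------------
# Constructed label-dependency scenario


def label_dependency_scenario(
    seed: int,
    n: int = 1000,
    n_noise_dims: int = 20,
    separation: float = 4.0,
    priors: tuple = (0.34, 0.33, 0.33),
) -> tuple:
    """Two-label dataset exhibiting a pure label dependency.

    Main label A takes values {0, 1, 2}: class 0 sits at the origin and
    classes 1 and 2 form lobes at ``-separation`` and ``+separation``
    along one random direction in an isotropic Gaussian background.
    Auxiliary label B = indicator(A >= 1) carries no feature information
    beyond A itself: the binary partition {0} vs {1, 2} is a sandwich
    that no linear boundary separates, while the three classes of A are
    pairwise linearly separable.  A (near-)linear base classifier can
    therefore predict A but not B directly — B is only reachable
    through the chain dependency, which is the situation auxiliary
    billing codes create (charged only alongside their main code).

    Returns (X, A, B) with X of shape (n, n_noise_dims).
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(size=n_noise_dims)
    u /= np.linalg.norm(u)
    A = rng.choice([0, 1, 2], size=n, p=list(priors))
    z = np.where(A == 0, 0.0, np.where(A == 1, -separation, separation))
    X = z[:, None] * u[None, :] + rng.normal(size=(n, n_noise_dims))
    B = (A >= 1).astype(int)
    return X, A, B


# ---------------------------------------------------------------------------
# Technologist coding-error simulator


def simulate_technologist(
    truths: Sequence[Labelset],
    forget_rate: float,
    add_rate: float,
    rng: np.random.Generator,
    code_defs: Mapping[str, CodeDefinition] | None = None,
    aux_forget_multiplier: float = 2.5,
) -> list:
    """Degrade truth labelsets the way manual coding errs.

    Each charged unit is independently forgotten with ``forget_rate``
    (auxiliary codes at ``aux_forget_multiplier`` times that rate,
    reflecting that manually added surcharge codes dominate coding
    errors); with probability ``add_rate`` per exam one spurious unit of
    a random imaging code is entered.  With forget > add the simulated
    coder shows the precision > recall asymmetry of real manual coding.
    """
    if not 0.0 <= forget_rate <= 1.0 or not 0.0 <= add_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    code_defs = code_defs or default_code_definitions()
    imaging_codes = sorted(c for c, d in code_defs.items() if d.imaging_related)
    coded = []
    for ls in truths:
        out: dict[str, int] = {}
        for code, n in ls.items():
            aux = code in code_defs and code_defs[code].auxiliary
            rate = min(1.0, forget_rate * (aux_forget_multiplier if aux else 1.0))
            kept = int(np.sum(rng.random(n) >= rate))
            if kept:
                out[code] = kept
        if rng.random() < add_rate:
            code = str(rng.choice(imaging_codes))
            cap = code_defs[code].max_count
            if out.get(code, 0) < cap:
                out[code] = out.get(code, 0) + 1
        coded.append(Labelset(out))
    return coded
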