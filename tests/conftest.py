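"""Shared fixtures: hand-built sequences/exams and small generated datasets."""

from datetime import datetime, timedelta

import pytest

from mricoder.labels import Labelset, default_code_definitions
from mricoder.logmodel import ExamInstance, SequenceRecord

T0 = datetime(2024, 3, 4, 8, 0, 0)


def make_seq(
    raw_name="t2_tse_tra",
    start_s=0,
    duration_s=200,
    tr_ms=4000.0,
    te_ms=90.0,
    ti_ms=None,
    technique="tse",
    orientation="tra",
    fat_saturation=False,
    breath_hold=False,
    b_values=(),
    table_position_mm=0.0,
    coil_ids=frozenset(),
    **kw,
):
    start = T0 + timedelta(seconds=start_s)
    return SequenceRecord(
        raw_name=raw_name,
        start_time=start,
        end_time=start + timedelta(seconds=duration_s),
        tr_ms=tr_ms,
        te_ms=te_ms,
        ti_ms=ti_ms,
        technique=technique,
        orientation=orientation,
        fat_saturation=fat_saturation,
        breath_hold=breath_hold,
        b_values=tuple(b_values),
        table_position_mm=table_position_mm,
        coil_ids=frozenset(coil_ids),
        **kw,
    )


def make_exam(sequences, exam_id="X1", registration_offset_s=-300, **kw):
    exam = ExamInstance(
        exam_id=exam_id,
        registration_time=T0 + timedelta(seconds=registration_offset_s),
        sequences=sorted(sequences, key=lambda s: s.start_time),
        **kw,
    )
    exam.table_positions = [
        (s.start_time, s.table_position_mm) for s in exam.sequences
    ]
    exam.aborted = not exam.sequences
    return exam


@pytest.fixture
def code_defs():
    return default_code_definitions()


@pytest.fixture
def ls():
    return Labelset
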