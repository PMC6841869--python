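"""Event dialect round-trips, exam assembly, and billing merge."""

import io
from datetime import datetime, timedelta

import numpy as np
import pytest

from mricoder.logmodel import (
    LogEvent,
    MergeAmbiguityError,
    assemble_exams,
    merge_billing,
    read_billing,
    read_events,
    write_billing,
    write_events,
    BillingRecord,
)
from mricoder.synthetic import GeneratorConfig, generate_dataset


def _ev(kind, ts, scanner="MR-A", **payload):
    return LogEvent(kind, ts, scanner, payload)


def _seq_payload(name, pos=0.0):
    return {
        "raw_name": name, "tr_ms": 4000.0, "te_ms": 90.0, "ti_ms": None,
        "technique": "tse", "dimensionality": "2d", "orientation": "tra",
        "fat_saturation": False, "breath_hold": False, "b_values": [],
        "fov_mm": 250.0, "slice_thickness_mm": 4.0, "coil_ids": [],
        "table_position_mm": pos,
    }


T = datetime(2024, 3, 4, 8, 0, 0)


class TestEventIO:
    def test_well_formed_lines_round_trip(self):
        events = [
            _ev("registration", T, subject_token="s1", approximate_age_years=44.0),
            _ev("sequence_start", T + timedelta(seconds=60), **_seq_payload("a")),
            _ev("sequence_end", T + timedelta(seconds=260), raw_name="a"),
        ]
        buf = io.StringIO()
        write_events(events, buf)
        log = read_events(io.StringIO(buf.getvalue()))
        assert log.rejects == []
        assert log.events == events

    def test_generated_events_round_trip_exactly(self):
        bundle = generate_dataset(GeneratorConfig(n_exams=30), seed=5)
        buf = io.StringIO()
        write_events(bundle.events, buf)
        log = read_events(io.StringIO(buf.getvalue()))
        assert log.rejects == []
        assert log.events == bundle.events

    def test_unknown_kind_rejected_with_reason(self):
        line = '{"event_kind": "telemetry", "timestamp": "2024-03-04T08:00:00", "scanner_id": "A", "payload": {}}'
        log = read_events(io.StringIO(line + "\n"))
        assert log.events == []
        assert len(log.rejects) == 1
        assert "telemetry" in log.rejects[0].reason

    def test_bad_timestamp_and_bad_json_rejected(self):
        lines = (
            '{"event_kind": "table_move", "timestamp": "yesterday", "scanner_id": "A", "payload": {"position_mm": 1}}\n'
            "not json at all\n"
        )
        log = read_events(io.StringIO(lines))
        assert log.events == []
        assert [r.line_no for r in log.rejects] == [1, 2]

    def test_empty_stream_is_empty_log_not_error(self):
        log = read_events(io.StringIO(""))
        assert log.events == [] and log.rejects == []


class TestAssembly:
    def test_single_split_point(self):
        events = [
            _ev("registration", T, subject_token="s1"),
            _ev("sequence_start", T + timedelta(seconds=60), **_seq_payload("a")),
            _ev("sequence_end", T + timedelta(seconds=260), raw_name="a"),
            _ev("sequence_start", T + timedelta(seconds=300), **_seq_payload("b")),
            _ev("sequence_end", T + timedelta(seconds=500), raw_name="b"),
            _ev("registration", T + timedelta(seconds=900), subject_token="s2"),
        ]
        result = assemble_exams(events)
        assert len(result.exams) == 2
        assert len(result.exams[0].sequences) == 2
        assert result.exams[0].aborted is False
        assert result.exams[1].aborted is True

    def test_registration_without_sequences_flagged_aborted(self):
        events = [
            _ev("registration", T, subject_token="s1"),
            _ev("registration", T + timedelta(seconds=600), subject_token="s2"),
            _ev("sequence_start", T + timedelta(seconds=700), **_seq_payload("a")),
            _ev("sequence_end", T + timedelta(seconds=900), raw_name="a"),
        ]
        result = assemble_exams(events)
        assert [e.aborted for e in result.exams] == [True, False]

    def test_boundary_tie_sequence_end_goes_to_earlier_exam(self):
        t_next = T + timedelta(seconds=500)
        events = [
            _ev("registration", T, subject_token="s1"),
            _ev("sequence_start", T + timedelta(seconds=100), **_seq_payload("a")),
            _ev("registration", t_next, subject_token="s2"),
            _ev("sequence_end", t_next, raw_name="a"),
        ]
        result = assemble_exams(events)
        assert len(result.exams[0].sequences) == 1
        assert len(result.exams[1].sequences) == 0

    def test_orphan_sequence_end_rejected_exam_kept(self):
        events = [
            _ev("registration", T, subject_token="s1"),
            _ev("sequence_end", T + timedelta(seconds=100), raw_name="ghost"),
            _ev("sequence_start", T + timedelta(seconds=200), **_seq_payload("a")),
            _ev("sequence_end", T + timedelta(seconds=400), raw_name="a"),
        ]
        result = assemble_exams(events)
        assert len(result.exams) == 1
        assert len(result.exams[0].sequences) == 1
        assert any("matching" in r.reason for r in result.rejects)

    def test_events_before_any_registration_rejected(self):
        events = [
            _ev("table_move", T, position_mm=100.0),
            _ev("registration", T + timedelta(seconds=60), subject_token="s1"),
        ]
        result = assemble_exams(events)
        assert any("before any registration" in r.reason for r in result.rejects)

    def test_random_interleaved_exams_match_brute_force_partition(self):
        """Assembly equals a brute-force partition by registration times."""
        rng = np.random.default_rng(42)
        events = []
        expected = {}  # (scanner, reg index) -> n sequences
        for scanner in ("MR-A", "MR-B"):
            t = T
            for k in range(25):
                events.append(_ev("registration", t, scanner,
                                  subject_token=f"{scanner}-{k}"))
                n_seq = int(rng.integers(0, 5))
                expected[(scanner, k)] = n_seq
                t += timedelta(seconds=120)
                for s in range(n_seq):
                    name = f"seq{k}-{s}"
                    events.append(_ev("sequence_start", t, scanner,
                                      **_seq_payload(name)))
                    t += timedelta(seconds=int(rng.integers(60, 300)))
                    events.append(_ev("sequence_end", t, scanner, raw_name=name))
                    t += timedelta(seconds=int(rng.integers(20, 90)))
                t += timedelta(seconds=int(rng.integers(300, 900)))
        events.sort(key=lambda e: e.timestamp)
        result = assemble_exams(events)
        assert len(result.exams) == 50
        by_scanner = {}
        for exam in result.exams:
            by_scanner.setdefault(exam.scanner_id, []).append(exam)
        for scanner, exams in by_scanner.items():
            for k, exam in enumerate(exams):
                assert len(exam.sequences) == expected[(scanner, k)]

    def test_consecutive_exam_spans_do_not_overlap_per_scanner(self):
        bundle = generate_dataset(GeneratorConfig(n_exams=60), seed=9)
        result = assemble_exams(bundle.events)
        assert not result.rejects
        by_scanner = {}
        for exam in result.exams:
            by_scanner.setdefault(exam.scanner_id, []).append(exam)
        for exams in by_scanner.values():
            exams.sort(key=lambda e: e.registration_time)
            for a, b in zip(exams, exams[1:]):
                assert a.end_time <= b.registration_time


class TestBillingMerge:
    def _two_exams(self):
        events = [
            _ev("registration", T, subject_token="s1", exam_id="A"),
            _ev("sequence_start", T + timedelta(seconds=60), **_seq_payload("a")),
            _ev("sequence_end", T + timedelta(seconds=260), raw_name="a"),
            _ev("registration", T + timedelta(hours=3), subject_token="s2",
                exam_id="B"),
            _ev("sequence_start", T + timedelta(hours=3, seconds=60),
                **_seq_payload("b")),
            _ev("sequence_end", T + timedelta(hours=3, seconds=260), raw_name="b"),
        ]
        return assemble_exams(events).exams

    def test_direct_aggregation_by_exam_id(self):
        exams = self._two_exams()
        billing = [
            BillingRecord("c1", 1, exam_id="A"),
            BillingRecord("c2", 2, exam_id="A"),
            BillingRecord("c2", 1, exam_id="A"),
        ]
        merge_billing(exams, billing)
        assert exams[0].labelset == {"c1": 1, "c2": 3}
        assert exams[1].labelset == {}
        assert exams[1].no_billing_match

    def test_unmatched_record_reported(self):
        exams = self._two_exams()
        result = merge_billing(exams, [BillingRecord("c1", 1, exam_id="ZZ")])
        assert len(result.unmatched) == 1

    def test_timestamp_keyed_merge_equals_id_keyed(self):
        # one scanner: with two, simultaneous exams make timestamp keys
        # genuinely ambiguous (that case is covered below)
        bundle = generate_dataset(
            GeneratorConfig(n_exams=20, abort_rate=0.0, scanners=("MR-A",)),
            seed=13,
        )
        exams_id = assemble_exams(bundle.events).exams
        merge_billing(exams_id, bundle.truth)
        by_id = {e.exam_id: e.labelset for e in exams_id}

        exams_ts = assemble_exams(bundle.events).exams
        reg = {e.exam_id: e.registration_time for e in exams_ts}
        ts_records = [
            BillingRecord(r.code_id, r.count,
                          timestamp=reg[r.exam_id] + timedelta(seconds=60))
            for r in bundle.truth
        ]
        merge_billing(exams_ts, ts_records, tolerance=timedelta(minutes=5))
        for exam in exams_ts:
            assert exam.labelset == by_id[exam.exam_id]

    def test_ambiguous_timestamp_raises_listing_candidates(self):
        exams = self._two_exams()
        rec = BillingRecord("c1", 1, timestamp=T + timedelta(hours=1, minutes=30))
        with pytest.raises(MergeAmbiguityError) as err:
            merge_billing(exams, [rec], tolerance=timedelta(hours=2))
        assert "A" in str(err.value) and "B" in str(err.value)

    def test_billing_csv_round_trip(self):
        records = [BillingRecord("39.0100", 1, exam_id="E1"),
                   BillingRecord("39.5010", 2, exam_id="E1")]
        buf = io.StringIO()
        write_billing(records, buf)
        assert read_billing(io.StringIO(buf.getvalue())) == records
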