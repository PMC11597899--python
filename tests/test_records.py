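"""Log parsing/writing, valence mapping, and illuminance utilities."""

from datetime import datetime

import pytest
from hypothesis import given
from hypothesis import strategies as st

from luxsense import (
    CCMRecord,
    ChildLog,
    Color,
    Emotion,
    Illumination,
    LogParseError,
    Mode,
    Valence,
    binarize_illumination,
    illumination_at_distance,
    parse_log,
    valence_of,
    write_log,
)

from conftest import child_logs


class TestParseLog:
    def test_sample_ccm_rows(self, sample_ccm_csv):
        log = parse_log(sample_ccm_csv, Mode.CCM)
        assert len(log.sessions) == 1 and log.n_records == 3
        first = log.records[0]
        assert first == CCMRecord(
            datetime(2024, 7, 23, 14, 35, 10), Color.BLUE, Illumination.HIGH, 60
        )
        assert [r.duration_s for r in log.records] == [60, 40, 30]

    def test_sample_scm_rows(self, sample_scm_csv):
        log = parse_log(sample_scm_csv, Mode.SCM)
        assert [r.response for r in log.records] == [
            Valence.POSITIVE,
            Valence.NEGATIVE,
            Valence.NEGATIVE,
        ]

    def test_empty_body_is_one_empty_session(self):
        log = parse_log("date_time,color,illumination,duration_s\n", Mode.CCM)
        assert log.sessions == ((),)

    def test_minute_precision_padded_to_seconds(self):
        log = parse_log(
            "date_time,color,illumination,duration_s\n2024-07-23 14:35,B,HI,60\n",
            Mode.CCM,
        )
        assert log.records[0].timestamp == datetime(2024, 7, 23, 14, 35, 0)
        assert "2024-07-23 14:35:00" in write_log(log)

    def test_session_column_groups_records(self):
        text = (
            "date_time,color,illumination,duration_s,session\n"
            "2024-07-23 10:00:00,B,HI,10,1\n"
            "2024-07-23 11:00:00,R,LI,20,2\n"
            "2024-07-23 11:00:30,G,LI,5,2\n"
        )
        log = parse_log(text, Mode.CCM)
        assert [len(s) for s in log.sessions] == [1, 2]

    def test_raw_emotion_words_map_to_valence(self):
        text = (
            "date_time,color,illumination,response\n"
            "2024-07-23 14:00:00,B,HI,joy\n"
            "2024-07-23 14:00:05,R,LI,neutrality\n"
        )
        log = parse_log(text, Mode.SCM)
        assert [r.response for r in log.records] == [Valence.POSITIVE, Valence.NEGATIVE]

    @pytest.mark.parametrize(
        "row, fieldname",
        [
            ("2024-07-23 14:35:10,Q,HI,60", "color"),
            ("2024-07-23 14:35:10,B,XX,60", "illumination"),
            ("2024-07-23 14:35:10,B,HI,-5", "duration_s"),
            ("not-a-date,B,HI,60", "date_time"),
        ],
    )
    def test_bad_ccm_row_names_row_and_field(self, row, fieldname):
        text = f"date_time,color,illumination,duration_s\n{row}\n"
        with pytest.raises(LogParseError) as exc:
            parse_log(text, Mode.CCM)
        assert exc.value.row == 1 and exc.value.fieldname == fieldname

    def test_bad_response_code(self):
        text = "date_time,color,illumination,response\n2024-07-23 14:35:10,B,HI,X\n"
        with pytest.raises(LogParseError) as exc:
            parse_log(text, Mode.SCM)
        assert exc.value.fieldname == "response"

    def test_out_of_order_timestamps_rejected(self):
        text = (
            "date_time,color,illumination,duration_s\n"
            "2024-07-23 14:35:10,B,HI,60\n"
            "2024-07-23 14:00:00,R,LI,40\n"
        )
        with pytest.raises(LogParseError) as exc:
            parse_log(text, Mode.CCM)
        assert exc.value.row == 2

    def test_missing_header_column(self):
        with pytest.raises(ValueError, match="missing columns"):
            parse_log("date_time,color,duration_s\n", Mode.CCM)


class TestWriteLog:
    def test_sample_rows_round_trip(self, sample_ccm_log):
        assert parse_log(write_log(sample_ccm_log), Mode.CCM) == sample_ccm_log

    def test_empty_session_round_trip(self):
        log = ChildLog(child_id="", mode=Mode.SCM, sessions=((),))
        text = write_log(log)
        assert text.strip() == "date_time,color,illumination,response"
        assert parse_log(text, Mode.SCM) == log

    @given(log=child_logs())
    def test_round_trip_identity(self, log):
        assert parse_log(write_log(log), log.mode) == log


class TestValence:
    @pytest.mark.parametrize(
        "emotion, valence",
        [
            (Emotion.JOY, Valence.POSITIVE),
            (Emotion.SURPRISE, Valence.POSITIVE),
            (Emotion.ANGER, Valence.NEGATIVE),
            (Emotion.FEAR, Valence.NEGATIVE),
            (Emotion.SADNESS, Valence.NEGATIVE),
            (Emotion.NEUTRALITY, Valence.NEGATIVE),
        ],
    )
    def test_mapping(self, emotion, valence):
        assert valence_of(emotion) is valence

    def test_partition_two_positive_four_negative(self):
        outcomes = [valence_of(e) for e in Emotion]
        assert outcomes.count(Valence.POSITIVE) == 2
        assert outcomes.count(Valence.NEGATIVE) == 4

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown emotion"):
            valence_of("boredom")


class TestIlluminance:
    def test_binarization_thresholds(self):
        assert binarize_illumination(50) is Illumination.LOW
        assert binarize_illumination(150) is Illumination.HIGH
        assert binarize_illumination(100) is Illumination.HIGH  # boundary -> HI

    @pytest.mark.parametrize("lux", [0, -10])
    def test_binarize_rejects_nonpositive(self, lux):
        with pytest.raises(ValueError):
            binarize_illumination(lux)

    def test_inverse_square_examples(self):
        assert illumination_at_distance(120, 0.5) == pytest.approx(480)
        assert illumination_at_distance(123.4, 1.0) == pytest.approx(123.4)
        assert illumination_at_distance(120, 2.0) == pytest.approx(30)

    @pytest.mark.parametrize("d", [0, -1])
    def test_rejects_nonpositive_distance(self, d):
        with pytest.raises(ValueError):
            illumination_at_distance(120, d)

    @given(
        lux=st.floats(1, 1e4),
        d1=st.floats(0.1, 10),
        d2=st.floats(0.1, 10),
        k=st.floats(0.1, 100),
    )
    def test_decreasing_in_distance_linear_in_lux(self, lux, d1, d2, k):
        if d1 < d2:
            assert illumination_at_distance(lux, d1) > illumination_at_distance(lux, d2)
        assert illumination_at_distance(k * lux, d1) == pytest.approx(
            k * illumination_at_distance(lux, d1)
        )

    @given(lux1=st.floats(1, 1e4), lux2=st.floats(1, 1e4), d=st.floats(0.1, 10))
    def test_binarized_class_monotone_in_lux(self, lux1, lux2, d):
        # increasing source lux can never flip the class from HI down to LI
        lo, hi = sorted([lux1, lux2])
        cls_lo = binarize_illumination(illumination_at_distance(lo, d))
        cls_hi = binarize_illumination(illumination_at_distance(hi, d))
        assert not (cls_lo is Illumination.HIGH and cls_hi is Illumination.LOW)


class TestChildLog:
    def test_mode_record_type_enforced(self, sample_ccm_log):
        with pytest.raises(TypeError):
            ChildLog(child_id="x", mode=Mode.SCM, sessions=sample_ccm_log.sessions)

    def test_needs_a_session(self):
        with pytest.raises(ValueError):
            ChildLog(child_id="x", mode=Mode.CCM, sessions=())

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            CCMRecord(datetime(2024, 7, 23), Color.RED, Illumination.LOW, -1)
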