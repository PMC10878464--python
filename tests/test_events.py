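
import pytest

from palscore.events import (ActionEvent, CompressionRecord, EventLogError,
                             ScenarioConfig, ScenarioRecord, read_event_log,
                             record_to_dict, recognition_time,
                             validate_record, write_event_log)

CSV_MINIMAL = """\
team_id,group,t_seconds,action,attributes
T01,aid_used,27,pulse_check,pulse_result=absent
T01,aid_used,51,start_compressions,
T01,aid_used,70,position_board,
"""


def test_csv_parse_three_rows():
    rec = read_event_log(CSV_MINIMAL, format="csv")
    assert rec.team_id == "T01" and rec.group == "aid_used"
    assert [e.action for e in rec.events] == [
        "pulse_check", "start_compressions", "position_board"]
    assert [e.t for e in rec.events] == [27.0, 51.0, 70.0]


def test_unsorted_json_resorted_with_warning():
    rec = ScenarioRecord("T02", "aid_used", events=[
        ActionEvent(51, "start_compressions"),
        ActionEvent(27, "pulse_check", {"pulse_result": "absent"})])
    text = write_event_log(rec, format="json")
    with pytest.warns(UserWarning, match="re-sorted"):
        back = read_event_log(text, format="json")
    assert [e.t for e in back.events] == [27.0, 51.0]


def test_missing_required_attribute_names_line():
    bad = CSV_MINIMAL + "T01,aid_used,200,administer_adrenaline,route=IV\n"
    with pytest.raises(EventLogError, match=r"line 5.*dose_mg"):
        read_event_log(bad, format="csv")


def test_malformed_row_names_line_and_column():
    bad = CSV_MINIMAL.replace("27", "notanumber")
    with pytest.raises(EventLogError, match="t_seconds"):
        read_event_log(bad, format="csv")


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_round_trip_identity(fmt, cohort):
    for rec in cohort[:4]:
        back = read_event_log(write_event_log(rec, format=fmt), format=fmt)
        assert record_to_dict(back) == record_to_dict(rec)


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_round_trip_unicode_and_empty(fmt):
    rec = ScenarioRecord("équipe-1", "aid_not_used", events=[],
                         compressions=[])
    back = read_event_log(write_event_log(rec, format=fmt), format=fmt)
    assert back.team_id == "équipe-1"
    assert back.events == [] and back.compressions == []


def test_recognition_time_rules():
    mk = lambda evs: ScenarioRecord("T", "aid_used", events=evs)
    assert recognition_time(mk([ActionEvent(
        27, "pulse_check", {"pulse_result": "absent"})])) == 27
    assert recognition_time(mk([])) is None
    assert recognition_time(mk([
        ActionEvent(10, "pulse_check", {"pulse_result": "present"}),
        ActionEvent(25, "pulse_check", {"pulse_result": "absent"})])) == 25


def test_recognition_invariant_under_event_order():
    evs = [ActionEvent(40, "pulse_check", {"pulse_result": "absent"}),
           ActionEvent(12, "pulse_check", {"pulse_result": "absent"}),
           ActionEvent(5, "call_help")]
    rec = ScenarioRecord("T", "aid_used", events=evs)
    shuffled = ScenarioRecord("T", "aid_used", events=evs[::-1])
    assert recognition_time(rec) == recognition_time(shuffled) == 12


def test_validation_flags_errors_and_warnings():
    rec = ScenarioRecord("T", "aid_used", events=[
        ActionEvent(700, "call_help"),               # beyond duration
        ActionEvent(10, "pulse_check", {}),           # missing pulse_result
        ActionEvent(20, "teleport")],                 # unknown kind
        compressions=[CompressionRecord(5, 1.0, 2.0)])  # depth <= residual
    issues = validate_record(rec)
    sev = {(i.severity, i.location) for i in issues}
    assert ("error", "events[0]") in sev
    assert ("error", "events[1]") in sev
    assert ("warning", "events[2]") in sev
    assert any(i.location == "compressions[0]" and i.severity == "error"
               for i in issues)


def test_validation_accepts_synthetic_records(cohort):
    for rec in cohort:
        assert [i for i in validate_record(rec) if i.severity == "error"] == []


def test_events_at_duration_valid_after_rejected():
    cfg = ScenarioConfig(duration_s=600)
    ok = ScenarioRecord("T", "aid_used",
                        events=[ActionEvent(600.0, "call_help")], config=cfg)
    assert validate_record(ok) == []
    bad = ScenarioRecord("T", "aid_used",
                         events=[ActionEvent(600.01, "call_help")], config=cfg)
    assert any(i.severity == "error" for i in validate_record(bad))


def test_config_rejects_nonpositive_values():
    with pytest.raises(EventLogError):
        ScenarioConfig(patient_weight_kg=0)
    with pytest.raises(EventLogError):
        ScenarioConfig(duration_s=-1)
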