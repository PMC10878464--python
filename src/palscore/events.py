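"""Timestamped resuscitation event-log data model.

A simulated nonshockable pediatric cardiac arrest scenario is recorded as a
:class:`ScenarioRecord`: an ordered stream of discrete team actions
(:class:`ActionEvent`), a stream of individual chest compressions
(:class:`CompressionRecord`) and a :class:`ScenarioConfig` describing the
simulated patient and the scoring thresholds.  All times are seconds from
scenario start (t = 0); events are instantaneous.

Two serialization dialects are supported and round-trip losslessly:

* JSON — ``{team_id, group, config: {...}, events: [...], compressions: [...]}``
* CSV — columns ``team_id, group, t_seconds, action, attributes`` where
  ``attributes`` is a semicolon-separated ``key=value`` list.  Chest
  compressions travel as pseudo-action rows (``action=compression`` with
  ``depth_cm``/``release_residual_cm`` attributes) and the scenario config as
  a ``# config=<json>`` header comment, so that a single CSV file carries a
  complete record.
"""

from __future__ import annotations

import csv
import io
import json
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path


__all__ = [
    "ACTION_KINDS",
    "REQUIRED_ATTRIBUTES",
    "GROUPS",
    "ActionEvent",
    "CompressionRecord",
    "ScoringThresholds",
    "ScenarioConfig",
    "ScenarioRecord",
    "ValidationIssue",
    "EventLogError",
    "validate_record",
    "read_event_log",
    "write_event_log",
    "recognition_time",
]

#: Recognized action kinds.  Unknown kinds are preserved on read but flagged
#: as validation warnings so that extended logs still parse.
ACTION_KINDS = frozenset(
    {
        "pulse_check",
        "start_compressions",
        "stop_compressions",
        "position_board",
        "call_help",
        "start_ekg_monitor",
        "call_iv_io_access",
        "establish_iv_io",
        "call_adrenaline",
        "administer_adrenaline",
        "saline_flush",
        "call_blood_gas",
        "treat_reversible_cause",
        "deliver_shock",
        "administer_medication",
        "ventilation",
        "switch_compressor",
        "start_bag_mask",
    }
)

#: Attributes that must be present (per action kind) for a record to validate.
REQUIRED_ATTRIBUTES: dict[str, tuple[str, ...]] = {
    "pulse_check": ("pulse_result",),
    "administer_adrenaline": ("dose_mg", "dilution_mg_per_ml", "route"),
    "administer_medication": ("med_name",),
    "treat_reversible_cause": ("cause_id",),
}

GROUPS = ("aid_not_used", "aid_used")

_FLOAT_ATTRS = {"dose_mg", "dilution_mg_per_ml", "depth_cm", "release_residual_cm"}


class EventLogError(ValueError):
    """Raised for malformed or invalid event logs (parse or validation)."""


@dataclass(frozen=True)
class ActionEvent:
    """One discrete team action at time ``t`` seconds from scenario start."""

    t: float
    action: str
    attributes: dict = field(default_factory=dict)

    def attr(self, key: str, default=None):
        return self.attributes.get(key, default)


@dataclass(frozen=True)
class CompressionRecord:
    """One chest compression: instant of maximal displacement, depth and the
    residual displacement left at release (0 = complete chest recoil)."""

    t: float
    depth_cm: float
    release_residual_cm: float


@dataclass(frozen=True)
class ScoringThresholds:
    """Tunable scoring constants.

    Time windows are the deviation-checklist defaults (seconds, measured from
    recognition of the pulseless state unless noted); the remaining fields
    parameterize adrenaline quality checks, the 15:2 cycle tolerance, the
    compression-episode pause threshold and the chest-recoil band.
    """

    cpr_start_s: float = 30.0
    board_s: float = 60.0
    call_help_s: float = 60.0
    ekg_s: float = 60.0
    iv_io_call_s: float = 60.0
    first_adrenaline_call_s: float = 30.0
    first_adrenaline_admin_s: float = 180.0
    second_call_min_s: float = 180.0          # after first administration
    second_call_max_s: float = 300.0
    second_admin_s: float = 300.0             # after first administration
    dose_tolerance_fraction: float = 0.10     # strict: |err|/target < 0.10
    correct_dilution_mg_per_ml: float = 0.1   # 1:10,000 adrenaline
    flush_within_s: float = 30.0
    cycle_compressions_min: int = 13          # 15:2 ratio tolerance band
    cycle_compressions_max: int = 17
    cycle_ventilations: int = 2
    cycle_conform_fraction: float = 0.8
    min_compressor_switches: int = 2
    pause_threshold_s: float = 2.0            # compression-episode gap
    recoil_residual_cm: float = 0.5           # complete-recoil residual bound

    def __post_init__(self):
        for name in (
            "cpr_start_s", "board_s", "call_help_s", "ekg_s", "iv_io_call_s",
            "first_adrenaline_call_s", "first_adrenaline_admin_s",
            "second_call_min_s", "second_call_max_s", "second_admin_s",
            "dose_tolerance_fraction", "correct_dilution_mg_per_ml",
            "flush_within_s", "cycle_conform_fraction", "pause_threshold_s",
            "recoil_residual_cm",
        ):
            if getattr(self, name) <= 0:
                raise EventLogError(f"threshold {name} must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario-level parameters for one simulated arrest.

    ``patient_weight_kg`` defaults to 10 kg (an arbitrary but typical
    pediatric weight; the scored adrenaline dose scales with it).
    ``duration_s`` defaults to the standard 10-minute scenario.
    """

    patient_weight_kg: float = 10.0
    duration_s: float = 600.0
    rhythm: str = "nonshockable"
    required_reversible_causes: frozenset = frozenset({"hypovolemia"})
    allowed_cause_medications: frozenset = frozenset({"saline_bolus"})
    thresholds: ScoringThresholds = field(default_factory=ScoringThresholds)

    def __post_init__(self):
        if self.patient_weight_kg <= 0:
            raise EventLogError("patient_weight_kg must be positive")
        if self.duration_s <= 0:
            raise EventLogError("duration_s must be positive")
        if self.rhythm not in ("nonshockable", "shockable"):
            raise EventLogError(f"unknown rhythm {self.rhythm!r}")
        # frozensets may arrive as lists from JSON
        object.__setattr__(
            self, "required_reversible_causes",
            frozenset(self.required_reversible_causes))
        object.__setattr__(
            self, "allowed_cause_medications",
            frozenset(self.allowed_cause_medications))
        if isinstance(self.thresholds, dict):
            object.__setattr__(self, "thresholds",
                               ScoringThresholds(**self.thresholds))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["required_reversible_causes"] = sorted(self.required_reversible_causes)
        d["allowed_cause_medications"] = sorted(self.allowed_cause_medications)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str          # "error" | "warning"
    location: str          # e.g. "events[3]" or a field name
    message: str


@dataclass
class ScenarioRecord:
    """One team's complete scenario log."""

    team_id: str
    group: str
    events: list = field(default_factory=list)
    compressions: list = field(default_factory=list)
    config: ScenarioConfig = field(default_factory=ScenarioConfig)

    def sorted(self) -> "ScenarioRecord":
        """Return a copy with events and compressions sorted by time."""
        return replace(
            self,
            events=sorted(self.events, key=lambda e: e.t),
            compressions=sorted(self.compressions, key=lambda c: c.t),
        )

    def events_of(self, action: str) -> list:
        return [e for e in self.events if e.action == action]

    def first_event(self, action: str):
        for e in self.events:
            if e.action == action:
                return e
        return None


def validate_record(record: ScenarioRecord) -> list[ValidationIssue]:
    """Validate a record, returning a list of issues (empty when clean).

    Errors: times outside ``[0, duration_s]``, missing required attributes,
    unsorted streams, non-physical compression geometry, bad group labels.
    Warnings: unrecognized action kinds (preserved, not rejected).
    """
    issues: list[ValidationIssue] = []
    dur = record.config.duration_s
    if record.group not in GROUPS:
        issues.append(ValidationIssue("error", "group",
                                      f"unknown group {record.group!r}"))
    prev = -math.inf
    for i, e in enumerate(record.events):
        loc = f"events[{i}]"
        if e.t < 0 or e.t > dur:
            issues.append(ValidationIssue(
                "error", loc, f"t={e.t} outside [0, {dur}]"))
        if e.t < prev:
            issues.append(ValidationIssue("error", loc, "events not sorted by t"))
        prev = e.t
        if e.action not in ACTION_KINDS:
            issues.append(ValidationIssue(
                "warning", loc, f"unknown action kind {e.action!r}"))
        for key in REQUIRED_ATTRIBUTES.get(e.action, ()):
            if key not in e.attributes:
                issues.append(ValidationIssue(
                    "error", loc,
                    f"{e.action} missing required attribute {key!r}"))
    prev = -math.inf
    for i, c in enumerate(record.compressions):
        loc = f"compressions[{i}]"
        if c.t < 0 or c.t > dur:
            issues.append(ValidationIssue(
                "error", loc, f"t={c.t} outside [0, {dur}]"))
        if c.t < prev:
            issues.append(ValidationIssue("error", loc,
                                          "compressions not sorted by t"))
        prev = c.t
        if c.depth_cm <= 0:
            issues.append(ValidationIssue("error", loc, "depth_cm must be > 0"))
        if c.release_residual_cm < 0:
            issues.append(ValidationIssue(
                "error", loc, "release_residual_cm must be >= 0"))
        if c.depth_cm <= c.release_residual_cm:
            issues.append(ValidationIssue(
                "error", loc, "depth_cm must exceed release_residual_cm"))
    return issues


def recognition_time(record: ScenarioRecord):
    """Time of recognition of the pulseless state, or ``None``.

    Recognition is the first ``pulse_check`` event whose ``pulse_result`` is
    ``"absent"``; it anchors most timed checklist items.  Input event order
    does not matter (times are scanned, not positions).
    """
    best = None
    for e in record.events:
        if e.action == "pulse_check" and e.attr("pulse_result") == "absent":
            if best is None or e.t < best:
                best = e.t
    return best


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _format_attrs(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(text: str, line_no: int) -> dict:
    attrs: dict = {}
    if not text:
        return attrs
    for part in text.split(";"):
        if not part:
            continue
        if "=" not in part:
            raise EventLogError(
                f"line {line_no}, column 'attributes': malformed pair {part!r}")
        k, v = part.split("=", 1)
        if k in _FLOAT_ATTRS:
            try:
                attrs[k] = float(v)
            except ValueError:
                raise EventLogError(
                    f"line {line_no}, column 'attributes': "
                    f"{k} must be numeric, got {v!r}") from None
        else:
            attrs[k] = v
    return attrs


def record_to_dict(record: ScenarioRecord) -> dict:
    return {
        "team_id": record.team_id,
        "group": record.group,
        "config": record.config.to_dict(),
        "events": [
            {"t": e.t, "action": e.action, "attributes": dict(e.attributes)}
            for e in record.events
        ],
        "compressions": [
            {"t": c.t, "depth_cm": c.depth_cm,
             "release_residual_cm": c.release_residual_cm}
            for c in record.compressions
        ],
    }


def record_from_dict(d: dict) -> ScenarioRecord:
    return ScenarioRecord(
        team_id=d["team_id"],
        group=d["group"],
        config=ScenarioConfig.from_dict(d.get("config", {})),
        events=[ActionEvent(float(e["t"]), e["action"],
                            dict(e.get("attributes", {})))
                for e in d.get("events", [])],
        compressions=[CompressionRecord(float(c["t"]), float(c["depth_cm"]),
                                        float(c["release_residual_cm"]))
                      for c in d.get("compressions", [])],
    )


def write_event_log(record: ScenarioRecord, format: str = "json") -> str:
    """Serialize a record to text in the named dialect (``csv`` or ``json``)."""
    if format == "json":
        return json.dumps(record_to_dict(record), indent=1)
    if format == "csv":
        buf = io.StringIO()
        buf.write("# record=" + json.dumps(
            {"team_id": record.team_id, "group": record.group,
             "config": record.config.to_dict()}, ensure_ascii=False) + "\n")
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["team_id", "group", "t_seconds", "action", "attributes"])
        for e in record.events:
            w.writerow([record.team_id, record.group, repr(e.t), e.action,
                        _format_attrs(e.attributes)])
        for c in record.compressions:
            attrs = {"depth_cm": c.depth_cm,
                     "release_residual_cm": c.release_residual_cm}
            w.writerow([record.team_id, record.group, repr(c.t),
                        "compression", _format_attrs(attrs)])
        return buf.getvalue()
    raise EventLogError(f"unsupported format {format!r}")


def _read_csv(text: str) -> ScenarioRecord:
    config = ScenarioConfig()
    team_id, group = None, None
    lines = text.splitlines()
    data_lines: list[tuple[int, str]] = []
    for i, line in enumerate(lines, start=1):
        if line.startswith("# record="):
            head = json.loads(line[len("# record="):])
            team_id, group = head.get("team_id"), head.get("group")
            config = ScenarioConfig.from_dict(head.get("config", {}))
        elif line.startswith("#") or not line.strip():
            continue
        else:
            data_lines.append((i, line))
    if not data_lines:
        raise EventLogError("empty CSV event log")
    header_no, header = data_lines[0]
    cols = next(csv.reader([header]))
    expected = ["team_id", "group", "t_seconds", "action", "attributes"]
    if cols != expected:
        raise EventLogError(
            f"line {header_no}: header must be {','.join(expected)}")
    events, compressions = [], []
    for line_no, line in data_lines[1:]:
        row = next(csv.reader([line]))
        if len(row) != 5:
            raise EventLogError(f"line {line_no}: expected 5 columns, got {len(row)}")
        tid, grp, t_s, action, attr_text = row
        team_id = team_id or tid
        group = group or grp
        try:
            t = float(t_s)
        except ValueError:
            raise EventLogError(
                f"line {line_no}, column 't_seconds': not a number: {t_s!r}"
            ) from None
        attrs = _parse_attrs(attr_text, line_no)
        if action == "compression":
            try:
                compressions.append(CompressionRecord(
                    t, attrs["depth_cm"], attrs["release_residual_cm"]))
            except KeyError as k:
                raise EventLogError(
                    f"line {line_no}: compression row missing {k}") from None
        else:
            for key in REQUIRED_ATTRIBUTES.get(action, ()):
                if key not in attrs:
                    raise EventLogError(
                        f"line {line_no}: {action} missing required "
                        f"attribute {key!r}")
            events.append(ActionEvent(t, action, attrs))
    return ScenarioRecord(team_id=team_id or "", group=group or "",
                          events=events, compressions=compressions,
                          config=config)


def read_event_log(source, format: str = "json") -> ScenarioRecord:
    """Read a scenario record from a path, stream or string.

    Events and compressions are re-sorted by time on read; a warning is
    emitted when the input was out of order.  Unknown action kinds are
    preserved (surfaced by :func:`validate_record` as warnings); missing
    required attributes raise :class:`EventLogError` naming the offence.
    """
    if isinstance(source, (str, Path)) and (
            isinstance(source, Path) or "\n" not in source):
        p = Path(source)
        if p.exists():
            text = p.read_text()
        else:
            text = str(source)
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()

    if format == "json":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise EventLogError(f"malformed JSON: {exc}") from None
        for i, e in enumerate(d.get("events", [])):
            for key in REQUIRED_ATTRIBUTES.get(e.get("action", ""), ()):
                if key not in e.get("attributes", {}):
                    raise EventLogError(
                        f"events[{i}]: {e['action']} missing required "
                        f"attribute {key!r}")
        record = record_from_dict(d)
    elif format == "csv":
        record = _read_csv(text)
    else:
        raise EventLogError(f"unsupported format {format!r}")

    if any(b.t < a.t for a, b in zip(record.events, record.events[1:])) or any(
            b.t < a.t for a, b in zip(record.compressions,
                                      record.compressions[1:])):
        warnings.warn(f"event log {record.team_id!r}: input out of time "
                      "order; re-sorted", stacklevel=2)
        record = record.sorted()
    return record
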