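"""Config-driven performance rubric for the asystole scenario.

A rubric is a list of items, each awarding full points when a declarative
predicate over the scenario record holds, optional partial points when a
weaker predicate holds, and 0 otherwise.  Higher totals mean better
performance.  The shipped default approximates a validated seven-item
clinical performance instrument for asystole scenarios totalling 0-13;
the original item wording is not public, so the default is explicitly
provisional — the real instrument can be loaded from YAML/JSON once
transcribed.

Predicate primitives (composable with ``all_of`` / ``any_of``):

``action_present``
    an event of the given action kind occurs (optionally with an attribute
    equal to a value).
``action_within``
    the first such event occurs within ``seconds`` of an anchor
    (``scenario_start`` or ``recognition``).
``adrenaline_dose_correct``
    some adrenaline administration is within the configured dose tolerance
    of 0.01 mg/kg.
``no_action``
    no event of the given action kind occurs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .events import ScenarioRecord, recognition_time

__all__ = ["Rubric", "RubricItem", "CPTScore", "load_rubric", "score_cpt",
           "DEFAULT_RUBRIC_SPEC", "default_rubric"]


class RubricError(ValueError):
    pass


def _anchor_time(record, anchor):
    if anchor == "scenario_start":
        return 0.0
    if anchor == "recognition":
        return recognition_time(record)
    raise RubricError(f"unknown anchor {anchor!r}")


def _matching_events(record, action, attr_equals):
    evs = record.events_of(action)
    if attr_equals:
        evs = [e for e in evs
               if all(e.attr(k) == v for k, v in attr_equals.items())]
    return evs


def _eval(pred: dict, record: ScenarioRecord) -> bool:
    kind = pred.get("kind")
    if kind == "action_present":
        return bool(_matching_events(record, pred["action"],
                                     pred.get("attr_equals")))
    if kind == "action_within":
        anchor = _anchor_time(record, pred.get("anchor", "scenario_start"))
        if anchor is None:
            return False
        evs = _matching_events(record, pred["action"],
                               pred.get("attr_equals"))
        return any(anchor <= e.t <= anchor + pred["seconds"] for e in evs)
    if kind == "adrenaline_dose_correct":
        target = 0.01 * record.config.patient_weight_kg
        tol = record.config.thresholds.dose_tolerance_fraction
        return any(
            e.attr("dose_mg") is not None
            and abs(e.attr("dose_mg") - target) / target < tol
            for e in record.events_of("administer_adrenaline"))
    if kind == "no_action":
        return not record.events_of(pred["action"])
    if kind == "all_of":
        return all(_eval(p, record) for p in pred["predicates"])
    if kind == "any_of":
        return any(_eval(p, record) for p in pred["predicates"])
    raise RubricError(f"unknown predicate primitive {kind!r}")


_PRIMITIVES = {"action_present", "action_within", "adrenaline_dose_correct",
               "no_action", "all_of", "any_of"}


def _check_predicate(pred, where):
    if not isinstance(pred, dict) or "kind" not in pred:
        raise RubricError(f"{where}: predicate must be a mapping with 'kind'")
    kind = pred["kind"]
    if kind not in _PRIMITIVES:
        raise RubricError(f"{where}: unknown predicate primitive {kind!r}")
    if kind in ("all_of", "any_of"):
        for i, p in enumerate(pred.get("predicates", [])):
            _check_predicate(p, f"{where}.predicates[{i}]")
    if kind == "action_within" and "seconds" not in pred:
        raise RubricError(f"{where}: action_within requires 'seconds'")


@dataclass(frozen=True)
class RubricItem:
    id: str
    description: str
    points_full: int
    predicate_full: dict
    points_partial: int | None = None
    predicate_partial: dict | None = None

    def award(self, record: ScenarioRecord) -> int:
        if _eval(self.predicate_full, record):
            return self.points_full
        if (self.predicate_partial is not None
                and _eval(self.predicate_partial, record)):
            return self.points_partial or 0
        return 0


@dataclass(frozen=True)
class Rubric:
    name: str
    items: tuple
    max_score: int


@dataclass(frozen=True)
class CPTScore:
    team_id: str
    group: str
    awarded: dict          # item id -> points
    total: int
    max_score: int


#: Provisional default asystole rubric: seven items, total 13.  Point split
#: chosen so that presence/timeliness of the core tasks dominates; this is
#: an approximation standing in for the validated instrument's (non-public)
#: item definitions, and is replaceable via load_rubric.
DEFAULT_RUBRIC_SPEC = {
    "name": "asystole-default (provisional approximation)",
    "max_score": 13,
    "items": [
        {"id": "pulse_check", "description":
            "Pulse checked promptly (within 60 s of scenario start)",
         "points_full": 2,
         "predicate_full": {"kind": "action_within", "action": "pulse_check",
                            "seconds": 60, "anchor": "scenario_start"},
         "points_partial": 1,
         "predicate_partial": {"kind": "action_present",
                               "action": "pulse_check"}},
        {"id": "cpr_started", "description":
            "Chest compressions started within 60 s of recognition",
         "points_full": 2,
         "predicate_full": {"kind": "action_within",
                            "action": "start_compressions",
                            "seconds": 60, "anchor": "recognition"},
         "points_partial": 1,
         "predicate_partial": {"kind": "action_present",
                               "action": "start_compressions"}},
        {"id": "bag_mask", "description":
            "Bag-mask ventilation started within 90 s of recognition",
         "points_full": 2,
         "predicate_full": {"kind": "action_within",
                            "action": "start_bag_mask",
                            "seconds": 90, "anchor": "recognition"},
         "points_partial": 1,
         "predicate_partial": {"kind": "action_present",
                               "action": "start_bag_mask"}},
        {"id": "vascular_access", "description":
            "IV/IO access established within 300 s of scenario start",
         "points_full": 2,
         "predicate_full": {"kind": "action_within",
                            "action": "establish_iv_io",
                            "seconds": 300, "anchor": "scenario_start"},
         "points_partial": 1,
         "predicate_partial": {"kind": "action_present",
                               "action": "establish_iv_io"}},
        {"id": "adrenaline_given", "description":
            "Adrenaline administered within 300 s of recognition",
         "points_full": 2,
         "predicate_full": {"kind": "action_within",
                            "action": "administer_adrenaline",
                            "seconds": 300, "anchor": "recognition"},
         "points_partial": 1,
         "predicate_partial": {"kind": "action_present",
                               "action": "administer_adrenaline"}},
        {"id": "adrenaline_dose", "description":
            "Adrenaline dose correct (0.01 mg/kg within tolerance)",
         "points_full": 2,
         "predicate_full": {"kind": "adrenaline_dose_correct"}},
        {"id": "rhythm_management", "description":
            "Nonshockable rhythm recognized (absent pulse identified) and "
            "no shock delivered",
         "points_full": 1,
         "predicate_full": {"kind": "all_of", "predicates": [
             {"kind": "action_present", "action": "pulse_check",
              "attr_equals": {"pulse_result": "absent"}},
             {"kind": "no_action", "action": "deliver_shock"}]}},
    ],
}


def load_rubric(config) -> Rubric:
    """Compile a rubric from a mapping, YAML/JSON text, or a file path.

    Rejects rubrics whose full points do not sum to ``max_score``, whose
    partial points are not strictly below full points, or that reference an
    unknown predicate primitive (error names it).
    """
    if isinstance(config, (str, Path)):
        p = Path(config)
        text = p.read_text() if p.exists() else str(config)
        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise RubricError("rubric config must be a mapping")
    items = []
    for i, item in enumerate(config.get("items", [])):
        where = f"items[{i}]"
        _check_predicate(item["predicate_full"], where + ".predicate_full")
        partial_pred = item.get("predicate_partial")
        partial_pts = item.get("points_partial")
        if partial_pred is not None:
            _check_predicate(partial_pred, where + ".predicate_partial")
            if partial_pts is None or not partial_pts < item["points_full"]:
                raise RubricError(
                    f"{where}: points_partial must be < points_full")
        items.append(RubricItem(
            id=str(item.get("id", i)),
            description=item.get("description", ""),
            points_full=int(item["points_full"]),
            predicate_full=item["predicate_full"],
            points_partial=partial_pts,
            predicate_partial=partial_pred,
        ))
    if not items:
        raise RubricError("rubric has no items")
    max_score = int(config.get("max_score",
                               sum(i.points_full for i in items)))
    total_full = sum(i.points_full for i in items)
    if total_full != max_score:
        raise RubricError(f"full points sum to {total_full}, "
                          f"but max_score is {max_score}")
    return Rubric(name=str(config.get("name", "rubric")),
                  items=tuple(items), max_score=max_score)


def default_rubric() -> Rubric:
    return load_rubric(json.loads(json.dumps(DEFAULT_RUBRIC_SPEC)))


def score_cpt(record: ScenarioRecord, rubric: Rubric | None = None) -> CPTScore:
    """Score a record on a rubric (default: the shipped asystole rubric)."""
    rubric = rubric or default_rubric()
    awarded = {item.id: item.award(record) for item in rubric.items}
    return CPTScore(team_id=record.team_id, group=record.group,
                    awarded=awarded, total=sum(awarded.values()),
                    max_score=rubric.max_score)
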