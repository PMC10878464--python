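"""15-item guideline-deviation checklist for nonshockable pediatric arrest.

Each item encodes one recommended resuscitation task for a nonshockable
pediatric cardiac arrest and scores 0 when the task is performed well and on
time, 1 when it is omitted, late or incorrect.  The team total therefore
ranges from 0 (perfect adherence) to 15.  Timed items are anchored at
*recognition of the pulseless state* (first pulse check reporting an absent
pulse); when the pulseless state is never recognized, every
recognition-anchored item is a deviation.

Item summary (windows in seconds from recognition unless noted; all windows
inclusive, thresholds configurable via :class:`~palscore.events.ScoringThresholds`):

1.  chest compressions started within 30
2.  CPR board positioned within 60
3.  compression:ventilation cycles conform to 15:2 (>= 80% of completed
    cycles have 13-17 compressions followed by exactly 2 ventilations)
4.  help called within 60
5.  compressors switched more than once during CPR (>= 2 switch events)
6.  EKG monitoring started within 60
7.  IV/IO access called within 60
8.  first adrenaline called within 30
9.  first adrenaline administered within 180 at 0.01 mg/kg (strict < 10%
    relative error), 0.1 mg/ml dilution, IV or IO route, during an active
    compression episode, followed by a saline flush within 30 s
10. second adrenaline called 180-300 s after the first administration
11. second adrenaline administered with item-9 quality within 300 s of the
    first administration
12. blood gas called during the arrest
13. every configured reversible cause treated
14. no shock delivered (the rhythm is nonshockable)
15. no medication other than adrenaline administered (cause-directed
    treatments configured in ``allowed_cause_medications`` are exempt)
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cpr import compression_episodes
from .events import ScenarioRecord, recognition_time

__all__ = ["ITEM_DESCRIPTIONS", "ItemResult", "CDevScore", "score_item",
           "score_team", "cohort_item_frequencies", "scores_to_frame"]

ITEM_DESCRIPTIONS = {
    1: "CPR started within 30 s from recognition of pulseless state",
    2: "CPR board positioned within 60 s from recognition of pulseless state",
    3: "Compression:ventilation ratio 15:2",
    4: "Help called within 60 s from recognition of pulseless state",
    5: "Compressors switched more than once during CPR",
    6: "EKG monitoring started within 60 s from recognition of pulseless state",
    7: "IV/IO access called within 60 s from recognition of pulseless state",
    8: "First adrenaline called within 30 s from recognition of pulseless state",
    9: ("First adrenaline administered at correct dose, dilution and route, "
        "flushed, during compressions, within 180 s from recognition"),
    10: "Second adrenaline called between 3 and 5 min from first administration",
    11: ("Second adrenaline administered at correct dose, dilution and route, "
         "flushed, during compressions, within 5 min of the first"),
    12: "Blood gas called during cardiac arrest",
    13: "Reversible causes treated",
    14: "Shock not administered",
    15: "Medications other than adrenaline not administered",
}


@dataclass(frozen=True)
class ItemResult:
    item_id: int
    status: str                 # "correct" | "deviation"
    reason: str = ""            # non-empty on deviation
    measured_time_s: float | None = None

    @property
    def deviation(self) -> int:
        return 1 if self.status == "deviation" else 0


@dataclass(frozen=True)
class CDevScore:
    team_id: str
    group: str
    items: tuple            # 15 ItemResults, item_ids 1..15
    total: int              # number of deviations, 0..15

    def item(self, item_id: int) -> ItemResult:
        return self.items[item_id - 1]

    @property
    def deviations(self) -> tuple:
        return tuple(r.deviation for r in self.items)


def _correct(item_id, t=None):
    return ItemResult(item_id, "correct", "", t)


def _dev(item_id, reason, t=None):
    return ItemResult(item_id, "deviation", reason, t)


def _timed_item(record, item_id, action, window, label):
    """Generic 'first <action> within <window> of recognition' item."""
    rec = recognition_time(record)
    if rec is None:
        return _dev(item_id, "pulseless state never recognized")
    ev = record.first_event(action)
    if ev is None:
        return _dev(item_id, f"{label} never performed")
    elapsed = ev.t - rec
    if elapsed <= window:
        return _correct(item_id, ev.t)
    return _dev(item_id, f"{label} at {elapsed:.1f} s from recognition "
                         f"(> {window:g} s)", ev.t)


def _cpr_start_time(record):
    """Start of CPR: first compression record, else first start_compressions
    event."""
    if record.compressions:
        return record.compressions[0].t
    ev = record.first_event("start_compressions")
    return ev.t if ev is not None else None


def _adrenaline_quality(record, admin, episodes):
    """Check dose/dilution/route/flush/during-compressions for one
    administration event; returns a list of failure reasons (empty = ok)."""
    th = record.config.thresholds
    reasons = []
    target = 0.01 * record.config.patient_weight_kg
    dose = admin.attr("dose_mg")
    if dose is None or not abs(dose - target) / target < th.dose_tolerance_fraction:
        reasons.append(f"dose {dose} mg deviates >= "
                       f"{100 * th.dose_tolerance_fraction:g}% from "
                       f"{target:g} mg")
    dil = admin.attr("dilution_mg_per_ml")
    if dil is None or abs(dil - th.correct_dilution_mg_per_ml) > 1e-9:
        reasons.append(f"dilution {dil} mg/ml is not "
                       f"{th.correct_dilution_mg_per_ml:g} mg/ml")
    if admin.attr("route") not in ("IV", "IO"):
        reasons.append(f"route {admin.attr('route')!r} is not IV or IO")
    if not any(ep.contains(admin.t) for ep in episodes):
        reasons.append("not administered while compressions were being "
                       "performed")
    if not any(admin.t < f.t <= admin.t + th.flush_within_s
               for f in record.events_of("saline_flush")):
        reasons.append(f"no saline flush within {th.flush_within_s:g} s")
    return reasons


def _cycles(record):
    """Completed compression:ventilation cycles as (n_compressions,
    n_ventilations) pairs.

    The merged compression/ventilation timeline is split into alternating
    runs; each compression run followed by a ventilation run is one
    completed cycle.  Trailing compressions with no subsequent ventilation
    are not a completed cycle.
    """
    timeline = sorted(
        [(c.t, "C") for c in record.compressions]
        + [(e.t, "V") for e in record.events_of("ventilation")])
    cycles = []
    n_c = n_v = 0
    for _, kind in timeline:
        if kind == "C":
            if n_v:                       # ventilation run just ended
                if n_c:
                    cycles.append((n_c, n_v))
                n_c = n_v = 0
            n_c += 1
        else:
            n_v += 1
    if n_c and n_v:
        cycles.append((n_c, n_v))
    return cycles


def score_item(record: ScenarioRecord, item_id: int) -> ItemResult:
    """Score one checklist item; see the module docstring for item logic."""
    th = record.config.thresholds
    rec = recognition_time(record)

    if item_id == 1:
        return _timed_item(record, 1, "start_compressions", th.cpr_start_s,
                           "CPR")
    if item_id == 2:
        return _timed_item(record, 2, "position_board", th.board_s,
                           "CPR board")
    if item_id == 3:
        cycles = _cycles(record)
        if not cycles:
            return _dev(3, "no completed compression:ventilation cycles")
        ok = sum(th.cycle_compressions_min <= c <= th.cycle_compressions_max
                 and v == th.cycle_ventilations for c, v in cycles)
        frac = ok / len(cycles)
        if frac >= th.cycle_conform_fraction:
            return _correct(3)
        return _dev(3, f"only {100 * frac:.0f}% of {len(cycles)} cycles "
                       "conform to 15:2")
    if item_id == 4:
        return _timed_item(record, 4, "call_help", th.call_help_s, "help call")
    if item_id == 5:
        start = _cpr_start_time(record)
        if start is None:
            return _dev(5, "CPR never started")
        n = sum(start <= e.t <= record.config.duration_s
                for e in record.events_of("switch_compressor"))
        if n >= th.min_compressor_switches:
            return _correct(5)
        return _dev(5, f"compressors switched {n} time(s) "
                       f"(need >= {th.min_compressor_switches})")
    if item_id == 6:
        return _timed_item(record, 6, "start_ekg_monitor", th.ekg_s,
                           "EKG monitoring")
    if item_id == 7:
        return _timed_item(record, 7, "call_iv_io_access", th.iv_io_call_s,
                           "IV/IO access call")
    if item_id == 8:
        return _timed_item(record, 8, "call_adrenaline",
                           th.first_adrenaline_call_s, "first adrenaline call")

    admins = record.events_of("administer_adrenaline")
    episodes = compression_episodes(record.compressions, th.pause_threshold_s)

    if item_id == 9:
        if rec is None:
            return _dev(9, "pulseless state never recognized")
        if not admins:
            return _dev(9, "adrenaline never administered")
        first = admins[0]
        reasons = _adrenaline_quality(record, first, episodes)
        elapsed = first.t - rec
        if elapsed > th.first_adrenaline_admin_s:
            reasons.insert(0, f"administered at {elapsed:.1f} s from "
                              f"recognition (> {th.first_adrenaline_admin_s:g} s)")
        if reasons:
            return _dev(9, "; ".join(reasons), first.t)
        return _correct(9, first.t)
    if item_id == 10:
        if not admins:
            return _dev(10, "first adrenaline never administered")
        t1 = admins[0].t
        lo, hi = t1 + th.second_call_min_s, t1 + th.second_call_max_s
        for e in record.events_of("call_adrenaline"):
            if lo <= e.t <= hi:
                return _correct(10, e.t)
        return _dev(10, "no adrenaline call between 3 and 5 min after first "
                        "administration")
    if item_id == 11:
        if not admins:
            return _dev(11, "first adrenaline never administered")
        if len(admins) < 2:
            return _dev(11, "second adrenaline never administered")
        t1, second = admins[0].t, admins[1]
        reasons = _adrenaline_quality(record, second, episodes)
        gap = second.t - t1
        if gap > th.second_admin_s:
            reasons.insert(0, f"administered {gap:.1f} s after the first "
                              f"(> {th.second_admin_s:g} s)")
        if reasons:
            return _dev(11, "; ".join(reasons), second.t)
        return _correct(11, second.t)
    if item_id == 12:
        ev = record.first_event("call_blood_gas")
        if ev is not None and ev.t <= record.config.duration_s:
            return _correct(12, ev.t)
        return _dev(12, "blood gas never called")
    if item_id == 13:
        treated = {e.attr("cause_id")
                   for e in record.events_of("treat_reversible_cause")}
        missing = record.config.required_reversible_causes - treated
        if missing:
            return _dev(13, "untreated reversible cause(s): "
                            + ", ".join(sorted(missing)))
        return _correct(13)
    if item_id == 14:
        ev = record.first_event("deliver_shock")
        if ev is None:
            return _correct(14)
        return _dev(14, "shock delivered in a nonshockable rhythm", ev.t)
    if item_id == 15:
        allowed = record.config.allowed_cause_medications
        for e in record.events_of("administer_medication"):
            if e.attr("med_name") not in allowed:
                return _dev(15, f"medication {e.attr('med_name')!r} "
                                "administered", e.t)
        return _correct(15)
    raise ValueError(f"invalid item_id {item_id}; must be 1..15")


def score_team(record: ScenarioRecord) -> CDevScore:
    """Score all 15 items; total = number of deviations."""
    items = tuple(score_item(record, i) for i in range(1, 16))
    return CDevScore(team_id=record.team_id, group=record.group, items=items,
                     total=sum(r.deviation for r in items))


def cohort_item_frequencies(scores) -> pd.DataFrame:
    """Per-item correct counts and percentages over a cohort.

    Returns a frame indexed by item_id with columns ``description``,
    ``n_correct``, ``n_teams``, ``pct_correct`` and ``pct_deviation``
    (the complement of ``pct_correct``).
    """
    scores = list(scores)
    if not scores:
        raise ValueError("empty score list")
    n = len(scores)
    rows = []
    for i in range(1, 16):
        n_correct = sum(1 - s.item(i).deviation for s in scores)
        pct = 100.0 * n_correct / n
        rows.append({"item_id": i, "description": ITEM_DESCRIPTIONS[i],
                     "n_correct": n_correct, "n_teams": n,
                     "pct_correct": pct, "pct_deviation": 100.0 - pct})
    return pd.DataFrame(rows).set_index("item_id")


def scores_to_frame(scores) -> pd.DataFrame:
    """Team-by-item 0/1 deviation matrix with group and total columns."""
    rows = []
    for s in scores:
        row = {"team_id": s.team_id, "group": s.group}
        row.update({f"item_{i}": s.item(i).deviation for i in range(1, 16)})
        row["total"] = s.total
        rows.append(row)
    return pd.DataFrame(rows)
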