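"""Independent brute-force re-evaluation of the deviation checklist.

Deliberately written as plain linear scans over the raw record, sharing no
helper code with the package, so it can serve as an oracle for the scorer.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom


def _recognition(record):
    times = [e.t for e in record.events
             if e.action == "pulse_check"
             and e.attributes.get("pulse_result") == "absent"]
    return min(times) if times else None


def _episodes_brute(record):
    """(start, end) spans of compression runs, gap threshold from config."""
    gap = record.config.thresholds.pause_threshold_s
    ts = [c.t for c in record.compressions]
    spans = []
    for t in ts:
        if spans and t - spans[-1][1] <= gap:
            spans[-1][1] = t
        else:
            spans.append([t, t])
    return spans


def _first_t(record, action):
    ts = [e.t for e in record.events if e.action == action]
    return min(ts) if ts else None


def _quality_ok(record, admin, spans):
    th = record.config.thresholds
    target = 0.01 * record.config.patient_weight_kg
    dose = admin.attributes.get("dose_mg")
    if dose is None or abs(dose - target) / target >= th.dose_tolerance_fraction:
        return False
    if abs(admin.attributes.get("dilution_mg_per_ml", -1)
           - th.correct_dilution_mg_per_ml) > 1e-9:
        return False
    if admin.attributes.get("route") not in ("IV", "IO"):
        return False
    if not any(s <= admin.t <= e for s, e in spans):
        return False
    flushes = [e.t for e in record.events if e.action == "saline_flush"]
    return any(admin.t < f <= admin.t + th.flush_within_s for f in flushes)


def oracle_deviations(record):
    """15-vector of 0/1 deviations, recomputed by direct rule evaluation."""
    th = record.config.thresholds
    rec = _recognition(record)
    dur = record.config.duration_s
    dev = []

    def window_item(action, w):
        t = _first_t(record, action)
        return 1 if (rec is None or t is None or t - rec > w) else 0

    dev.append(window_item("start_compressions", th.cpr_start_s))      # 1
    dev.append(window_item("position_board", th.board_s))              # 2

    # 3: completed cycles from the merged timeline
    merged = sorted([(c.t, 0) for c in record.compressions]
                    + [(e.t, 1) for e in record.events
                       if e.action == "ventilation"])
    cycles, nc, nv = [], 0, 0
    for _, is_vent in merged:
        if is_vent:
            nv += 1
        else:
            if nv > 0:
                if nc > 0:
                    cycles.append((nc, nv))
                nc, nv = 0, 0
            nc += 1
    if nc and nv:
        cycles.append((nc, nv))
    if not cycles:
        dev.append(1)
    else:
        good = [1 for c, v in cycles
                if th.cycle_compressions_min <= c <= th.cycle_compressions_max
                and v == th.cycle_ventilations]
        dev.append(0 if sum(good) / len(cycles) >= th.cycle_conform_fraction
                   else 1)

    dev.append(window_item("call_help", th.call_help_s))               # 4

    # 5: compressor switches during CPR
    cts = [c.t for c in record.compressions]
    start_ev = _first_t(record, "start_compressions")
    cpr_start = min(cts) if cts else start_ev
    if cpr_start is None:
        dev.append(1)
    else:
        n_sw = sum(1 for e in record.events if e.action == "switch_compressor"
                   and cpr_start <= e.t <= dur)
        dev.append(0 if n_sw >= th.min_compressor_switches else 1)

    dev.append(window_item("start_ekg_monitor", th.ekg_s))             # 6
    dev.append(window_item("call_iv_io_access", th.iv_io_call_s))      # 7
    dev.append(window_item("call_adrenaline", th.first_adrenaline_call_s))  # 8

    spans = _episodes_brute(record)
    admins = sorted([e for e in record.events
                     if e.action == "administer_adrenaline"],
                    key=lambda e: e.t)
    # 9
    if rec is None or not admins:
        dev.append(1)
    else:
        a = admins[0]
        ok = (a.t - rec <= th.first_adrenaline_admin_s
              and _quality_ok(record, a, spans))
        dev.append(0 if ok else 1)
    # 10
    if not admins:
        dev.append(1)
    else:
        t1 = admins[0].t
        calls = [e.t for e in record.events if e.action == "call_adrenaline"]
        ok = any(t1 + th.second_call_min_s <= t <= t1 + th.second_call_max_s
                 for t in calls)
        dev.append(0 if ok else 1)
    # 11
    if len(admins) < 2:
        dev.append(1)
    else:
        a2 = admins[1]
        ok = (a2.t - admins[0].t <= th.second_admin_s
              and _quality_ok(record, a2, spans))
        dev.append(0 if ok else 1)
    # 12
    dev.append(0 if any(e.action == "call_blood_gas" and e.t <= dur
                        for e in record.events) else 1)
    # 13
    treated = {e.attributes.get("cause_id") for e in record.events
               if e.action == "treat_reversible_cause"}
    dev.append(0 if record.config.required_reversible_causes <= treated
               else 1)
    # 14
    dev.append(1 if any(e.action == "deliver_shock" for e in record.events)
               else 0)
    # 15
    bad_med = any(e.action == "administer_medication"
                  and e.attributes.get("med_name")
                  not in record.config.allowed_cause_medications
                  for e in record.events)
    dev.append(1 if bad_med else 0)
    return tuple(dev)


def oracle_fisher_2x2(a, b, c, d):
    """Two-sided Fisher p for [[a, b], [c, d]] via the hypergeometric pmf."""
    N, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, c1 - (N - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, r1, c1)
    p_obs = hypergeom.pmf(a, N, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def oracle_no_flow(record, start, end, step=0.01):
    """No-flow fraction by 10 ms time-grid discretization."""
    gap = record.config.thresholds.pause_threshold_s
    grid = np.arange(start, end, step)
    active = np.zeros(grid.size, bool)
    for s, e in _episodes_brute(record):
        active |= (grid >= s) & (grid <= e)
    return float(1.0 - active.mean())
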