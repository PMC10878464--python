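"""Seeded synthetic cohorts of simulated pediatric arrest scenarios.

The generator emulates the study conditions of a 27-team multicentre
simulation cohort stratified by use of a PALS pocket-card cognitive aid
(14 teams without, 13 with).  For each team it:

1. draws 15 per-item conformance indicators (Bernoulli, per-group success
   probabilities defaulting to the reference cohort's observed per-item
   proportions; an optional latent team-competence factor induces
   inter-item correlation, off by default);
2. draws task times from log-normal distributions anchored either at
   scenario start or at recognition of the pulseless state, conditioned on
   the drawn indicator (inside the checklist window when conformant,
   beyond it — or omitted with a configurable probability — when not);
3. emits a chest-compression stream in compression:ventilation cycles
   (15:2 when the ratio item is conformant) whose rate, depth, recoil and
   no-flow fraction follow the reference cohort's distributions;
4. verifies generator-scorer consistency: the deviation checklist scored on
   the emitted log reproduces the drawn indicators exactly, retrying the
   time draws (never the indicators) a bounded number of times.

Everything is reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cdev import score_team
from .events import (ActionEvent, CompressionRecord, ScenarioConfig,
                     ScenarioRecord)

__all__ = ["ITEM_SUCCESS_PROBS_NO_AID", "ITEM_SUCCESS_PROBS_AID",
           "ITEM_SUCCESS_PROBS_OVERALL", "TaskTime", "TASK_TIME_DEFAULTS",
           "CompressionParams", "CohortParams", "draw_item_indicators",
           "simulate_team", "simulate_team_from_indicators",
           "simulate_cohort", "simulate_rater_pair",
           "simulate_rater_totals", "perfect_record"]

# Observed per-item success proportions (correct counts / teams) in the
# reference 27-team cohort, by pocket-card stratum and overall.
ITEM_SUCCESS_PROBS_NO_AID = tuple(
    c / 14 for c in (14, 0, 10, 2, 7, 11, 10, 1, 1, 2, 1, 10, 5, 13, 13))
ITEM_SUCCESS_PROBS_AID = tuple(
    c / 13 for c in (12, 2, 13, 1, 6, 11, 7, 1, 2, 4, 7, 11, 5, 13, 13))
ITEM_SUCCESS_PROBS_OVERALL = tuple(
    c / 27 for c in (26, 2, 23, 3, 13, 22, 17, 2, 3, 6, 8, 21, 10, 26, 26))


@dataclass(frozen=True)
class TaskTime:
    """Log-normal elapsed-time model for one task: exp(mu) = median_s."""

    median_s: float
    sigma: float


#: Per-task elapsed-time distributions.  Where the reference cohort reports
#: a time-to-task median/IQR the median (minus its anchor's median) and a
#: sigma fitted from the IQR (sigma = ln(q3/q1)/(2*0.6745)) are used;
#: remaining sigmas/medians are plausible fills for tasks without reported
#: times.  Anchors: pulse_check/blood_gas/cause_treat from scenario start,
#: adren_admin2_gap from the first adrenaline administration, the rest from
#: recognition of the pulseless state.
TASK_TIME_DEFAULTS: dict[str, TaskTime] = {
    "pulse_check": TaskTime(27.0, 0.372),
    "cpr_start": TaskTime(24.0, 0.35),
    "board": TaskTime(110.0, 0.5),
    # calibrated so the marginal median of emitted call times (conformant
    # early callers included) matches the reference time-to-task median
    "call_help": TaskTime(200.0, 0.578),
    "ekg": TaskTime(30.0, 0.5),
    "iv_io_call": TaskTime(55.0, 0.5),
    "adren_call1": TaskTime(170.0, 0.5),
    "adren_admin1": TaskTime(237.0, 0.234),
    "adren_admin2_gap": TaskTime(115.0, 0.4),
    "bag_mask": TaskTime(43.0, 0.4),
    "iv_io_establish": TaskTime(163.0, 0.45),
    "blood_gas": TaskTime(200.0, 0.5),
    "cause_treat": TaskTime(350.0, 0.4),
}


@dataclass(frozen=True)
class CompressionParams:
    """Cohort-level CPR quality distributions (per-team draws).

    Rate and depth are log-normal (median, sigma fitted from the reference
    IQRs); the complete-recoil percentage and the no-flow-fraction target
    are clipped normals around the reference medians.
    """

    rate_median: float = 85.0
    rate_sigma: float = 0.267
    depth_median_cm: float = 6.1
    depth_sigma: float = 0.311
    recoil_pct_mean: float = 45.0
    recoil_pct_sd: float = 14.0
    nff_mean: float = 0.24
    nff_sd: float = 0.074
    conforming_cycle_compressions: int = 15
    nonconforming_cycle_compressions: int = 10


@dataclass(frozen=True)
class CohortParams:
    """Study-condition parameters for a synthetic cohort."""

    n_no_aid: int = 14
    n_aid: int = 13
    item_success_probs: dict = field(default_factory=lambda: {
        "aid_not_used": ITEM_SUCCESS_PROBS_NO_AID,
        "aid_used": ITEM_SUCCESS_PROBS_AID,
    })
    task_times: dict = field(default_factory=lambda: dict(TASK_TIME_DEFAULTS))
    compression: CompressionParams = field(default_factory=CompressionParams)
    omission_prob: float = 0.5      # P(omit | non-conformant timed item)
    latent_loading: float = 0.0     # inter-item correlation factor, off
    rater_flip_prob: float = 0.05
    config: ScenarioConfig = field(default_factory=ScenarioConfig)
    seed: int | None = None

    def __post_init__(self):
        for g, probs in self.item_success_probs.items():
            probs = tuple(float(p) for p in probs)
            if len(probs) != 15 or not all(0 <= p <= 1 for p in probs):
                raise ValueError(f"item_success_probs[{g}] must be 15 "
                                 "probabilities in [0, 1]")
            self.item_success_probs[g] = probs
        if not 0 <= self.omission_prob <= 1:
            raise ValueError("omission_prob must be in [0, 1]")
        if not 0 <= self.latent_loading < 1:
            raise ValueError("latent_loading must be in [0, 1)")

    @property
    def n_teams(self) -> int:
        return self.n_no_aid + self.n_aid


def draw_item_indicators(rng, probs, latent_loading: float = 0.0):
    """Draw 15 Bernoulli conformance indicators (True = task conformant).

    With a nonzero latent loading lam, a shared team-competence normal z is
    mixed into each item's uniform through a Gaussian copula
    (u_i = Phi(lam*z + sqrt(1-lam^2)*e_i)); marginal success probabilities
    are preserved while items become positively correlated.
    """
    from scipy.stats import norm

    probs = np.asarray(probs, float)
    if latent_loading == 0.0:
        return rng.random(15) < probs
    z = rng.standard_normal()
    e = rng.standard_normal(15)
    u = norm.cdf(latent_loading * z
                 + math.sqrt(1.0 - latent_loading ** 2) * e)
    return u < probs


# ---------------------------------------------------------------------------
# time draws
# ---------------------------------------------------------------------------

def _lognormal(rng, tt: TaskTime) -> float:
    return float(tt.median_s * math.exp(tt.sigma * rng.standard_normal()))


def _trunc_lognormal(rng, tt: TaskTime, lo=None, hi=None, tries=200) -> float:
    """Log-normal draw conditioned on [lo, hi]; uniform fallback."""
    lo = 0.0 if lo is None else lo
    hi = math.inf if hi is None else hi
    if lo >= hi:
        raise ValueError(f"empty truncation interval [{lo}, {hi}]")
    for _ in range(tries):
        v = _lognormal(rng, tt)
        if lo <= v <= hi:
            return v
    hi_eff = hi if math.isfinite(hi) else max(lo * 2, tt.median_s * 4)
    return float(rng.uniform(lo, hi_eff))


def _snap_into_run(runs, t, lo=-math.inf, hi=math.inf, margin=0.1):
    """Move t minimally so it lies strictly inside a compression run and
    within [lo, hi]; None when impossible."""
    best = None
    for start, end in runs:
        a, b = max(start + margin, lo), min(end - margin, hi)
        if a > b:
            continue
        cand = min(max(t, a), b)
        if best is None or abs(cand - t) < abs(best - t):
            best = cand
    return best


def _snap_into_gap(runs, t, end_of_scenario):
    """Move t to the nearest midpoint of a pause between compression runs
    (or of the tail after the last run)."""
    gaps = [((runs[i][1] + runs[i + 1][0]) / 2.0)
            for i in range(len(runs) - 1)]
    if runs and runs[-1][1] + 4.0 < end_of_scenario:
        gaps.append((runs[-1][1] + end_of_scenario) / 2.0)
    if not gaps:
        return None
    return min(gaps, key=lambda g: abs(g - t))


# ---------------------------------------------------------------------------
# team construction
# ---------------------------------------------------------------------------

def _build_compressions(rng, params, t_cc, duration, conforming, nff_target,
                        t_rec):
    """Compression + ventilation streams in cycles from t_cc to scenario end.

    Returns (compressions, ventilation_times, runs) where runs are
    (first, last) compression times per cycle.  Cycle pauses are sized so
    the no-flow fraction over [t_rec, duration] approximates nff_target
    (pauses never shrink below 2.5 s so they always split episodes).
    """
    cp = params.compression
    rate = float(np.clip(_lognormal(rng, TaskTime(cp.rate_median,
                                                  cp.rate_sigma)), 40, 140))
    n_per = (cp.conforming_cycle_compressions if conforming
             else cp.nonconforming_cycle_compressions)
    # spacing chosen so the measured rate over active run time equals `rate`
    spacing = (60.0 / rate) * n_per / (n_per - 1)
    run_dur = (n_per - 1) * spacing

    period = duration - t_rec
    target_noflow = nff_target * period
    noflow_in_cpr = max(0.0, target_noflow - (t_cc - t_rec))
    active_total = max(run_dur, (duration - t_cc) - noflow_in_cpr)
    n_cycles = max(1, int(active_total / run_dur))
    pause = float(np.clip(noflow_in_cpr / n_cycles, 2.5, 60.0))

    depth_team = float(np.clip(_lognormal(rng, TaskTime(cp.depth_median_cm,
                                                        cp.depth_sigma)),
                               3.0, 8.5))
    recoil_pct = float(np.clip(rng.normal(cp.recoil_pct_mean,
                                          cp.recoil_pct_sd), 1.0, 99.0))

    comp_times, vent_times, runs = [], [], []
    t = t_cc
    while t <= duration - 1.0:
        run = [t + k * spacing for k in range(n_per)
               if t + k * spacing <= duration]
        comp_times.extend(run)
        if len(run) < n_per:
            break
        runs.append((run[0], run[-1]))
        t_last = run[-1]
        v1, v2 = t_last + 0.35 * pause, t_last + 0.65 * pause
        if v2 <= duration:
            vent_times.extend([v1, v2])
        t = t_last + pause

    n = len(comp_times)
    depths = np.clip(depth_team * np.exp(rng.normal(0.0, 0.05, n)), 2.0, None)
    complete = rng.random(n) < recoil_pct / 100.0
    residuals = np.where(complete, rng.uniform(0.0, 0.45, n),
                         rng.uniform(0.6, 1.8, n))
    comps = [CompressionRecord(round(t, 3), round(float(d), 3),
                               round(float(r), 3))
             for t, d, r in zip(comp_times, depths, residuals)]
    return comps, vent_times, runs


def _adrenaline_attrs(rng, weight, failure=None):
    target = 0.01 * weight
    dose = target * (1.0 + rng.uniform(-0.09, 0.09))
    dilution = 0.1
    if failure == "dose":
        dose = target * float(rng.choice([10.0, 0.5, 1.25]))
    elif failure == "dilution":
        dilution = 1.0
    route = "IV" if rng.random() < 0.8 else "IO"
    return {"dose_mg": round(float(dose), 5),
            "dilution_mg_per_ml": dilution, "route": route}


def _build_team(rng, params: CohortParams, group, team_id, ind):
    """One construction attempt; returns a ScenarioRecord or None when a
    placement constraint could not be satisfied."""
    cfg = params.config
    th = cfg.thresholds
    D = cfg.duration_s
    tt = params.task_times
    events: list[ActionEvent] = []

    def omit() -> bool:
        return rng.random() < params.omission_prob

    t_rec = _trunc_lognormal(rng, tt["pulse_check"], lo=5.0, hi=60.0)
    events.append(ActionEvent(round(t_rec, 2), "pulse_check",
                              {"pulse_result": "absent"}))

    # item 1 — CPR start (compressions always happen; late when deviant)
    if ind[0]:
        e1 = _trunc_lognormal(rng, tt["cpr_start"], lo=1.0, hi=th.cpr_start_s)
    else:
        e1 = _trunc_lognormal(rng, tt["cpr_start"], lo=th.cpr_start_s + 0.5,
                              hi=120.0)
    t_cc = round(t_rec + e1, 2)
    events.append(ActionEvent(t_cc, "start_compressions"))

    nff_target = float(np.clip(rng.normal(params.compression.nff_mean,
                                          params.compression.nff_sd),
                               0.05, 0.45))
    comps, vent_times, runs = _build_compressions(
        rng, params, t_cc, D, conforming=bool(ind[2]),
        nff_target=nff_target, t_rec=t_rec)
    events.extend(ActionEvent(round(v, 3), "ventilation") for v in vent_times)

    # item 5 — compressor switches
    if ind[4]:
        for frac in (0.33, 0.66):
            events.append(ActionEvent(round(t_cc + frac * (D - t_cc), 2),
                                      "switch_compressor"))
    elif rng.random() < 0.5:
        events.append(ActionEvent(round(t_cc + 0.45 * (D - t_cc), 2),
                                  "switch_compressor"))

    # simple recognition-anchored timed items: (index, task, action, window)
    for idx, task, action, window in (
            (1, "board", "position_board", th.board_s),
            (3, "call_help", "call_help", th.call_help_s),
            (5, "ekg", "start_ekg_monitor", th.ekg_s),
            (6, "iv_io_call", "call_iv_io_access", th.iv_io_call_s)):
        if ind[idx]:
            e = _trunc_lognormal(rng, tt[task], lo=0.5, hi=window)
        elif omit():
            continue
        else:
            e = _trunc_lognormal(rng, tt[task], lo=window + 0.5,
                                 hi=D - t_rec - 1.0)
        events.append(ActionEvent(round(t_rec + e, 2), action))

    # adrenaline chain (items 8-11 -> ind[7..10])
    give1 = bool(ind[8] or ind[9] or ind[10]) or not omit()
    t1 = None
    if give1:
        hi_abs = D - 310.0 if (ind[9] or ind[10]) else D - 10.0
        lo_e = max(t_cc - t_rec, 35.0) + 1.0
        if ind[8]:
            failure1 = None
            e = _trunc_lognormal(rng, tt["adren_admin1"], lo=lo_e,
                                 hi=th.first_adrenaline_admin_s)
            t1 = _snap_into_run(runs, t_rec + e, lo=t_rec + lo_e,
                                hi=t_rec + th.first_adrenaline_admin_s)
        else:
            failure1 = rng.choice(
                ["late"] * 14 + ["dose"] * 2 + ["dilution"] * 1
                + ["flush"] * 2 + ["pause"] * 1)
            if failure1 == "late" and hi_abs - t_rec > \
                    th.first_adrenaline_admin_s + 2:
                e = _trunc_lognormal(
                    rng, tt["adren_admin1"],
                    lo=th.first_adrenaline_admin_s + 1.0, hi=hi_abs - t_rec)
                t1 = _snap_into_run(
                    runs, t_rec + e,
                    lo=t_rec + th.first_adrenaline_admin_s + 0.5, hi=hi_abs)
            else:
                if failure1 == "late":      # no room to be late; fail on dose
                    failure1 = "dose"
                e = _trunc_lognormal(rng, tt["adren_admin1"], lo=lo_e,
                                     hi=hi_abs - t_rec)
                if failure1 == "pause":
                    t1 = _snap_into_gap(runs, t_rec + e, D)
                else:
                    t1 = _snap_into_run(runs, t_rec + e, lo=t_rec + lo_e,
                                        hi=hi_abs)
        if t1 is None:
            return None
        t1 = round(t1, 3)
        events.append(ActionEvent(
            t1, "administer_adrenaline",
            _adrenaline_attrs(rng, cfg.patient_weight_kg, failure1)))
        if failure1 != "flush":
            events.append(ActionEvent(round(t1 + rng.uniform(2, 8), 2),
                                      "saline_flush"))

    # item 8 — first adrenaline call (always earlier than any administration)
    hi_call = (t1 - t_rec - 2.0) if t1 is not None else D - t_rec - 1.0
    if ind[7]:
        e = _trunc_lognormal(rng, TaskTime(20.0, 0.4), lo=0.5,
                             hi=min(th.first_adrenaline_call_s, hi_call))
        events.append(ActionEvent(round(t_rec + e, 2), "call_adrenaline"))
    elif not omit():
        lo = th.first_adrenaline_call_s + 0.5
        if hi_call > lo:
            e = _trunc_lognormal(rng, tt["adren_call1"], lo=lo, hi=hi_call)
            events.append(ActionEvent(round(t_rec + e, 2), "call_adrenaline"))

    # item 10 — second adrenaline call, window [180, 300] after t1
    if give1:
        if ind[9]:
            t_c2 = t1 + rng.uniform(th.second_call_min_s + 3.0,
                                    th.second_call_max_s - 3.0)
            events.append(ActionEvent(round(t_c2, 2), "call_adrenaline"))
        elif not omit():
            late_ok = t1 + th.second_call_max_s + 3.0 <= D - 1.0
            if late_ok and rng.random() < 0.5:
                t_c2 = t1 + rng.uniform(th.second_call_max_s + 3.0,
                                        min(450.0, D - 1.0 - t1))
            else:
                t_c2 = t1 + rng.uniform(60.0, th.second_call_min_s - 5.0)
            events.append(ActionEvent(round(t_c2, 2), "call_adrenaline"))

    # item 11 — second adrenaline administration
    if give1:
        give2, failure2, gap = False, None, None
        if ind[10]:
            give2 = True
            gap = _trunc_lognormal(rng, tt["adren_admin2_gap"], lo=35.0,
                                   hi=th.second_admin_s - 5.0)
        elif rng.random() >= 0.4:
            give2 = True
            late_ok = t1 + th.second_admin_s + 5.0 <= D - 5.0
            if late_ok and rng.random() < 0.5:
                failure2 = "late"
                gap = rng.uniform(th.second_admin_s + 4.0, D - 4.0 - t1)
            else:
                hi_gap = min(th.second_admin_s - 5.0, D - 5.0 - t1)
                if hi_gap <= 40.0:       # no room for a second dose at all
                    give2 = False
                else:
                    failure2 = str(rng.choice(
                        ["dose"] * 2 + ["dilution"] + ["flush"] * 2
                        + ["pause"]))
                    gap = _trunc_lognormal(rng, tt["adren_admin2_gap"],
                                           lo=35.0, hi=hi_gap)
        if give2:
            desired = t1 + gap
            if failure2 == "pause":
                t2 = _snap_into_gap(runs, desired, D)
            elif failure2 == "late":
                t2 = _snap_into_run(runs, desired,
                                    lo=t1 + th.second_admin_s + 0.5,
                                    hi=D - 2.0)
            else:
                t2 = _snap_into_run(runs, desired, lo=t1 + 30.0,
                                    hi=min(t1 + th.second_admin_s - 0.5,
                                           D - 2.0))
            if t2 is None:
                return None
            t2 = round(t2, 3)
            events.append(ActionEvent(
                t2, "administer_adrenaline",
                _adrenaline_attrs(rng, cfg.patient_weight_kg, failure2)))
            if failure2 != "flush":
                events.append(ActionEvent(
                    round(min(t2 + rng.uniform(2, 8), D - 0.1), 2),
                    "saline_flush"))

    # tasks without checklist items: always performed
    events.append(ActionEvent(
        round(t_rec + _trunc_lognormal(rng, tt["bag_mask"], lo=2.0,
                                       hi=D - t_rec - 1.0), 2),
        "start_bag_mask"))
    events.append(ActionEvent(
        round(t_rec + _trunc_lognormal(rng, tt["iv_io_establish"], lo=10.0,
                                       hi=D - t_rec - 1.0), 2),
        "establish_iv_io"))

    # item 12 — blood gas (omission is the only deviation mode)
    if ind[11]:
        t_bg = _trunc_lognormal(rng, tt["blood_gas"], lo=30.0, hi=D - 1.0)
        events.append(ActionEvent(round(t_bg, 2), "call_blood_gas"))

    # item 13 — reversible causes (treated via an allowed medication too)
    if ind[12]:
        for cause in sorted(cfg.required_reversible_causes):
            t_tc = _trunc_lognormal(rng, tt["cause_treat"], lo=100.0,
                                    hi=D - 10.0)
            events.append(ActionEvent(round(t_tc, 2),
                                      "treat_reversible_cause",
                                      {"cause_id": cause}))
            if cfg.allowed_cause_medications:
                med = sorted(cfg.allowed_cause_medications)[0]
                events.append(ActionEvent(round(t_tc + 5.0, 2),
                                          "administer_medication",
                                          {"med_name": med}))

    # items 14, 15 — prohibitions; deviation = the event occurs
    if not ind[13]:
        events.append(ActionEvent(round(rng.uniform(100, 500), 2),
                                  "deliver_shock"))
    if not ind[14]:
        med = str(rng.choice(["atropine", "amiodarone", "lidocaine"]))
        events.append(ActionEvent(round(rng.uniform(150, 500), 2),
                                  "administer_medication",
                                  {"med_name": med}))

    events.sort(key=lambda e: e.t)
    return ScenarioRecord(team_id=team_id, group=group, events=events,
                          compressions=comps, config=cfg)


def simulate_team_from_indicators(params: CohortParams, group: str,
                                  indicators, seed=None, team_id: str = "T01",
                                  rng=None,
                                  max_retries: int = 50) -> ScenarioRecord:
    """Emit an event log scoring exactly to the given conformance indicators.

    ``indicators`` is a 15-vector of truthy values (True = item conformant).
    Event times are (re-)drawn until the deviation checklist scored on the
    emitted log reproduces the indicators exactly (bounded retries).  Raises
    ``RuntimeError`` if consistency cannot be reached, which would indicate
    a generator defect rather than bad luck.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ind = np.asarray(indicators, bool)
    if ind.shape != (15,):
        raise ValueError("indicators must be a 15-vector")
    expected = tuple(0 if x else 1 for x in ind)
    for _ in range(max_retries):
        record = _build_team(rng, params, group, team_id, ind)
        if record is None:
            continue
        if score_team(record).deviations == expected:
            return record
    raise RuntimeError(
        f"could not generate a log scoring to the drawn indicators for "
        f"{team_id} after {max_retries} attempts")


def simulate_team(params: CohortParams, group: str, seed=None,
                  team_id: str = "T01", rng=None,
                  max_retries: int = 50) -> ScenarioRecord:
    """Simulate one team: draw conformance indicators from the group's item
    success probabilities, then emit a log scoring exactly to them."""
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = params.item_success_probs[group]
    ind = draw_item_indicators(rng, probs, params.latent_loading)
    return simulate_team_from_indicators(params, group, ind, rng=rng,
                                         team_id=team_id,
                                         max_retries=max_retries)


def simulate_cohort(params: CohortParams | None = None):
    """Simulate a full stratified cohort; reproducible given ``params.seed``.

    Returns ``params.n_no_aid`` records labelled ``aid_not_used`` followed
    by ``params.n_aid`` labelled ``aid_used``, with team ids T01, T02, ...
    """
    params = params or CohortParams()
    seeds = np.random.SeedSequence(params.seed).spawn(params.n_teams)
    records = []
    for i, ss in enumerate(seeds):
        group = "aid_not_used" if i < params.n_no_aid else "aid_used"
        records.append(simulate_team(params, group,
                                     rng=np.random.default_rng(ss),
                                     team_id=f"T{i + 1:02d}"))
    return records


def simulate_rater_pair(true_items, epsilon: float, seed=None, rng=None):
    """Two raters' 0/1 item vectors: each flips truth independently w.p.
    epsilon (annotation noise for agreement analyses)."""
    if not 0 <= epsilon <= 0.5:
        raise ValueError("epsilon must be in [0, 0.5]")
    if rng is None:
        rng = np.random.default_rng(seed)
    truth = np.asarray(true_items, int)
    a = np.where(rng.random(truth.size) < epsilon, 1 - truth, truth)
    b = np.where(rng.random(truth.size) < epsilon, 1 - truth, truth)
    return a, b


def simulate_rater_totals(scores, epsilon: float, seed=None):
    """Per-team deviation totals from two noisy raters of the same cohort."""
    rng = np.random.default_rng(seed)
    ta, tb = [], []
    for s in scores:
        a, b = simulate_rater_pair(s.deviations, epsilon, rng=rng)
        ta.append(int(a.sum()))
        tb.append(int(b.sum()))
    return np.array(ta), np.array(tb)


def perfect_record(team_id: str = "PERFECT", group: str = "aid_used",
                   config: ScenarioConfig | None = None) -> ScenarioRecord:
    """A deterministic, fully guideline-conformant scenario log (0 deviations).

    Useful as a test fixture and a readable example of what conformance
    means operationally.
    """
    cfg = config or ScenarioConfig()
    t_rec = 20.0
    t_cc = 25.0
    spacing = 0.6
    pause = 5.0
    comps, vents, runs = [], [], []
    t = t_cc
    while t + 14 * spacing <= cfg.duration_s - pause:
        run = [round(t + k * spacing, 3) for k in range(15)]
        comps.extend(run)
        runs.append((run[0], run[-1]))
        vents.extend([round(run[-1] + 1.5, 3), round(run[-1] + 3.0, 3)])
        t = run[-1] + pause

    def in_run(t):
        best = min(runs, key=lambda r: abs((r[0] + r[1]) / 2 - t))
        return round(min(max(t, best[0] + 0.1), best[1] - 0.1), 3)

    dose = round(0.01 * cfg.patient_weight_kg, 5)
    t1 = in_run(t_rec + 120.0)
    t2 = in_run(t1 + 250.0)
    events = [ActionEvent(v, "ventilation") for v in vents]
    events += [
        ActionEvent(t_rec, "pulse_check", {"pulse_result": "absent"}),
        ActionEvent(t_cc, "start_compressions"),
        ActionEvent(t_rec + 25.0, "position_board"),
        ActionEvent(t_rec + 30.0, "call_help"),
        ActionEvent(t_rec + 35.0, "start_ekg_monitor"),
        ActionEvent(t_rec + 40.0, "call_iv_io_access"),
        ActionEvent(t_rec + 25.0, "call_adrenaline"),
        ActionEvent(t_rec + 45.0, "start_bag_mask"),
        ActionEvent(t_rec + 90.0, "establish_iv_io"),
        ActionEvent(t1, "administer_adrenaline",
                    {"dose_mg": dose, "dilution_mg_per_ml": 0.1,
                     "route": "IV"}),
        ActionEvent(round(t1 + 4.0, 3), "saline_flush"),
        ActionEvent(round(t1 + 240.0, 2), "call_adrenaline"),
        ActionEvent(t2, "administer_adrenaline",
                    {"dose_mg": dose, "dilution_mg_per_ml": 0.1,
                     "route": "IO"}),
        ActionEvent(round(t2 + 4.0, 3), "saline_flush"),
        ActionEvent(300.0, "call_blood_gas"),
        ActionEvent(200.0, "switch_compressor"),
        ActionEvent(400.0, "switch_compressor"),
    ]
    for cause in sorted(cfg.required_reversible_causes):
        events.append(ActionEvent(350.0, "treat_reversible_cause",
                                  {"cause_id": cause}))
    events.sort(key=lambda e: e.t)
    compressions = [CompressionRecord(t, 5.5, 0.2) for t in comps]
    return ScenarioRecord(team_id=team_id, group=group, events=events,
                          compressions=compressions, config=cfg)
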