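"""End-to-end study pipeline: score a cohort, compare strata, emit tables.

``run_study`` takes a list of scenario records (ingested or simulated),
scores every team on the deviation checklist and the performance rubric,
computes CPR quality metrics and times-to-task, and produces a
:class:`CohortReport` with three table analogs:

* ``item_table`` — per checklist item: correct counts/%, per-group
  counts/%, group difference in percentage points with binomial CI, and an
  exact Fisher p-value;
* ``comparison_table`` — quantitative rows (per-task times, CPR quality
  metrics, checklist and rubric totals): medians/IQRs overall and per
  group, Hodges-Lehmann shift (aid minus no-aid) with CI, Wilcoxon p;
* ``descriptives`` — cohort-level medians/IQRs and AHA-band team counts;

plus an optional dual-rater agreement block (Lin CCC with bootstrap CI) and
complete run metadata (thresholds, methods, seed).  Reports are rendered to
lossless JSON, CSV-per-table, or human-readable markdown.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cdev import (ITEM_DESCRIPTIONS, cohort_item_frequencies, score_team,
                   scores_to_frame)
from .cpr import compute_metrics
from .events import ScenarioRecord, recognition_time
from .rubric import Rubric, default_rubric, score_cpt
from .stats import (StatResult, fisher_exact, hodges_lehmann,
                    lin_ccc_with_ci, median_iqr, proportion_difference,
                    wilcoxon_rank_sum)

__all__ = ["CohortReport", "run_study", "render_report", "load_report",
           "TASK_TIME_EVENTS"]

GROUP_LO, GROUP_HI = "aid_not_used", "aid_used"   # comparison = hi - lo

#: quantitative time-to-task rows: label -> how the time is measured
TASK_TIME_EVENTS = {
    "time_to_pulse_check_s": ("event", "pulse_check"),
    "time_to_start_compressions_s": ("cpr_start", None),
    "time_to_ekg_monitor_s": ("event", "start_ekg_monitor"),
    "time_to_call_help_s": ("event", "call_help"),
    "time_to_bag_mask_s": ("event", "start_bag_mask"),
    "time_to_iv_io_line_s": ("event", "establish_iv_io"),
    "time_to_adrenaline_s": ("admin", 0),
    "time_to_repeat_adrenaline_s": ("admin", 1),
}

CPR_METRIC_ROWS = {
    "mean_cc_rate_per_min": "mean_rate_per_min",
    "mean_cc_depth_cm": "mean_depth_cm",
    "complete_recoil_pct": "recoil_complete_fraction",
    "no_flow_fraction": "no_flow_fraction",
}

CPR_FLAG_ROWS = {
    "rate_100_120_pct_teams": "rate_in_100_120",
    "depth_5_6cm_pct_teams": "depth_in_5_6cm",
    "recoil_gt_50pct_pct_teams": "recoil_gt_50pct",
    "nff_lt_20pct_pct_teams": "nff_lt_20pct",
}


@dataclass
class CohortReport:
    descriptives: pd.DataFrame
    item_table: pd.DataFrame
    comparison_table: pd.DataFrame
    agreement: dict | None
    metadata: dict
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        def frame(df):
            return json.loads(df.to_json(orient="table", index=True))
        return {
            "descriptives": frame(self.descriptives),
            "item_table": frame(self.item_table),
            "comparison_table": frame(self.comparison_table),
            "agreement": self.agreement,
            "metadata": self.metadata,
            "scores": frame(self.scores),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortReport":
        def unframe(obj):
            import io
            return pd.read_json(io.StringIO(json.dumps(obj)), orient="table")
        return cls(descriptives=unframe(d["descriptives"]),
                   item_table=unframe(d["item_table"]),
                   comparison_table=unframe(d["comparison_table"]),
                   agreement=d.get("agreement"),
                   metadata=d["metadata"],
                   scores=unframe(d["scores"]))

    def equals(self, other: "CohortReport") -> bool:
        return json.dumps(self.to_dict(), sort_keys=True) == \
            json.dumps(other.to_dict(), sort_keys=True)


def _team_times(record: ScenarioRecord) -> dict:
    """Absolute times (s from scenario start) to each tracked task, NaN when
    the task was never performed."""
    out = {}
    for label, (kind, arg) in TASK_TIME_EVENTS.items():
        t = math.nan
        if kind == "event":
            ev = record.first_event(arg)
            t = ev.t if ev is not None else math.nan
        elif kind == "cpr_start":
            if record.compressions:
                t = record.compressions[0].t
            else:
                ev = record.first_event("start_compressions")
                t = ev.t if ev is not None else math.nan
        elif kind == "admin":
            admins = record.events_of("administer_adrenaline")
            t = admins[arg].t if len(admins) > arg else math.nan
        out[label] = t
    return out


def _mdn_iqr_str(x) -> str:
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return ""
    m, q1, q3 = median_iqr(x)
    return f"{m:g} ({q1:g}-{q3:g})"


def _stat_cols(res: StatResult | None, prefix: str) -> dict:
    if res is None:
        return {}
    out = {}
    if res.estimate is not None:
        out[f"{prefix}"] = res.estimate
    if res.ci_low is not None:
        out[f"{prefix}_ci_low"] = res.ci_low
        out[f"{prefix}_ci_high"] = res.ci_high
    return out


def run_study(records, *, rubric: Rubric | None = None,
              rater_totals=None, n_resamples: int = 2000,
              seed: int | None = None,
              proportion_ci_method: str = "wald") -> CohortReport:
    """Score, measure and statistically compare a cohort of scenario records.

    ``rater_totals`` — optional pair of per-team score vectors from two
    independent raters; when given, Lin's CCC with a seeded bootstrap CI is
    reported as the agreement block.  Deterministic given records, options
    and seed.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    ids = [r.team_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate team_ids: {dupes}")
    rubric = rubric or default_rubric()

    cdev_scores = [score_team(r) for r in records]
    cpt_scores = [score_cpt(r, rubric) for r in records]
    groups = [r.group for r in records]
    n_by_group = {g: groups.count(g) for g in (GROUP_LO, GROUP_HI)}
    comparative = all(n >= 2 for n in n_by_group.values())
    if not comparative:
        warnings.warn("fewer than 2 records in a group: descriptives only",
                      stacklevel=2)

    # quantitative per-team measures
    rows = []
    for rec, cd, cp in zip(records, cdev_scores, cpt_scores):
        row = {"team_id": rec.team_id, "group": rec.group,
               "cdev_total": cd.total, "cpt_total": cp.total}
        row.update(_team_times(rec))
        if rec.compressions and recognition_time(rec) is not None:
            m = compute_metrics(rec)
            for label, attr in CPR_METRIC_ROWS.items():
                row[label] = getattr(m, attr)
            for label, attr in CPR_FLAG_ROWS.items():
                row[label] = bool(getattr(m, attr))
        rows.append(row)
    team_frame = pd.DataFrame(rows)

    # ----- item table (checklist analog) -----------------------------------
    freq = cohort_item_frequencies(cdev_scores)
    item_rows = []
    for i in range(1, 16):
        row = {"item_id": i, "description": ITEM_DESCRIPTIONS[i],
               "n_correct": int(freq.loc[i, "n_correct"]),
               "n_teams": int(freq.loc[i, "n_teams"]),
               "pct_correct": freq.loc[i, "pct_correct"],
               "pct_deviation": freq.loc[i, "pct_deviation"]}
        if comparative:
            k = {g: sum(1 - s.item(i).deviation
                        for s in cdev_scores if s.group == g)
                 for g in (GROUP_LO, GROUP_HI)}
            n_lo, n_hi = n_by_group[GROUP_LO], n_by_group[GROUP_HI]
            row.update({
                "n_correct_no_aid": k[GROUP_LO],
                "pct_correct_no_aid": 100.0 * k[GROUP_LO] / n_lo,
                "n_correct_aid": k[GROUP_HI],
                "pct_correct_aid": 100.0 * k[GROUP_HI] / n_hi,
            })
            diff = proportion_difference(k[GROUP_LO], n_lo, k[GROUP_HI],
                                         n_hi, method=proportion_ci_method)
            row.update(_stat_cols(diff, "diff_pct_points"))
            table = [[k[GROUP_LO], n_lo - k[GROUP_LO]],
                     [k[GROUP_HI], n_hi - k[GROUP_HI]]]
            row["fisher_p"] = fisher_exact(table).p_value
        item_rows.append(row)
    item_table = pd.DataFrame(item_rows).set_index("item_id")

    # ----- comparison table (quantitative analog) --------------------------
    quant_cols = (["cdev_total", "cpt_total"] + list(TASK_TIME_EVENTS)
                  + [c for c in list(CPR_METRIC_ROWS) + list(CPR_FLAG_ROWS)
                     if c in team_frame.columns])
    comp_rows = []
    for col in quant_cols:
        vals = team_frame[col]
        if col in CPR_FLAG_ROWS:
            # binary band indicators: % of teams, compared by Fisher
            present = vals.dropna().astype(bool)
            row = {"measure": col, "n": int(present.size),
                   "overall": 100.0 * present.mean() if present.size else
                   math.nan}
            if comparative:
                sub = team_frame.loc[present.index]
                k, n = {}, {}
                for g in (GROUP_LO, GROUP_HI):
                    gvals = present[sub["group"] == g]
                    k[g], n[g] = int(gvals.sum()), int(gvals.size)
                if min(n.values()) >= 2:
                    row.update({
                        "no_aid": 100.0 * k[GROUP_LO] / n[GROUP_LO],
                        "aid": 100.0 * k[GROUP_HI] / n[GROUP_HI]})
                    diff = proportion_difference(
                        k[GROUP_LO], n[GROUP_LO], k[GROUP_HI], n[GROUP_HI],
                        method=proportion_ci_method)
                    row.update(_stat_cols(diff, "diff_pct_points"))
                    row["p_value"] = fisher_exact(
                        [[k[GROUP_LO], n[GROUP_LO] - k[GROUP_LO]],
                         [k[GROUP_HI], n[GROUP_HI] - k[GROUP_HI]]]).p_value
            comp_rows.append(row)
            continue
        x = vals.dropna()
        row = {"measure": col, "n": int(x.size),
               "overall": _mdn_iqr_str(x)}
        if comparative:
            lo = vals[team_frame["group"] == GROUP_LO].dropna()
            hi = vals[team_frame["group"] == GROUP_HI].dropna()
            row["no_aid"] = _mdn_iqr_str(lo)
            row["aid"] = _mdn_iqr_str(hi)
            if lo.size >= 2 and hi.size >= 2:
                hl = hodges_lehmann(lo.to_numpy(), hi.to_numpy())
                row.update(_stat_cols(hl, "hl_shift"))
                row["p_value"] = wilcoxon_rank_sum(lo.to_numpy(),
                                                   hi.to_numpy()).p_value
        comp_rows.append(row)
    comparison_table = pd.DataFrame(comp_rows).set_index("measure")

    # ----- descriptives -----------------------------------------------------
    desc_rows = []
    for col in quant_cols:
        if col in CPR_FLAG_ROWS:
            continue
        for g, label in ((None, "overall"), (GROUP_LO, "no_aid"),
                         (GROUP_HI, "aid")):
            sub = team_frame if g is None else \
                team_frame[team_frame["group"] == g]
            x = sub[col].dropna().to_numpy()
            if x.size == 0 or (g is not None and not comparative):
                continue
            m, q1, q3 = median_iqr(x)
            desc_rows.append({"measure": col, "stratum": label,
                              "n": int(x.size), "median": m,
                              "q1": q1, "q3": q3})
    descriptives = pd.DataFrame(desc_rows).set_index(["measure", "stratum"])

    # ----- agreement --------------------------------------------------------
    agreement = None
    if rater_totals is not None:
        a, b = (np.asarray(v, float) for v in rater_totals)
        res = lin_ccc_with_ci(a, b, n_resamples=n_resamples, seed=seed)
        agreement = {"ccc": res.estimate, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "method": res.method,
                     "n_resamples": res.n_resamples, "n_pairs": int(a.size)}

    cfg = records[0].config
    metadata = {
        "palscore_version": _version,
        "n_teams": len(records),
        "n_by_group": n_by_group,
        "comparative": comparative,
        "rubric": rubric.name,
        "rubric_max_score": rubric.max_score,
        "seed": seed,
        "bootstrap_resamples": n_resamples,
        "proportion_ci_method": proportion_ci_method,
        "orientation": "differences and shifts are aid minus no-aid",
        "thresholds": {k: (sorted(v) if isinstance(v, frozenset) else v)
                       for k, v in cfg.to_dict().items()},
        "methods": {
            "categorical": "fisher exact, full enumeration (point-probability rule)",
            "quantitative": "wilcoxon rank-sum; hodges-lehmann shift with "
                            "mann-whitney inversion CI",
            "quantiles": "SAS empirical-distribution-with-averaging rule",
        },
    }
    scores = scores_to_frame(cdev_scores)
    scores["cpt_total"] = [s.total for s in cpt_scores]
    return CohortReport(descriptives=descriptives, item_table=item_table,
                        comparison_table=comparison_table,
                        agreement=agreement, metadata=metadata,
                        scores=scores.set_index("team_id"))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _markdown(report: CohortReport) -> str:
    md = ["# Cohort report", ""]
    md += [f"- teams: {report.metadata['n_teams']} "
           f"({report.metadata['n_by_group']})",
           f"- rubric: {report.metadata['rubric']}", ""]
    it = report.item_table.copy()
    for c in it.columns:
        if it[c].dtype.kind == "f":
            it[c] = it[c].map(
                lambda v: f"{v:.3f}" if "p" == c[-1] or c == "fisher_p"
                else f"{v:.1f}")
    md += ["## Checklist items (counts are correctly performed tasks)", "",
           it.to_markdown(), ""]
    ct = report.comparison_table.copy()
    for c in ct.columns:
        if ct[c].dtype.kind == "f":
            ct[c] = ct[c].map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    md += ["## Times to task and CPR quality", "", ct.to_markdown(), ""]
    dt = report.descriptives.reset_index()
    md += ["## Descriptives", "", dt.to_markdown(index=False), ""]
    if report.agreement:
        a = report.agreement
        md += ["## Inter-rater agreement", "",
               f"Lin CCC {a['ccc']:.3f} (95% CI {a['ci_low']:.3f}-"
               f"{a['ci_high']:.3f}; {a['n_resamples']} bootstrap "
               "resamples)", ""]
    return "\n".join(md)


def render_report(report: CohortReport, format: str, out_dir) -> list:
    """Write a report to ``out_dir`` as ``json`` (lossless), ``csv`` (one
    file per table) or ``markdown``; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "json":
        p = out_dir / "report.json"
        p.write_text(json.dumps(report.to_dict(), indent=1))
        return [p]
    if format == "csv":
        paths = []
        for name, df in (("descriptives", report.descriptives),
                         ("item_table", report.item_table),
                         ("comparison_table", report.comparison_table),
                         ("scores", report.scores)):
            p = out_dir / f"{name}.csv"
            df.to_csv(p)
            paths.append(p)
        p = out_dir / "metadata.json"
        p.write_text(json.dumps({"metadata": report.metadata,
                                 "agreement": report.agreement}, indent=1))
        paths.append(p)
        return paths
    if format == "markdown":
        p = out_dir / "report.md"
        p.write_text(_markdown(report))
        return [p]
    raise ValueError(f"unsupported format {format!r}")


def load_report(path) -> CohortReport:
    """Reload a JSON report written by :func:`render_report`."""
    return CohortReport.from_dict(json.loads(Path(path).read_text()))
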