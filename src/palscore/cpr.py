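"""CPR quality metrics from the chest-compression stream.

Compressions are grouped into *episodes*: maximal runs of consecutive
compressions whose inter-compression gap never exceeds a pause threshold
(default 2.0 s).  Episodes support both the quality metrics here (no-flow
fraction, rate over performed CPR) and the "while compressions are being
performed" condition of the adrenaline checklist items.

Metrics mirror standard resuscitation-quality reporting:

* mean compression rate over active episode time only, so pausing degrades
  the no-flow fraction rather than the measured rate;
* mean depth (cm);
* complete chest recoil: % of compressions whose residual displacement at
  release is at or below a threshold (default 0.5 cm);
* no-flow fraction: share of the resuscitation period (recognition of the
  pulseless state to scenario end, by default) with no compressions;

each flagged against the AHA quality bands (rate 100-120/min, depth 5-6 cm,
recoil in > 50% of compressions, no-flow fraction < 20%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .events import ScenarioRecord, recognition_time

__all__ = ["CompressionEpisode", "CPRMetrics", "compression_episodes",
           "compute_metrics", "PERIOD_ANCHORS"]

PERIOD_ANCHORS = ("recognition", "first_compression", "scenario_start")


@dataclass(frozen=True)
class CompressionEpisode:
    """A maximal run of compressions with no pause above threshold."""

    start_s: float
    end_s: float
    n_compressions: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t <= self.end_s


@dataclass(frozen=True)
class CPRMetrics:
    team_id: str
    n_compressions: int
    n_episodes: int
    mean_rate_per_min: float        # over active episode time (NaN if undefined)
    mean_depth_cm: float
    recoil_complete_fraction: float  # percent of compressions, 0-100
    active_time_s: float             # episode time inside the period
    no_flow_time_s: float
    period_s: float
    no_flow_fraction: float          # fraction of the period, 0-1
    rate_in_100_120: bool
    depth_in_5_6cm: bool
    recoil_gt_50pct: bool
    nff_lt_20pct: bool
    period_anchor: str = "recognition"
    pause_threshold_s: float = 2.0
    recoil_residual_cm: float = 0.5


def compression_episodes(compressions, pause_threshold_s: float = 2.0):
    """Group sorted compressions into episodes.

    Consecutive compressions whose gap is <= ``pause_threshold_s`` belong to
    the same episode; an episode runs from its first to its last compression.
    """
    if pause_threshold_s <= 0:
        raise ValueError("pause_threshold_s must be positive")
    times = [c.t for c in compressions]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("compressions must be sorted by time")
    episodes: list[CompressionEpisode] = []
    i = 0
    n = len(times)
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] - times[j] <= pause_threshold_s:
            j += 1
        episodes.append(CompressionEpisode(times[i], times[j], j - i + 1))
        i = j + 1
    return episodes


def _overlap(lo1, hi1, lo2, hi2) -> float:
    return max(0.0, min(hi1, hi2) - max(lo1, lo2))


def compute_metrics(record: ScenarioRecord, *,
                    period_anchor: str = "recognition") -> CPRMetrics:
    """Compute CPR quality metrics for one record.

    The resuscitation period runs from the selected anchor (default:
    recognition of the pulseless state) to scenario end.  Raises
    ``ValueError`` when the anchor is undefined or the period has zero
    length.  An empty compression stream yields NaN rate/depth/recoil and a
    no-flow fraction of 1.
    """
    th = record.config.thresholds
    episodes = compression_episodes(record.compressions, th.pause_threshold_s)

    if period_anchor == "recognition":
        start = recognition_time(record)
        if start is None:
            raise ValueError("recognition time undefined: no pulse_check "
                             "with pulse_result=absent")
    elif period_anchor == "first_compression":
        if not record.compressions:
            raise ValueError("no compressions: first_compression anchor "
                             "undefined")
        start = record.compressions[0].t
    elif period_anchor == "scenario_start":
        start = 0.0
    else:
        raise ValueError(f"unknown period anchor {period_anchor!r}")
    end = record.config.duration_s
    period = end - start
    if period <= 0:
        raise ValueError("zero-length resuscitation period")

    n = len(record.compressions)
    total_episode_time = sum(e.duration_s for e in episodes)
    if total_episode_time > 0:
        mean_rate = 60.0 * n / total_episode_time
    else:
        mean_rate = math.nan
    if n:
        mean_depth = sum(c.depth_cm for c in record.compressions) / n
        n_complete = sum(c.release_residual_cm <= th.recoil_residual_cm
                         for c in record.compressions)
        recoil_pct = 100.0 * n_complete / n
    else:
        mean_depth = math.nan
        recoil_pct = math.nan

    active_in_period = sum(_overlap(e.start_s, e.end_s, start, end)
                           for e in episodes)
    no_flow = period - active_in_period
    nff = no_flow / period

    return CPRMetrics(
        team_id=record.team_id,
        n_compressions=n,
        n_episodes=len(episodes),
        mean_rate_per_min=mean_rate,
        mean_depth_cm=mean_depth,
        recoil_complete_fraction=recoil_pct,
        active_time_s=active_in_period,
        no_flow_time_s=no_flow,
        period_s=period,
        no_flow_fraction=nff,
        rate_in_100_120=bool(not math.isnan(mean_rate)
                             and 100.0 <= mean_rate <= 120.0),
        depth_in_5_6cm=bool(not math.isnan(mean_depth)
                            and 5.0 <= mean_depth <= 6.0),
        recoil_gt_50pct=bool(not math.isnan(recoil_pct) and recoil_pct > 50.0),
        nff_lt_20pct=bool(nff < 0.20),
        period_anchor=period_anchor,
        pause_threshold_s=th.pause_threshold_s,
        recoil_residual_cm=th.recoil_residual_cm,
    )
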