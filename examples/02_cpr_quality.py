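"""CPR quality metrics from a chest-compression stream.

Two compression episodes separated by a long pause: the no-flow fraction
is the share of the resuscitation period (recognition at 30 s to scenario
end at 600 s) with no compressions, and the rate is measured over
performed CPR only, so pausing degrades no-flow, not rate.
"""

import numpy as np

from palscore import ScenarioRecord, ActionEvent, CompressionRecord, \
    compute_metrics

comp_times = np.concatenate([
    np.arange(60.0, 300.0, 0.55),       # ~109/min for 4 min
    np.arange(340.0, 600.0, 0.55),      # 40 s pause, then CPR to the end
])
rng = np.random.default_rng(0)
comps = [CompressionRecord(float(t), float(d), float(r))
         for t, d, r in zip(comp_times,
                            rng.normal(5.4, 0.3, comp_times.size),
                            rng.uniform(0.0, 0.9, comp_times.size))]
record = ScenarioRecord(
    "demo", "aid_used",
    events=[ActionEvent(30.0, "pulse_check", {"pulse_result": "absent"})],
    compressions=comps)

m = compute_metrics(record)
print(f"compressions: {m.n_compressions} in {m.n_episodes} episodes")
print(f"mean rate:    {m.mean_rate_per_min:.1f}/min  "
      f"(in 100-120 band: {m.rate_in_100_120})")
print(f"mean depth:   {m.mean_depth_cm:.2f} cm   "
      f"(in 5-6 cm band: {m.depth_in_5_6cm})")
print(f"full recoil:  {m.recoil_complete_fraction:.1f}% of compressions "
      f"(> 50%: {m.recoil_gt_50pct})")
print(f"no-flow:      {100 * m.no_flow_fraction:.1f}% of the "
      f"{m.period_s:.0f} s period (< 20%: {m.nff_lt_20pct})")
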