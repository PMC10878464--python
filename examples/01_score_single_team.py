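"""Score one team's event log on the 15-item deviation checklist.

Builds a small in-memory log for a 10 kg simulated patient: the team
recognizes the pulseless state at 27 s, starts compressions at 51 s
(24 s later — within the 30 s window), but positions the CPR board late
and gives the first adrenaline after the 3-minute window.
"""

from palscore import ScenarioRecord, ActionEvent, CompressionRecord, \
    ScenarioConfig, score_team, score_cpt

events = [
    ActionEvent(27, "pulse_check", {"pulse_result": "absent"}),
    ActionEvent(51, "start_compressions"),
    ActionEvent(150, "position_board"),              # > 60 s: deviation
    ActionEvent(70, "call_help"),                    # 43 s: on time
    ActionEvent(60, "start_ekg_monitor"),
    ActionEvent(80, "call_iv_io_access"),
    ActionEvent(100, "call_adrenaline"),             # > 30 s: deviation
    ActionEvent(260, "administer_adrenaline",        # 233 s > 180 s: late
                {"dose_mg": 0.1, "dilution_mg_per_ml": 0.1, "route": "IV"}),
    ActionEvent(264, "saline_flush"),
    ActionEvent(90, "start_bag_mask"),
    ActionEvent(300, "call_blood_gas"),
]
# a continuous compression stream from 51 s to scenario end
compressions = [CompressionRecord(51 + 0.6 * k, 5.4, 0.2)
                for k in range(int((600 - 51) / 0.6))]
record = ScenarioRecord("demo-team", "aid_not_used", events=sorted(
    events, key=lambda e: e.t), compressions=compressions,
    config=ScenarioConfig(patient_weight_kg=10.0))

score = score_team(record)
print(f"deviation total: {score.total}/15  (0 = perfect adherence)")
for item in score.items:
    if item.status == "deviation":
        print(f"  item {item.item_id:2d}: {item.reason}")

cpt = score_cpt(record)
print(f"performance rubric: {cpt.total}/{cpt.max_score} "
      "(higher = better technical performance)")
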