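"""Start/stop and speed coding of the simulated units.

Finding: units built with start transients are flagged start coding with
large modulation indices, and speed-gain units tend to be flagged speed
coding (the small 0.01 (sp/s)/(mm/s) gain is near the detection floor for
some units, mirroring the graded speed coding of real populations); the
Venn categories over {phase, speed, start/stop} sum to the unit count.
"""
import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, unit_cohort, walking_session

from spikegait import bouts as bt
from spikegait import events as ev
from spikegait import kinematics as kin

out = RESULTS / "event_speed"
out.mkdir(parents=True, exist_ok=True)

track, table = walking_session(seed=2)
units = unit_cohort(track, table, kappa=1.0, n_units=8, seed0=100)
speed = kin.body_speed(track)
motion = bt.detect_motion_bouts(speed, track.frame_rate)
print(f"{len(motion)} motion bouts, initiation rate "
      f"{bt.initiation_rate(motion, track.duration):.2f}/min")

rng = np.random.default_rng(1)
rows = []
for st in units:
    start = ev.start_stop_test(st, motion, "start")
    stop = ev.start_stop_test(st, motion, "stop")
    sp = ev.speed_coding(st, speed, track.frame_rate, rng=rng)
    gt = st.ground_truth["params"]
    rows.append(
        {
            "unit_id": st.unit_id,
            "gt_start_amp": gt.start_transient_amp,
            "gt_speed_gain": gt.speed_gain,
            "start_sig": start.significant,
            "mi_start": start.modulation_index,
            "stop_sig": stop.significant,
            "speed_sig": sp.significant,
            "speed_score": sp.score,
        }
    )
    print(
        f"{st.unit_id}: start sig={start.significant} MI={start.modulation_index:.2f} | "
        f"speed sig={sp.significant} score={sp.score:.2f} "
        f"(gt: amp={gt.start_transient_amp}, gain={gt.speed_gain})"
    )

import pandas as pd

df = pd.DataFrame(rows)
df.to_csv(out / "event_speed_coding.csv", index=False)
venn = {}
for r in rows:
    cats = ev.coding_categories(True, r["speed_sig"], r["start_sig"], r["stop_sig"])
    key = "+".join(sorted(cats)) if cats else "none"
    venn[key] = venn.get(key, 0) + 1
(out / "venn.json").write_text(json.dumps(venn, indent=2))
print("venn:", venn, f"-> {out}")
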