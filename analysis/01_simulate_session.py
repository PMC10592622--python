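"""Generate and persist a seeded synthetic recording session.

Writes the pose track, per-unit spike lists, and a manifest naming every
file and the ground-truth generator parameters, so the later stages run
from files exactly as they would on a real session export.
"""
import sys
from pathlib import Path

import yaml

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, unit_cohort, walking_session

out = RESULTS / "simulated"
out.mkdir(parents=True, exist_ok=True)

track, table = walking_session(seed=2)
track.to_csv(out / "pose.csv")

units = unit_cohort(track, table, kappa=1.0, n_units=8, seed0=100)
manifest = {"pose": str(out / "pose.csv"), "frame_rate": 80.0, "spikes": [], "ground_truth": []}
for st in units:
    path = out / f"{st.unit_id}.csv"
    st.to_csv(path)
    manifest["spikes"].append({"unit_id": st.unit_id, "path": str(path)})
    gp = st.ground_truth["params"]
    manifest["ground_truth"].append(
        {
            "unit_id": st.unit_id,
            "kappa": gp.phase_kappa,
            "preferred_phase_deg": gp.preferred_phase,
            "coupled_limb": gp.coupled_limb,
        }
    )
(out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
print(f"wrote {len(units)} units + pose track ({track.n_frames} frames) -> {out}")
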