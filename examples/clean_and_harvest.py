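"""Cytoplasm harvesting and pipette cleaning after a successful recording.

After whole-cell access, the cytoplasm is aspirated with a gentle pressure
sequence (-40 mbar for 1 min, -60 mbar for 2.5 min, -40 mbar for 1 min).
The pipette is then cleaned in a detergent bath (-300 mbar intake,
+1000 mbar expulsion) and rinsed in aCSF so it can be reused immediately.
"""

import numpy as np

from autopatch import (
    GroundTruthCell,
    PatchAttemptRecord,
    PatchConfig,
    SimulatedRig,
    clean_pipette,
    harvest_cytoplasm,
    run_autopatch,
)

cell = GroundTruthCell(centroid_um=np.array([60.0, 30.0, 20.0]), radius_um=5.0)
rig = SimulatedRig(cells=[cell], start_tip_um=(10.0, 30.0, 55.0), seed=42)
record = run_autopatch(rig, cell.centroid_um)
print(f"patching outcome: {record.outcome.value}, Rs = {record.Rs_Mohm:.1f} MOhm")

log = PatchAttemptRecord(rig.state.tip_stage_um.copy())
t0 = rig.state.sim_time_s
harvest_cytoplasm(rig, PatchConfig(), log)
stages = [e for e in log.events if e["event"] == "harvest_stage"]
print("harvest stages (pressure mbar, duration s):",
      [(s["stage_pressure_mbar"], s["duration_s"]) for s in stages])
print(f"harvest took {rig.state.sim_time_s - t0:.0f} s of simulated time")

cfg = PatchConfig(alconox_position_um=(0.0, 0.0, 80.0), acsf_position_um=(5.0, 0.0, 80.0))
t0 = rig.state.sim_time_s
clean_pipette(rig, cfg, log)
setpoints = sorted({row[2] for row in rig.history if row[1] == "CLEAN"})
print(f"cleaning used pressure setpoints {setpoints} mbar only, "
      f"took {rig.state.sim_time_s - t0:.0f} s")
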