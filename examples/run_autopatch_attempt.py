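"""One complete automated whole-cell patching attempt on the simulated rig.

Plans a 2 um-stepped trajectory to a staging point above the target, hunts
under 60 mbar positive pressure with continuous impedance monitoring,
descends at 20 mbar until the contact jump, forms a gigaseal under gentle
vacuum with the holding potential ramped to -60 mV, and breaks in with
suction pulses of increasing duration.  The attempt's diary is printed at
the end.
"""

import numpy as np

from autopatch import GroundTruthCell, ObstacleSpec, SimulatedRig, run_autopatch

cell = GroundTruthCell(centroid_um=np.array([60.0, 30.0, 20.0]), radius_um=5.0)
obstacle = ObstacleSpec(center_um=np.array([40.0, 30.0, 40.0]), radius_um=4.0)
rig = SimulatedRig(cells=[cell], obstacles=[obstacle], start_tip_um=(10.0, 30.0, 55.0), seed=42)

record = run_autopatch(rig, cell.centroid_um)

print(f"outcome: {record.outcome.value}")
if record.Rs_Mohm is not None:
    quality = "high quality (< 30 MOhm)" if record.Rs_Mohm < 30 else "acceptable (< 100 MOhm)"
    print(f"access resistance Rs = {record.Rs_Mohm:.1f} MOhm -> {quality}")
print(f"simulated duration: {record.phase_log[-1][0]:.1f} s over {len(record.phase_log)} ticks")
print("\nkey diary events:")
for e in record.events:
    if e["event"] in ("obstacle_detected", "contact", "gigaseal", "membrane_ruptured", "whole_cell") or (
        e["event"] == "avoidance_step"
    ):
        extra = {k: v for k, v in e.items() if k not in ("t", "phase", "event", "pressure_mbar", "resistance_Mohm")}
        print(f"  t={e['t']:7.2f}s [{e['phase']:7s}] {e['event']} {extra if extra else ''}")
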