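"""Estimate the manipulator-to-stage calibration from probe moves.

The micromanipulator's axes are generally not aligned with the microscope
stage (here the advance axis is tilted -33 degrees from horizontal).  Moving
the pipette known distances along its own axes and observing where the tip
lands in stage coordinates gives a linear system whose least-squares
solution is the calibration matrix — no orthogonality assumed.
"""

import numpy as np

from autopatch import SimulatedRig, estimate_calibration

rig = SimulatedRig(seed=0, start_tip_um=(100.0, 100.0, 100.0))

moves = []
for delta in (np.array([20.0, 0, 0]), np.array([0, 20.0, 0]), np.array([0, 0, 20.0])):
    before = rig.state.tip_stage_um.copy()
    rig.move_pipette(delta)
    moves.append((delta, rig.state.tip_stage_um - before))

cal = estimate_calibration(moves)
print("recovered calibration matrix (pipette axes -> stage):")
print(np.round(cal.matrix, 6))
print("hidden rig truth:")
print(np.round(rig.A, 6))
print(f"max entry error: {np.max(np.abs(cal.matrix - rig.A)):.2e}  (exact on noiseless moves)")

target = np.array([150.0, 120.0, 60.0])
rig.move_pipette(cal.to_pipette(target - rig.state.tip_stage_um))
print(f"closed-loop move to {target.tolist()}: tip now at {np.round(rig.state.tip_stage_um, 9).tolist()}")
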