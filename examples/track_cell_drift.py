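"""Track a target cell's drift in 3D during a (simulated) pipette approach.

Lateral drift is measured with a sparse pyramidal KLT feature tracker
against a template captured at optimal focus; axial drift with the
stddev-of-difference focus measure over a small stack around the last focus
position.
"""

import numpy as np
from scipy import ndimage

from autopatch import (
    ImageStack,
    PhantomSpec,
    ScoredBox,
    generate_cell_phantom_stack,
    make_track_state,
    track_lateral,
    track_z,
    update_target,
)

spec = PhantomSpec(stack_shape=(15, 260, 348), n_cells=1, seed=2)
stack, cells = generate_cell_phantom_stack(spec)
cell = cells[0]
k = int(round(cell.centroid_um[2]))
px = stack.pixel_size_um
r = cell.radius_um / px
box = ScoredBox(
    slice_index=k, x=cell.centroid_um[0] / px - 1.5 * r, y=cell.centroid_um[1] / px - 1.5 * r,
    w=3 * r, h=3 * r,
)
state = make_track_state(stack.voxels[k].astype(float), box, px)
print(f"template captured at slice {k} with {len(state.features)} corner features")

# the tissue drifts 3 px right, 2 px up between template and current frame
frame = ndimage.shift(state.template, (-2.0, 3.0), order=1, mode="nearest")
dx, dy = track_lateral(state, frame)
print(f"lateral drift : dx={dx:.3f} um dy={dy:.3f} um ({dx/px:.2f}, {dy/px:.2f} px; truth 3, -2)")

# the cell also sank 2 um: a mini-stack about the old focus shows it below center
mini = ImageStack(stack.voxels[k - 1 : k + 6], px, stack.z_step_um)
dz = track_z(state, mini)
print(f"axial drift   : dz={dz:.1f} um (negative = cell moved down)")

state = update_target(state, (dx, dy, dz))
print(f"accumulated target offset: {np.round(state.current_offset_um, 3).tolist()} um")
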