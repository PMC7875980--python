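"""Localize a patch-pipette tip in a label-free image stack.

Builds a synthetic DIC-like stack containing one pipette at a known pose,
runs the two-stage detector (coarse initialization, then gradient-descent
refinement of the two-cylinder model) and compares the recovered tip with
the ground truth.
"""

import numpy as np

from autopatch import detect_pipette, generate_pipette_phantom

stack, truth = generate_pipette_phantom(seed=1, noise_sigma=0.02)
model, trace = detect_pipette(stack)

err = np.linalg.norm(model.tip_um - truth.tip_um)
print(f"true tip      : {np.round(truth.tip_um, 2).tolist()} um (stage frame)")
print(f"detected tip  : {np.round(model.tip_um, 2).tolist()} um")
print(f"tip error     : {err:.3f} um   (sub-micrometre accuracy lets the")
print("                pipette reliably reach ~10 um somata)")
print(f"refinement    : {len(trace)} accepted steps, final energy {trace[-1]:.3f}")
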