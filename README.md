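# autopatch

Computational core of an automated, label-free, image-guided patch-clamp
workstation for brain slices — as a pure-Python library exercised entirely
against synthetic DIC-like image phantoms and a simulated electrophysiology
rig. It is written for electrophysiologists and lab-automation engineers who
want to develop, test and reason about autopatching logic without a
microscope, manipulator or amplifier on the desk.

The package covers the full visual patching loop:

* **Pipette tip localization** in unlabeled 3D stacks. The pipette is
  modelled as two cylinders (the glass walls) sharing a reference point — the
  tip — and an orientation (yaw ψ, tilt θ, half-opening α). A fast
  initialization on a darkness map is refined by numerical-gradient descent
  of an energy that combines wall-footprint darkness coverage with a
  matched-filter term pinning the tip where the dark wedge ends.
* **Manipulator–stage calibration**: the linear map A with
  `Δstage = A·Δpipette` is the least-squares solution over probe moves; no
  orthogonality or tilt assumptions (the default rig hides a −33° advance
  axis).
* **Cell-detection post-processing**: per-slice scored boxes (from any
  detector callable; a classical blob detector ships for phantoms) are
  united along Z when their intersection is ≥ 60 % of the smaller box,
  iterating against the running intersection region and bridging up to two
  empty slices; detections are ranked by confidence.
* **Evaluation**: centroid matching within 5 µm laterally and 3 µm axially;
  P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); annotator-agreement
  comparisons.
* **3D cell tracking**: sparse pyramidal Kanade–Lucas–Tomasi features for
  lateral drift, a stddev-of-difference focus measure for axial drift.
* **The autopatching state machine**: hunting at 50–70 mbar with 2 µm steps
  and impedance monitoring, spiral obstacle avoidance, descent at
  10–30 mbar until a 0.7–1.2 MΩ contact jump, gigaseal formation at
  −30…−10 mbar with a stepwise −60 mV holding ramp and a staged escalation
  protocol, break-in by suction pulses (−140…−100 mbar, pulse *k* lasting
  0.5 + 0.2·*k* s, bounded at 3 min), pipette cleaning, cytoplasm
  harvesting, and a JSONL diary with report generation.

The synthetic side (`autopatch.phantom`, `autopatch.rig`) renders textured
stacks with blurred elliptical somata and the defocus-faded two-walled
pipette silhouette, and simulates electrode physics: 3.5–5 MΩ pipettes, a
contact resistance jump, first-order pressure dynamics, vacuum-driven seal
growth to ≥ 1 GΩ, and membrane rupture under accumulated suction impulse.

## Worked example

```bash
python examples/detect_pipette_tip.py
```

```
true tip      : [30.04, 27.14, 26.88] um (stage frame)
detected tip  : [30.21, 27.13, 26.82] um
tip error     : 0.175 um   (sub-micrometre accuracy lets the
                pipette reliably reach ~10 um somata)
refinement    : 145 accepted steps, final energy -1.768
```

The tip error is the 3D Euclidean distance between the refined model's
reference point and the rendered ground truth; sub-micrometre accuracy is
what makes aiming at ~10 µm somata reliable. A full attempt
(`python examples/run_autopatch_attempt.py`) prints the diary of one
simulated patch: obstacle hit and spiral avoidance, the 1.0 MΩ contact jump,
gigaseal after ~15 s of gentle vacuum, membrane rupture on the fourth
suction pulse, and the final access resistance (Rs = 30 MΩ, i.e. an
acceptable recording; < 30 MΩ would count as high quality).

Other examples: `calibrate_manipulator.py`, `detect_and_evaluate_cells.py`,
`track_cell_drift.py`, `clean_and_harvest.py`. A thin CLI wraps the same
library calls (`autopatch detect-pipette|detect-cells|evaluate|run|report`).

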