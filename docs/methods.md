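# Methods

This note documents the models behind `autopatch`, the parameters that
matter, the numerical choices, and what the synthetic test bed does and does
not establish about real data.

## Coordinate conventions

One global frame is used everywhere: x = column · pixel size, y = row ·
pixel size, z = slice index · z-step, all in micrometres ("stage frame").
Slice indices are 0-based; pixel boxes are half-open `[x, x+w) × [y, y+h)`.
z increases with slice index ("up"); the pipette advances downward, so its
approach has a negative stage-z component and "a few micrometres above the
cell" means larger z. The default lateral calibration is the reference 40×
DIC setup, 160.08 × 119.6 µm imaged on 1392 × 1040 px (0.115 µm/px), with
1 µm slice spacing.

## Synthetic phantoms

`PhantomSpec` renders tissue-like stacks: a static background texture
(Gaussian random field, 8 px correlation length, intensity s.d. 0.04 around
a 0.5 base), somata as elliptical Gaussians (radius 4–6 µm, contrast 0.35,
aspect 0.8–1.25) whose amplitude decays as a Gaussian of axial distance
with σ_z = 3 µm — reproducing the roughly five-slice depth over which an
annotator can see a cell at 1 µm spacing — and whose in-plane blur grows
with defocus. Cells are rejection-placed with pairwise 3D separation above
twice the maximum radius. Per-voxel Gaussian noise (default s.d. 0.02) is
added last; a fixed seed gives bit-identical stacks.

The pipette forward model is shared between rendering and fitting: each
wall is a ray from the tip; its in-plane darkness profile is a Gaussian
tube of radius 1 µm, dimmed by `exp(-dz²/2σ_z²)` and widened by
`sqrt(1 + (dz/σ_z)²)` with defocus (σ_z = 3 µm); the two wall contributions
add and saturate, so near the apex they merge into one dark blob. The
composite is multiplicative (`I ← I·(1 − c·D)`, default contrast c = 0.6).
Pipette phantoms default to 80 slices of 400 × 520 px (46 × 60 µm): a
smaller crop was tried first and discarded because with only ~15 µm of
visible shank the opening angle is unidentifiable (a collapsed
single-cylinder fit can outscore the true two-wall pose).

What the phantoms do **not** emulate: DIC shear/relief shading, depth-
dependent scattering, z-varying tissue texture, moving debris, or
photometric drift. Passing tests therefore demonstrate the correctness and
conditioning of the algorithms under controlled appearance, not detector
performance on real tissue — which is exactly the role the plug-in detector
interface (any `image -> boxes` callable) leaves to a trained network.

## Pipette tip localization

`darkness_map` builds the observation the fit runs on: per slice, a
background estimate at σ = 50 px is computed on a 4×-decimated copy with
the dark pixels masked out (normalized convolution). The masking matters: a
plain Gaussian background dips around the silhouette, dimming the map where
the pipette footprint is large and biasing the fitted tip z by ~0.5 µm.
Positive residuals (darker than background) are smoothed (σ = 2 px) and
normalized to [0, 1]; constant intensity offsets cancel exactly.

**Initialization.** On the maximum projection of the map, pixels above mean
+ 2 s.d. are grouped into connected components. The pipette is taken as the
border-touching component that concentrates the largest share of the map's
total darkness, accepted only above 15 % (across 20 random poses the
silhouette holds 21–35 %; texture blobs in a full-size blank stack hold
≤ 10 %, so a stack without a pipette raises a detection failure; in very
small crops this margin vanishes and absence detection is ambiguous). The
tip is the component pixel farthest from the touched border lines, yaw
points from the tip to the component's border-entry pixels, and the tip
slice maximizes the local map response. Tilt and half-opening start at the
nominal +33° and 0.15 rad. On default phantoms this lands within ~2–4 µm
and ~5° of the truth; the refinement contract assumes at most 10 µm / 15°.

**Energy.** Two terms, evaluated on deterministic stratified samples
(500/wall along the centerline, clipped to the ray's exit from the volume):

* *coverage*: negative mean map darkness over the wall-centerline samples,
  centred by the map's global mean (a uniform map scores 0 for every pose);
* *apex*: negative Pearson correlation, over a window of the wall rays from
  6 µm before to 4 µm past the tip (100 samples/wall), between the map and
  the darkness the forward model itself predicts there.

A pure mean-darkness energy was implemented first and measurably fails: the
merged two-wall blob bleeds 1–2 µm ahead of the geometric tip, so coverage
alone has a flat, forward-biased direction along the wedge (axial scans on
four seeds put its minimum 0.75–2.5 µm off). The apex correlation locks the
reference point to the end of the dark wedge; with it the combined energy's
minimum sits at the true pose within the scan resolution (±0.25 µm).

**Optimization.** Numerical-gradient descent (central differences,
per-parameter scales, backtracking line search with shrink 0.5, tolerance
1e-6, ≤ 500 iterations) over tip, yaw, tilt and half-opening. Two paths are
run: a direct descent on the full-resolution map (best when the
initializer is within a couple of µm) and a coarse-to-fine path over
antialiased, subsampled maps at 5 and 2 µm smoothing with the opening angle
frozen and the initial tilt bracketed ±0.1 rad (its gradient is weak on
blurred maps). The lower-energy result receives a tight polish pass. The
returned energy trace is the full-resolution descent of the winning path;
accepted-step energies are non-increasing, and a result worse than the
initialization raises a refinement error.

Measured accuracy on the phantom suite: mean 3D tip error 0.19 µm over 20
seeded stacks with additive noise up to 5 % of range (worst case 0.45 µm),
and ≤ 0.3 µm noiseless — comfortably inside the ~1 µm regime needed to aim
at 10 µm somata.

**Calibration.** With probe moves `(Δpipette, Δstage)` the matrix A
minimizing Σ‖Δstage − A·Δpipette‖² is solved by least squares; exact for
noiseless data from any invertible A, < 2 % per entry with 0.5 µm
observation noise on six moves. Degenerate (rank < 3) move sets are
rejected.

## Cell detection, Z-merging, evaluation

The shipped phantom detector band-passes each slice at the soma scale
(difference of Gaussians), finds peaks above an absolute threshold, and
refines each center by a least-squares isotropic Gaussian fit; the box side
is the nominal soma diameter and confidence is the response normalized to
the strongest blob in the image. On coplanar in-focus phantoms it reaches
recall ≥ 0.9 at IoU 0.5; on a texture-free background its centers are
sub-2-px. Under the default texture the *apparent* blob center itself is
displaced by up to ~0.6 µm (an ideal fit initialized at the truth shows the
same displacement), which is irrelevant at the 5 µm matching tolerance the
evaluation uses.

Z-merging processes boxes in ascending slice order (canonically sorted
within a slice, making the result invariant to within-slice permutation). A
box joins an open detection when the area of its intersection with the
detection's *running intersection region* is at least 60 % of the smaller
of the two, and its slice is at most three above the detection's last
member (up to two empty slices bridged). The running region is narrowed to
each accepted intersection, floored at 4 px² so it cannot vanish. Ties go
to the best ratio, then the oldest detection. Every input box ends up in
exactly one detection; confidence aggregates as the member maximum and the
3D centroid is the confidence-weighted mean of member box centers.

Matching for evaluation is greedy by ascending lateral distance among pairs
within 5 µm laterally **and** 3 µm axially (two separate tolerances);
unmatched detections are false positives, unmatched ground truth false
negatives. Greedy equals the optimal assignment whenever tolerance
neighbourhoods are disjoint; the suite verifies equality against exhaustive
assignment on all random instances with ≤ 6 objects. Metrics are reported
in percent with the 0/0 → 0 convention.

## Tracking

Lateral: Shi–Tomasi corners (≤ 30) inside the template box, tracked by
iterative Lucas–Kanade over a 3-level image pyramid with a 15 px window;
features whose normal matrix is near-singular, that diverge, or that leave
the frame are dropped, the reported drift is the median over survivors, and
features are refreshed once more than half are lost. Accuracy on phantom
patches: exact to < 0.01 px for pure translations up to 10 px, < 0.05 px at
2 % additive noise (contracted bounds: 0.2 / 0.5 px).

Axial: over an odd mini-stack centred on the last focus position, the
standard deviation of (slice − template) inside the template box is
minimized; `dz = (argmin − center) · z_step`, negative when the cell sits
below the assumed focus. The curve has a unique minimum on phantom
mini-stacks across ±3 µm constructed shifts.

The controller queries tracking only at halt points and shifts the target
(and replans) accordingly; lateral and axial updates accumulate
component-wise.

## The patching state machine

Phases run HUNT → DESCEND → SEAL → BREAKIN → WHOLE_CELL with failure exits
only; the commanded pressure is always inside the active phase's protocol
window (hunting 50–70 mbar, positioning 10–30 mbar, sealing −30…−10 mbar
escalated to at most 2×, break-in pulses −140…−100 mbar, cleaning
−300/+1000 mbar). Notable defaults, with the open choices made here:

| parameter | default | note |
|---|---|---|
| hunting step | 2 µm | stepwise advance with impedance monitoring |
| staging point | 5 µm above the cell top | "a few µm above", fixed here to 5 |
| contact threshold | 1.0 MΩ | center of the 0.7–1.2 MΩ window |
| obstacle threshold | = contact threshold | separate config key |
| obstacle vs contact | obstacle iff lateral distance to target > 10 µm | "early" increase disambiguation |
| pull-back / spiral | 6 µm; Archimedean, 1 µm pitch, 8 pts/turn, ≤ 15 µm | avoidance manoeuvre |
| baseline resistance | mean of last 5 clear reads | drift-robust |
| holding ramp | −10 mV steps, 1 s apart, to −60 mV | "stepwise" concretized |
| seal deadline | 30 s, then ×1.5 (20 s), ×2 (20 s), ±2 µm wiggle (2 s/axis), release 10 s, reapply 20 s | strict order |
| break-in | pulse k: 0.5 + 0.2·k s at −120 mbar, 2 s pauses, ≤ 180 s | |
| success gate | Rs ≤ 100 MΩ | higher Rs is recorded but the outcome is BREAKIN_FAIL (no separate quality-fail class) |
| clock | discrete 50 ms ticks | all durations quantized |

Cleaning runs detergent intake (−300 mbar, 4 s), five 1 s + 1 s
expel/intake alternations, 10 s expulsion, then a 10 s rinse expulsion in
aCSF; harvesting applies −40 mbar (60 s), −60 mbar (default 150 s of the
2–3 min range), −40 mbar (60 s). Every action is stamped into the attempt's
event log; the full per-tick (time, phase, setpoint, actual pressure,
resistance) trace is kept on the record, and the diary is JSONL with
corrupt lines skipped and counted on read.

## The simulated rig

The rig honours the observable contracts of the hardware: baseline pipette
resistance drawn uniformly from 3.5–5 MΩ; the −5 mV test step obeys
I = V/R; a +1.0 MΩ jump within (radius + 1 µm) of a cell; obstacle
resistance bumps inside obstacle spheres; first-order pressure dynamics
with τ = 0.2 s (exact exponential update). Seal resistance grows as
dR/dt = k(p)·(R_max − R) while cell-attached under vacuum, with
k = 0.0023 s⁻¹·mbar⁻¹ × |p| saturating at 30 mbar and R_max = 2 GΩ — so a
default sealable cell crosses 1 GΩ in ~15 s at −20 mbar (design band
10–25 s, inside the 30 s protocol deadline); non-sealable cells have k = 0.
Rupture is deterministic: suction stronger than −80 mbar on a gigasealed
patch accumulates |p|·dt, and crossing the cell's threshold (default
250 mbar·s, reached on break-in pulse 3–4) drops the measured resistance to
the cell's access resistance, drawn lognormal with median 30 MΩ
(σ = 0.45). The manipulator applies a hidden true calibration (advance axis
tilted −33°) that the calibration module must recover. The published
protocol gives no quantitative seal or rupture dynamics, so these constants
are internal stand-ins chosen once for plausible timing; conclusions about
real seal kinetics cannot be drawn from them.

Monte-Carlo behaviour: over seeded populations with a 60 % sealable
fraction, attempt successes are binomial in the sealable draw (the
lognormal Rs tail above 100 MΩ contributes < 1 %), which the suite checks
against the exact binomial 95 % interval at n = 20.

## Known limitations

* The phantom appearance is far cleaner than real DIC tissue; real-image
  performance of any detector must be established separately.
* Absence-of-pipette detection relies on a darkness-mass threshold that is
  only meaningful at realistic fields of view (see above).
* The two-cylinder fit assumes both walls visible and a single pipette; no
  multi-pipette support.
* The rig's seal/rupture constants are plausible but not fitted to any
  measured kinetics; timing-sensitive conclusions transfer only at the
  level of protocol logic, not biophysics.
* The template tracker never updates its appearance model; long drifts with
  appearance change would need re-templating.
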