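import math

import numpy as np
import pytest

from autopatch import (
    CalibrationTransform,
    ImageStack,
    PipetteModel,
    SimulatedRig,
    darkness_map,
    detect_tip,
    estimate_calibration,
    generate_pipette_phantom,
    initialize_pipette_model,
    pipette_energy,
    pipette_to_stage,
    refine_pipette_model,
)
from autopatch.errors import BoundsError, DegenerateCalibrationError, DetectionFailureError
from autopatch.phantom import _background
from autopatch.rig import default_hidden_calibration


def _angle_diff(a, b):
    return abs((a - b + math.pi) % (2 * math.pi) - math.pi)


# -- calibration ------------------------------------------------------------


def test_identity_calibration_recovered_exactly():
    moves = [((10, 0, 0), (10, 0, 0)), ((0, 10, 0), (0, 10, 0)), ((0, 0, 10), (0, 0, 10))]
    cal = estimate_calibration(moves)
    assert cal.matrix == pytest.approx(np.eye(3), abs=1e-9)


def test_tilted_axis_calibration_recovered_exactly():
    a_true = default_hidden_calibration(33.0)
    deltas = [np.array([12.0, 0, 0]), np.array([0, 9.0, 0]), np.array([0, 0, 15.0])]
    moves = [(d, a_true @ d) for d in deltas]
    cal = estimate_calibration(moves)
    assert np.max(np.abs(cal.matrix - a_true)) / np.max(np.abs(a_true)) < 1e-9


def test_noisy_calibration_recovered_within_two_percent(rng):
    a_true = default_hidden_calibration(33.0)
    deltas = [rng.uniform(-30, 30, 3) for _ in range(6)]
    moves = [(d, a_true @ d + rng.normal(0, 0.5, 3)) for d in deltas]
    cal = estimate_calibration(moves)
    assert np.max(np.abs(cal.matrix - a_true)) / np.max(np.abs(a_true)) < 0.02


def test_rank_deficient_moves_rejected():
    moves = [((10, 0, 0), (10, 0, 0)), ((20, 0, 0), (20, 0, 0)), ((30, 0, 0), (30, 0, 0))]
    with pytest.raises(DegenerateCalibrationError):
        estimate_calibration(moves)
    with pytest.raises(DegenerateCalibrationError):
        estimate_calibration(moves[:2])


def test_pipette_to_stage_roundtrip():
    cal = CalibrationTransform(default_hidden_calibration(33.0))
    delta = np.array([5.0, -3.0, 2.0])
    assert cal.to_pipette(pipette_to_stage(cal, delta)) == pytest.approx(delta, abs=1e-12)
    ident = CalibrationTransform(np.eye(3))
    assert pipette_to_stage(ident, delta) == pytest.approx(delta)


def test_closed_loop_reaches_commanded_stage_target():
    rig = SimulatedRig(seed=0, start_tip_um=(100.0, 100.0, 100.0))
    cal = CalibrationTransform(rig.A.copy())
    target = np.array([140.0, 80.0, 60.0])
    rig.move_pipette(cal.to_pipette(target - rig.state.tip_stage_um))
    assert rig.state.tip_stage_um == pytest.approx(target, abs=1e-9)


# -- darkness map -----------------------------------------------------------


def test_uniform_stack_gives_zero_map():
    stack = ImageStack(np.full((4, 60, 80), 0.5), 0.115, 1.0)
    dm = darkness_map(stack)
    assert np.all(dm.voxels == 0.0)


def test_map_invariant_to_intensity_offset(pipette_case):
    stack = pipette_case["stack"]
    shifted = ImageStack(stack.voxels + 0.1, stack.pixel_size_um, stack.z_step_um)
    a = darkness_map(stack)
    b = darkness_map(shifted)
    assert a.voxels == pytest.approx(b.voxels, abs=1e-4)


def test_wall_voxels_much_darker_than_background_in_map(pipette_case):
    dm, model = pipette_case["dmap"], pipette_case["truth"]
    px = dm.pixel_size_um
    wall = []
    for w in model.wall_directions():
        for s in np.linspace(3, 15, 10):
            p = model.tip_um + s * w
            wall.append(dm.voxels[int(round(p[2])), int(round(p[1] / px)), int(round(p[0] / px))])
    assert np.mean(wall) > 3.0 * dm.voxels.mean()


# -- energy -----------------------------------------------------------------


def test_energy_prefers_truth_over_lateral_shift(pipette_case):
    dm, truth = pipette_case["dmap"], pipette_case["truth"]
    lat = truth.wall_directions()[0] - truth.wall_directions()[1]
    lat /= np.linalg.norm(lat)
    shifted = truth.replace(tip_um=truth.tip_um + 5.0 * lat)
    assert pipette_energy(dm, truth) < pipette_energy(dm, shifted)


def test_energy_zero_on_uniform_map():
    dm = ImageStack(np.full((20, 120, 160), 0.3), 0.115, 1.0)
    model = PipetteModel(tip_um=np.array([8.0, 6.0, 10.0]), yaw_rad=0.3, tilt_rad=0.5)
    assert pipette_energy(dm, model) == pytest.approx(0.0, abs=1e-6)


def test_energy_errors_when_footprint_outside(pipette_case):
    dm = pipette_case["dmap"]
    far = PipetteModel(tip_um=np.array([1e4, 1e4, 1e4]), yaw_rad=0.0, tilt_rad=0.5)
    with pytest.raises(BoundsError):
        pipette_energy(dm, far)


def test_truth_is_local_energy_minimum(pipette_case):
    dm, truth = pipette_case["dmap"], pipette_case["truth"]
    e0 = pipette_energy(dm, truth)
    perturbations = [
        truth.replace(tip_um=truth.tip_um + np.array([5.0, 0, 0])),
        truth.replace(tip_um=truth.tip_um + np.array([0, -5.0, 0])),
        truth.replace(tip_um=truth.tip_um + np.array([0, 0, 5.0])),
        truth.replace(yaw_rad=truth.yaw_rad + math.radians(5)),
        truth.replace(yaw_rad=truth.yaw_rad - math.radians(5)),
        truth.replace(tilt_rad=truth.tilt_rad + math.radians(5)),
    ]
    for p in perturbations:
        assert pipette_energy(dm, p) > e0


# -- initialization ---------------------------------------------------------


def test_initialization_within_capture_range(pipette_case):
    truth = pipette_case["truth"]
    init = initialize_pipette_model(pipette_case["stack"], dmap=pipette_case["dmap"])
    assert np.linalg.norm(init.tip_um - truth.tip_um) <= 10.0
    assert _angle_diff(init.yaw_rad, truth.yaw_rad) <= math.radians(15)


def test_initialization_recovers_rotated_orientations():
    # same scene rotated 90 degrees in-plane via a different ground-truth yaw
    for seed in (21, 22):
        stack, truth = generate_pipette_phantom(seed=seed)
        init = initialize_pipette_model(stack)
        assert _angle_diff(init.yaw_rad, truth.yaw_rad) <= math.radians(15)


def test_blank_stack_raises_detection_failure(rng):
    # a full-size stack with tissue texture but no pipette
    vox = _background((80, 400, 520), 8.0, rng)
    stack = ImageStack(vox.astype(np.float32), 0.115, 1.0)
    with pytest.raises(DetectionFailureError):
        initialize_pipette_model(stack)


# -- refinement and full detector ------------------------------------------


def test_refine_from_three_micron_offset_converges(pipette_case):
    dm, truth = pipette_case["dmap"], pipette_case["truth"]
    off = truth.replace(tip_um=truth.tip_um + np.array([2.0, -2.0, 1.0]))
    model, trace = refine_pipette_model(dm, off)
    assert np.linalg.norm(model.tip_um - truth.tip_um) <= 0.3
    assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))


def test_refine_from_truth_does_not_worsen(pipette_case):
    dm, truth = pipette_case["dmap"], pipette_case["truth"]
    model, _ = refine_pipette_model(dm, truth)
    assert np.linalg.norm(model.tip_um - truth.tip_um) <= 0.3


def test_refine_captures_large_initial_offset(pipette_case):
    dm, truth = pipette_case["dmap"], pipette_case["truth"]
    far = truth.replace(
        tip_um=truth.tip_um + np.array([5.0, -6.0, 5.0]),
        yaw_rad=truth.yaw_rad + math.radians(12),
    )
    model, _ = refine_pipette_model(dm, far)
    assert np.linalg.norm(model.tip_um - truth.tip_um) <= 1.0


def test_full_detector_accuracy(refined_pipette):
    err = np.linalg.norm(refined_pipette["model"].tip_um - refined_pipette["truth"].tip_um)
    assert err <= 0.3  # noiseless phantom
    assert all(
        b <= a + 1e-12 for a, b in zip(refined_pipette["trace"], refined_pipette["trace"][1:])
    )


def test_detect_tip_fails_on_blank_stack(rng):
    vox = _background((80, 400, 520), 8.0, rng)
    stack = ImageStack(vox.astype(np.float32), 0.115, 1.0)
    with pytest.raises(DetectionFailureError):
        detect_tip(stack)
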