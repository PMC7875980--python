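"""The automated patching state machine.

Orchestrates one whole-cell attempt end to end: straight-line trajectory
planning in manipulator coordinates, the hunting phase with continuous
impedance monitoring and spiral obstacle avoidance, descent onto the cell,
gigaseal formation with the escalation protocol, suction-pulse break-in,
pipette cleaning and cytoplasm harvesting.  Every action is stamped into the
attempt's event log (the diary).

Phase pressures follow the published protocol windows: hunting 50-70 mbar,
positioning 10-30 mbar, sealing -30..-10 mbar (escalated up to 2x), break-in
pulses -140..-100 mbar.  The seal deadline is 30 s before escalation starts;
break-in is bounded at 3 min; pulse k lasts 0.5 + 0.2*k seconds.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np

from .errors import AutopatchError, ConfigurationError, PlanningError, StateError, TravelLimitError
from .pipette import CalibrationTransform
from .rig import Phase, SimulatedRig


class Outcome(str, enum.Enum):
    WHOLE_CELL = "WHOLE_CELL"
    SEAL_FAIL = "SEAL_FAIL"
    BREAKIN_FAIL = "BREAKIN_FAIL"
    OBSTACLE_FAIL = "OBSTACLE_FAIL"
    ERROR = "ERROR"


@dataclasses.dataclass
class PatchConfig:
    """Tunable protocol parameters, all in the printed protocol windows."""

    hunt_pressure_mbar: float = 60.0          # window [50, 70]
    position_pressure_mbar: float = 20.0      # window [10, 30]
    seal_pressure_mbar: float = -20.0         # window [-30, -10]
    breakin_pressure_mbar: float = -120.0     # window [-140, -100]
    contact_threshold_Mohm: float = 1.0       # window [0.7, 1.2]
    obstacle_threshold_Mohm: float | None = None  # defaults to contact threshold
    step_um: float = 2.0
    above_cell_offset_um: float = 5.0
    holding_target_mV: float = -60.0
    holding_step_mV: float = -10.0
    holding_interval_s: float = 1.0
    gigaseal_Mohm: float = 1000.0
    seal_deadline_s: float = 30.0
    breakin_timeout_s: float = 180.0
    inter_pulse_pause_s: float = 2.0
    fail_Rs_Mohm: float = 100.0
    cell_diameter_um: float = 10.0
    pullback_um: float = 6.0
    spiral_pitch_um: float = 1.0
    spiral_points_per_turn: int = 8
    spiral_max_radius_um: float = 15.0
    obstacle_pass_um: float = 16.0
    obstacle_lateral_exclusion_um: float = 10.0
    baseline_window: int = 5
    baseline_band_Mohm: float = 0.2
    dt_s: float = 0.05
    track_every_steps: int = 5
    alconox_position_um: tuple | None = None
    acsf_position_um: tuple | None = None

    _RANGES = {
        "hunt_pressure_mbar": (50.0, 70.0),
        "position_pressure_mbar": (10.0, 30.0),
        "seal_pressure_mbar": (-30.0, -10.0),
        "breakin_pressure_mbar": (-140.0, -100.0),
        "contact_threshold_Mohm": (0.7, 1.2),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigurationError(f"{name}={v} outside protocol window [{lo}, {hi}]")
        if not self.step_um > 0:
            raise ConfigurationError("step_um must be positive")
        if self.obstacle_threshold_Mohm is None:
            self.obstacle_threshold_Mohm = self.contact_threshold_Mohm


@dataclasses.dataclass
class PatchAttemptRecord:
    """Diary entry for one patching attempt."""

    target_um: np.ndarray
    outcome: Outcome = Outcome.ERROR
    Rs_Mohm: float | None = None
    #: rows of (time_s, phase, pressure_setpoint_mbar, pressure_actual_mbar,
    #: resistance_Mohm) at every simulation tick of the attempt
    phase_log: list = dataclasses.field(default_factory=list)
    events: list = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "target_um": [float(v) for v in np.asarray(self.target_um, float)],
            "outcome": self.outcome.value,
            "Rs_Mohm": None if self.Rs_Mohm is None else float(self.Rs_Mohm),
            "phase_log": [
                [float(t), ph, float(sp), float(pa), float(r)]
                for (t, ph, sp, pa, r) in self.phase_log
            ],
            "events": self.events,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatchAttemptRecord":
        rec = cls(np.asarray(d["target_um"], float))
        rec.outcome = Outcome(d["outcome"])
        rec.Rs_Mohm = d.get("Rs_Mohm")
        rec.phase_log = [tuple(row) for row in d.get("phase_log", [])]
        rec.events = list(d.get("events", []))
        return rec


@dataclasses.dataclass
class Trajectory:
    """Planned approach: hunting waypoints then a pure-Z descent segment."""

    hunt_waypoints_pipette: list   # cumulative pipette-frame offsets from start
    descent_step_pipette: np.ndarray
    staging_um: np.ndarray         # stage frame


def plan_trajectory(
    cal: CalibrationTransform, tip_um, target_um, cfg: PatchConfig
) -> Trajectory:
    """Plan a stepwise straight-line approach to a staging point above the cell.

    The pipette first travels (2 um steps, in its own coordinates) to a point
    ``above_cell_offset_um`` above the top of the target cell, then descends
    on it along pure manipulator Z.  Raises :class:`PlanningError` before any
    motion if the target is unreachable.
    """
    tip = np.asarray(tip_um, float)
    target = np.asarray(target_um, float)
    staging = target + np.array([0.0, 0.0, cfg.above_cell_offset_um + cfg.cell_diameter_um / 2.0])
    delta_p = cal.to_pipette(staging - tip)
    dist = float(np.linalg.norm(delta_p))
    if not np.all(np.isfinite(delta_p)):
        raise PlanningError("target not reachable through the calibration transform")
    n_steps = max(0, int(math.ceil(dist / cfg.step_um - 1e-9)))
    waypoints = [delta_p * ((i + 1) / n_steps) for i in range(n_steps)] if n_steps else []
    return Trajectory(
        hunt_waypoints_pipette=waypoints,
        descent_step_pipette=np.array([0.0, 0.0, -cfg.step_um]),
        staging_um=staging,
    )


class AttemptContext:
    """Mutable per-attempt state shared between the phase routines."""

    def __init__(self, rig: SimulatedRig, cfg: PatchConfig, cal: CalibrationTransform, record: PatchAttemptRecord, tracker=None):
        self.rig = rig
        self.cfg = cfg
        self.cal = cal
        self.record = record
        self.tracker = tracker
        self.baseline_reads: list = []
        self.target_um = np.asarray(record.target_um, float).copy()
        self.pipette_pos = np.zeros(3)  # cumulative pipette-frame offset

    # -- helpers ------------------------------------------------------------

    def log(self, event: str, **kw) -> None:
        s = self.rig.state
        row = {
            "t": round(float(s.sim_time_s), 4),
            "phase": s.phase.value,
            "event": event,
            "pressure_mbar": float(s.pressure_setpoint_mbar),
            "resistance_Mohm": round(float(s.resistance_Mohm), 4),
        }
        row.update(kw)
        self.record.events.append(row)

    def move(self, delta_pipette) -> None:
        delta = np.asarray(delta_pipette, float)
        self.rig.move_pipette(delta)
        self.pipette_pos = self.pipette_pos + delta
        self.rig.step(self.cfg.dt_s)

    def wait(self, seconds: float) -> None:
        n = max(1, int(round(seconds / self.cfg.dt_s)))
        for _ in range(n):
            self.rig.step(self.cfg.dt_s)

    def baseline(self) -> float:
        reads = self.baseline_reads[-self.cfg.baseline_window:]
        return float(np.mean(reads)) if reads else self.rig.baseline_R

    def lateral_distance_to_target(self) -> float:
        d = self.rig.state.tip_stage_um[:2] - self.target_um[:2]
        return float(np.linalg.norm(d))

    def apply_tracking(self) -> None:
        """Query the (optional) tracker at a halt point and shift the target."""
        if self.tracker is None:
            return
        dxyz = np.asarray(self.tracker(), float)
        if np.any(dxyz != 0.0):
            self.target_um = self.target_um + dxyz
            self.log("tracking_update", dxyz_um=[float(v) for v in dxyz])


# ---------------------------------------------------------------------------
# Phase routines


def hunt_step(ctx: AttemptContext, waypoint_delta) -> str:
    """Advance one hunting waypoint and classify {clear, obstacle, arrived}."""
    ctx.move(waypoint_delta)
    r = ctx.rig.read_resistance()
    if r - ctx.baseline() >= ctx.cfg.obstacle_threshold_Mohm - 1e-9 and (
        ctx.lateral_distance_to_target() > ctx.cfg.obstacle_lateral_exclusion_um
    ):
        ctx.log("obstacle_detected", delta_R=round(r - ctx.baseline(), 4))
        return "obstacle"
    ctx.baseline_reads.append(r)
    return "clear"


def _spiral_offsets(cfg: PatchConfig):
    """Archimedean spiral probe offsets in the pipette's lateral (Y, Z) plane."""
    k = 0
    while True:
        k += 1
        theta = 2 * math.pi * k / cfg.spiral_points_per_turn
        r = cfg.spiral_pitch_um * theta / (2 * math.pi)
        if r > cfg.spiral_max_radius_um:
            return
        yield np.array([0.0, r * math.cos(theta), r * math.sin(theta)])


def avoid_obstacle(ctx: AttemptContext, axis_dir_pipette: np.ndarray) -> bool:
    """Spiral avoidance manoeuvre.  Returns True once the obstacle is passed.

    Numbered sub-steps, mirroring the published procedure: 1 forward motion
    stopped at the obstacle, 2 pull back, 3 lateral spiral until the
    resistance is back to normal, 4 advance past the obstacle, 5 readjust to
    the trajectory, 6 approach continues.
    """
    cfg = ctx.cfg
    base = ctx.baseline()
    ctx.log("avoidance_step", n=1, detail="forward motion stopped at obstacle")
    ctx.move(-axis_dir_pipette * cfg.pullback_um)
    ctx.log("avoidance_step", n=2, detail="pulled back")
    n_pass = max(1, int(math.ceil(cfg.obstacle_pass_um / cfg.step_um)))
    for offset in _spiral_offsets(cfg):
        ctx.move(offset)
        r = ctx.rig.read_resistance()
        ctx.log("avoidance_step", n=3, detail="spiral probe", radius_um=round(float(np.linalg.norm(offset)), 3))
        if abs(r - base) <= cfg.baseline_band_Mohm:
            # try to slip past the obstacle at this lateral offset
            advanced = 0
            blocked = False
            for _ in range(n_pass):
                ctx.move(axis_dir_pipette * cfg.step_um)
                advanced += 1
                if ctx.rig.read_resistance() - base >= cfg.obstacle_threshold_Mohm - 1e-9:
                    blocked = True
                    break
            if not blocked:
                ctx.log("avoidance_step", n=4, detail="obstacle passed")
                ctx.move(-offset)
                ctx.log("avoidance_step", n=5, detail="readjusted to trajectory")
                ctx.log("avoidance_step", n=6, detail="approach continued")
                return True
            ctx.move(-axis_dir_pipette * (advanced * cfg.step_um))
        ctx.move(-offset)
    return False


def run_hunt(ctx: AttemptContext, traj: Trajectory) -> bool:
    """Hunting phase toward the staging point.  False on OBSTACLE_FAIL."""
    cfg = ctx.cfg
    ctx.rig.set_phase(Phase.HUNT)
    ctx.rig.set_pressure(cfg.hunt_pressure_mbar)
    ctx.wait(3 * ctx.rig.tau)  # let the pressure settle before moving
    # seed the baseline with a few clear reads
    for _ in range(cfg.baseline_window):
        ctx.baseline_reads.append(ctx.rig.read_resistance())
        ctx.rig.step(cfg.dt_s)
    prev = np.zeros(3)
    waypoints = list(traj.hunt_waypoints_pipette)
    i = 0
    steps_since_track = 0
    while i < len(waypoints):
        wp = waypoints[i]
        outcome = hunt_step(ctx, wp - prev)
        if outcome == "obstacle":
            axis = wp - prev
            norm = np.linalg.norm(axis)
            axis = axis / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
            if not avoid_obstacle(ctx, axis):
                return False
            # replan the remainder from the current tip position
            traj2 = plan_trajectory(ctx.cal, ctx.rig.state.tip_stage_um, ctx.target_um, cfg)
            waypoints = [ctx.pipette_pos + w for w in traj2.hunt_waypoints_pipette]
            prev = ctx.pipette_pos.copy()
            i = 0
            continue
        prev = wp
        i += 1
        steps_since_track += 1
        if steps_since_track >= cfg.track_every_steps:
            steps_since_track = 0
            ctx.apply_tracking()
            traj2 = plan_trajectory(ctx.cal, ctx.rig.state.tip_stage_um, ctx.target_um, cfg)
            if traj2.hunt_waypoints_pipette:
                waypoints = [ctx.pipette_pos + w for w in traj2.hunt_waypoints_pipette]
                prev = ctx.pipette_pos.copy()
                i = 0
    ctx.log("arrived_at_staging")
    return True


def descend_to_cell(ctx: AttemptContext) -> bool:
    """Z descent with impedance monitoring; True on the contact event."""
    cfg = ctx.cfg
    ctx.apply_tracking()
    ctx.rig.set_phase(Phase.DESCEND)
    ctx.rig.set_pressure(cfg.position_pressure_mbar)
    ctx.wait(3 * ctx.rig.tau)
    base = ctx.baseline()
    max_travel = 2.0 * cfg.above_cell_offset_um + cfg.cell_diameter_um
    travelled = 0.0
    step = np.array([0.0, 0.0, -cfg.step_um])
    while travelled <= max_travel + 1e-9:
        ctx.move(step)
        travelled += cfg.step_um
        r = ctx.rig.read_resistance()
        if r - base >= cfg.contact_threshold_Mohm - 1e-9:
            ctx.log("contact", delta_R=round(r - base, 4))
            return True
    ctx.log("missed_cell", travelled_um=travelled)
    return False


def form_seal(ctx: AttemptContext) -> bool:
    """Gigaseal formation with the escalation protocol.

    Cease pressure immediately on contact, apply gentle vacuum and ramp the
    holding potential to -60 mV in steps.  If no gigaseal within 30 s:
    amplify the vacuum x1.5 then x2 (20 s each), wiggle the pipette +/-2 um
    per axis (2 s each), release the vacuum for 10 s, reapply for 20 s.
    """
    cfg = ctx.cfg
    rig = ctx.rig
    rig.set_phase(Phase.SEAL)
    rig.set_pressure(0.0)
    ctx.log("pressure_ceased")
    ctx.wait(0.5)
    rig.set_pressure(cfg.seal_pressure_mbar)
    ctx.log("seal_vacuum_applied")

    holding = 0.0
    next_hold_t = rig.state.sim_time_s

    def tick(duration: float) -> bool:
        """Advance sim time, ramping the holding potential; True on gigaseal."""
        nonlocal holding, next_hold_t
        n = max(1, int(round(duration / cfg.dt_s)))
        for _ in range(n):
            if holding > cfg.holding_target_mV and rig.state.sim_time_s >= next_hold_t:
                holding = max(cfg.holding_target_mV, holding + cfg.holding_step_mV)
                rig.set_holding(holding)
                next_hold_t += cfg.holding_interval_s
            rig.step(cfg.dt_s)
            if rig.read_resistance() >= cfg.gigaseal_Mohm:
                return True
        return False

    if tick(cfg.seal_deadline_s):
        ctx.log("gigaseal")
        return True
    for factor in (1.5, 2.0):
        rig.set_pressure(cfg.seal_pressure_mbar * factor)
        ctx.log("escalation_vacuum", factor=factor)
        if tick(20.0):
            ctx.log("gigaseal")
            return True
    rig.set_pressure(cfg.seal_pressure_mbar)
    for axis in range(3):
        delta = np.zeros(3)
        delta[axis] = 2.0
        ctx.log("escalation_wiggle", axis="xyz"[axis])
        rig.move_pipette(delta)
        if tick(1.0):
            ctx.log("gigaseal")
            return True
        rig.move_pipette(-delta)
        if tick(1.0):
            ctx.log("gigaseal")
            return True
    rig.set_pressure(0.0)
    ctx.log("escalation_release")
    if tick(10.0):
        ctx.log("gigaseal")
        return True
    rig.set_pressure(cfg.seal_pressure_mbar)
    ctx.log("escalation_reapply")
    if tick(20.0):
        ctx.log("gigaseal")
        return True
    ctx.log("seal_failed")
    return False


def break_in(ctx: AttemptContext) -> bool:
    """Suction-pulse break-in; pulse k lasts 0.5 + 0.2*k s, bounded at 3 min."""
    cfg = ctx.cfg
    rig = ctx.rig
    rig.set_phase(Phase.BREAKIN)
    t0 = rig.state.sim_time_s
    attempt = 0
    while True:
        attempt += 1
        duration = 0.5 + 0.2 * attempt
        if rig.state.sim_time_s - t0 + duration > cfg.breakin_timeout_s:
            ctx.log("breakin_timeout", attempts=attempt - 1)
            return False
        rig.set_pressure(cfg.breakin_pressure_mbar)
        ctx.log("breakin_pulse", attempt=attempt, duration_s=round(duration, 3))
        ctx.wait(duration)
        rig.set_pressure(0.0)
        ctx.wait(min(cfg.inter_pulse_pause_s, max(cfg.dt_s, cfg.breakin_timeout_s - (rig.state.sim_time_s - t0))))
        if rig.read_resistance() < cfg.gigaseal_Mohm / 2.0 and rig.ruptured:
            ctx.log("membrane_ruptured", attempt=attempt)
            return True
        if rig.state.sim_time_s - t0 >= cfg.breakin_timeout_s:
            ctx.log("breakin_timeout", attempts=attempt)
            return False


def clean_pipette(rig: SimulatedRig, cfg: PatchConfig, record: PatchAttemptRecord | None = None) -> None:
    """Two-bath pipette cleaning.

    Detergent (Alconox) bath: -300 mbar for 4 s, then +1000/-300 mbar
    alternated for 1 s each five times, then +1000 mbar for 10 s.  Rinse
    (aCSF) bath: +1000 mbar for 10 s.  Finally return to the start position.
    Pressure setpoints are only ever -300, +1000 or 0 mbar.
    """
    if cfg.alconox_position_um is None or cfg.acsf_position_um is None:
        raise ConfigurationError("cleaning bath positions are not calibrated")
    record = record if record is not None else PatchAttemptRecord(rig.state.tip_stage_um.copy())
    ctx = AttemptContext(rig, cfg, CalibrationTransform(np.eye(3)), record)
    rig.set_phase(Phase.CLEAN)
    start = rig.state.tip_stage_um.copy()

    def goto(pos_um, label):
        rig.set_pressure(0.0)
        rig.state.tip_stage_um = np.asarray(pos_um, float).copy()
        rig.step(cfg.dt_s)
        ctx.log("cleaning_move", bath=label)

    ctx.log("cleaning_start", bath="alconox")
    goto(cfg.alconox_position_um, "alconox")
    rig.set_pressure(-300.0)
    ctx.wait(4.0)
    for _ in range(5):
        rig.set_pressure(1000.0)
        ctx.wait(1.0)
        rig.set_pressure(-300.0)
        ctx.wait(1.0)
    rig.set_pressure(1000.0)
    ctx.wait(10.0)
    goto(cfg.acsf_position_um, "acsf")
    rig.set_pressure(1000.0)
    ctx.wait(10.0)
    goto(start, "start")
    rig.set_pressure(0.0)
    rig.reset_patch()
    ctx.log("cleaning_end", bath="acsf")


def harvest_cytoplasm(rig: SimulatedRig, cfg: PatchConfig, record: PatchAttemptRecord | None = None, mid_stage_s: float = 150.0) -> None:
    """Gentle cytoplasm aspiration in the whole-cell configuration.

    Pressure sequence -40 mbar (1 min), -60 mbar (2-3 min, default 150 s),
    -40 mbar (1 min).  Raises :class:`StateError` outside whole-cell.
    """
    if rig.state.phase is not Phase.WHOLE_CELL:
        raise StateError(f"cytoplasm harvest requires WHOLE_CELL, rig is in {rig.state.phase.value}")
    record = record if record is not None else PatchAttemptRecord(rig.state.tip_stage_um.copy())
    ctx = AttemptContext(rig, cfg, CalibrationTransform(np.eye(3)), record)
    for pressure, duration in ((-40.0, 60.0), (-60.0, mid_stage_s), (-40.0, 60.0)):
        rig.set_pressure(pressure)
        ctx.log("harvest_stage", stage_pressure_mbar=pressure, duration_s=duration)
        ctx.wait(duration)
    rig.set_pressure(0.0)
    ctx.log("harvest_done")


def run_autopatch(
    rig: SimulatedRig,
    target_um,
    cfg: PatchConfig | None = None,
    cal: CalibrationTransform | None = None,
    tracker=None,
) -> PatchAttemptRecord:
    """Execute one complete patching attempt and return its diary record.

    ``tracker`` is an optional zero-argument callable returning the measured
    (dx, dy, dz) drift of the target in micrometres since the last query; it
    is invoked only while the pipette is halted.
    """
    cfg = cfg or PatchConfig()
    cal = cal if cal is not None else CalibrationTransform(rig.A.copy())
    target = np.asarray(target_um, float)
    record = PatchAttemptRecord(target_um=target.copy())
    log_start = len(rig.history)
    ctx = AttemptContext(rig, cfg, cal, record, tracker=tracker)
    try:
        traj = plan_trajectory(cal, rig.state.tip_stage_um, target, cfg)
        reach = np.abs(cal.to_pipette(traj.staging_um - rig.state.tip_stage_um))
        if np.any(reach > rig.travel_limit_um):
            raise PlanningError("target outside manipulator travel range")
        if not run_hunt(ctx, traj):
            record.outcome = Outcome.OBSTACLE_FAIL
        elif not descend_to_cell(ctx):
            record.outcome = Outcome.ERROR
        elif not form_seal(ctx):
            record.outcome = Outcome.SEAL_FAIL
        elif not break_in(ctx):
            record.outcome = Outcome.BREAKIN_FAIL
        else:
            rs = rig.read_resistance() - rig.baseline_R
            record.Rs_Mohm = float(rs)
            if rs <= cfg.fail_Rs_Mohm:
                rig.set_phase(Phase.WHOLE_CELL)
                record.outcome = Outcome.WHOLE_CELL
                ctx.log("whole_cell", Rs_Mohm=round(rs, 3))
            else:
                record.outcome = Outcome.BREAKIN_FAIL
                ctx.log("rs_too_high", Rs_Mohm=round(rs, 3))
    except (PlanningError, TravelLimitError, StateError, AutopatchError) as exc:
        record.outcome = Outcome.ERROR
        record.events.append({"t": float(rig.state.sim_time_s), "phase": rig.state.phase.value, "event": "error", "detail": str(exc)})
    if record.outcome in (Outcome.SEAL_FAIL, Outcome.BREAKIN_FAIL, Outcome.OBSTACLE_FAIL, Outcome.ERROR):
        if rig.state.phase is not Phase.IDLE:
            rig.set_phase(Phase.FAIL)
    record.phase_log = [tuple(row) for row in rig.history[log_start:]]
    return record
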