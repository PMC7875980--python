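"""Simulated electrophysiology rig: manipulator, pressure controller, amplifier.

The rig stands in for the hardware stack so the controller can be exercised
end to end.  Its physics is deliberately minimal but honours the observable
contracts a real rig presents to the software:

* pipette resistance 3.5-5 MOhm, monitored by 5 ms / -5 mV test steps;
* a resistance jump when the tip touches a cell (or an obstacle en route);
* seal resistance that grows toward a gigaseal under gentle suction while
  cell-attached, first-order in time with a rate proportional to the vacuum;
* membrane rupture once the cumulative suction impulse (|pressure| x pulse
  duration) of break-in pulses on a gigasealed patch exceeds a threshold,
  after which the measured resistance drops to the cell's access resistance;
* first-order pressure dynamics toward the commanded setpoint;
* a hidden manipulator-to-stage calibration matrix (default: pipette X axis
  tilted -33 degrees from horizontal) that the calibration module must
  recover.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np

from .errors import AutopatchError, TravelLimitError
from .phantom import GroundTruthCell

#: Seal ceiling: seals saturate around 2 GOhm, so 1 GOhm is crossed on the way.
SEAL_R_MAX_MOHM = 2000.0
#: Tip-to-membrane distance at which contact is registered, added to the cell
#: radius.
CONTACT_MARGIN_UM = 1.0
#: Contact resistance jump, the center of the 0.7-1.2 MOhm detection window.
DEFAULT_CONTACT_JUMP_MOHM = 1.0
#: Suction stronger than this counts toward the rupture impulse; it separates
#: break-in pulses (-100 mbar and beyond) from seal vacuum (>= -60 mbar).
RUPTURE_PRESSURE_GATE_MBAR = -80.0


class Phase(str, enum.Enum):
    IDLE = "IDLE"
    HUNT = "HUNT"
    DESCEND = "DESCEND"
    SEAL = "SEAL"
    BREAKIN = "BREAKIN"
    WHOLE_CELL = "WHOLE_CELL"
    CLEAN = "CLEAN"
    FAIL = "FAIL"


@dataclasses.dataclass
class ObstacleSpec:
    """A blocking structure (blood vessel, another cell) on the pipette path."""

    center_um: np.ndarray
    radius_um: float
    resistance_bump_Mohm: float = 2.0

    def __post_init__(self) -> None:
        self.center_um = np.asarray(self.center_um, dtype=float)
        if not self.radius_um > 0:
            raise AutopatchError("obstacle radius must be positive")


@dataclasses.dataclass
class RigState:
    """Snapshot of the simulated rig."""

    tip_stage_um: np.ndarray
    pressure_setpoint_mbar: float = 0.0
    pressure_actual_mbar: float = 0.0
    resistance_Mohm: float = 4.0
    holding_potential_mV: float = 0.0
    phase: Phase = Phase.IDLE
    sim_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.tip_stage_um = np.asarray(self.tip_stage_um, dtype=float)


def default_hidden_calibration(tilt_deg: float = 33.0) -> np.ndarray:
    """True manipulator->stage matrix: X axis descends at ``tilt_deg``.

    Advancing along the manipulator X axis moves the tip forward and down
    (negative stage z); Y and Z axes coincide with the stage axes.
    """
    t = math.radians(tilt_deg)
    return np.array(
        [
            [math.cos(t), 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [-math.sin(t), 0.0, 1.0],
        ]
    )


class SimulatedRig:
    """Discrete-time rig simulation.

    Parameters
    ----------
    cells, obstacles:
        The hidden scene, in stage micrometres.
    start_tip_um:
        Initial pipette tip position (stage frame).
    hidden_calibration:
        The true 3x3 manipulator->stage matrix; the software only ever sees
        its effect on the tip position.
    seed:
        Seeds the pipette's baseline resistance draw (3.5-5 MOhm) and any
        enabled sensor noise.
    """

    def __init__(
        self,
        cells=None,
        obstacles=None,
        start_tip_um=(0.0, 0.0, 60.0),
        hidden_calibration=None,
        pressure_tau_s: float = 0.2,
        travel_limit_um: float = 10000.0,
        contact_jump_Mohm: float = DEFAULT_CONTACT_JUMP_MOHM,
        resistance_noise_Mohm: float = 0.0,
        seed: int = 0,
    ) -> None:
        self.cells = list(cells or [])
        self.obstacles = list(obstacles or [])
        self.A = (
            default_hidden_calibration() if hidden_calibration is None else np.asarray(hidden_calibration, float)
        )
        self.tau = pressure_tau_s
        self.travel_limit_um = travel_limit_um
        self.contact_jump = contact_jump_Mohm
        self.noise = resistance_noise_Mohm
        self.rng = np.random.default_rng(seed)
        self.baseline_R = float(self.rng.uniform(3.5, 5.0))
        self.state = RigState(tip_stage_um=np.asarray(start_tip_um, float), resistance_Mohm=self.baseline_R)
        self._cum_pipette_move = np.zeros(3)
        self.seal_R = 0.0
        self.sealed_cell: GroundTruthCell | None = None
        self.ruptured = False
        self.rupture_impulse = 0.0
        self.history: list = []  # (t, phase, setpoint, actual, R)
        self._log()

    # -- bookkeeping --------------------------------------------------------

    def _log(self) -> None:
        s = self.state
        self.history.append(
            (s.sim_time_s, s.phase.value, s.pressure_setpoint_mbar, s.pressure_actual_mbar, s.resistance_Mohm)
        )

    def _contact_cell(self) -> GroundTruthCell | None:
        for c in self.cells:
            if np.linalg.norm(self.state.tip_stage_um - c.centroid_um) <= c.radius_um + CONTACT_MARGIN_UM:
                return c
        return None

    # -- commands -----------------------------------------------------------

    def set_pressure(self, mbar: float) -> None:
        self.state.pressure_setpoint_mbar = float(mbar)

    def set_holding(self, mV: float) -> None:
        self.state.holding_potential_mV = float(mV)

    def set_phase(self, phase: Phase) -> None:
        self.state.phase = phase

    def move_pipette(self, delta_pipette_um) -> RigState:
        """Move the manipulator by ``delta`` in its own axes.

        The stage-frame displacement is ``A @ delta`` with the hidden true
        calibration.  Moves are linear, so successive moves commute to their
        sum.  Raises :class:`TravelLimitError` beyond the travel range.
        """
        delta = np.asarray(delta_pipette_um, dtype=float)
        new_cum = self._cum_pipette_move + delta
        if np.any(np.abs(new_cum) > self.travel_limit_um):
            raise TravelLimitError(f"move to {new_cum} exceeds travel limit {self.travel_limit_um} um")
        self._cum_pipette_move = new_cum
        self.state.tip_stage_um = self.state.tip_stage_um + self.A @ delta
        return self.state

    def read_resistance(self) -> float:
        """Measured tip resistance in MOhm (5 ms, -5 mV test-step protocol).

        The simulated current response to the -5 mV step obeys Ohm's law,
        ``I = V / R``; see :meth:`test_step_current_nA`.
        """
        r = self.baseline_R
        if self.ruptured and self.sealed_cell is not None:
            r += self.sealed_cell.access_resistance_Mohm
        else:
            for ob in self.obstacles:
                if np.linalg.norm(self.state.tip_stage_um - ob.center_um) <= ob.radius_um:
                    r += ob.resistance_bump_Mohm
            if self._contact_cell() is not None:
                r += self.contact_jump
            r += self.seal_R
        if self.noise > 0:
            r += float(self.rng.normal(0.0, self.noise))
        self.state.resistance_Mohm = max(r, self.baseline_R)
        return self.state.resistance_Mohm

    def test_step_current_nA(self, step_mV: float = -5.0) -> float:
        """Current response of the test voltage step; |I| = |V|/R."""
        return step_mV / self.read_resistance()

    def step(self, dt_s: float) -> RigState:
        """Advance the simulation clock by ``dt_s``.

        Pressure relaxes exponentially toward the setpoint; the seal grows
        while cell-attached under vacuum; accumulated suction impulse beyond
        the cell's rupture threshold breaks the gigasealed membrane.
        """
        if not dt_s > 0:
            raise AutopatchError("dt_s must be positive")
        s = self.state
        # first-order pressure response (exact update)
        alpha = math.exp(-dt_s / self.tau)
        s.pressure_actual_mbar = (
            s.pressure_setpoint_mbar + (s.pressure_actual_mbar - s.pressure_setpoint_mbar) * alpha
        )
        # seal dynamics
        cell = self.sealed_cell if self.sealed_cell is not None else self._contact_cell()
        if cell is not None and not self.ruptured:
            if s.pressure_actual_mbar < 0.0 and cell.sealable:
                self.sealed_cell = cell
                k = cell.seal_rate_per_mbar_s * min(abs(s.pressure_actual_mbar), 30.0)
                self.seal_R = SEAL_R_MAX_MOHM - (SEAL_R_MAX_MOHM - self.seal_R) * math.exp(-k * dt_s)
            # rupture accounting: only on a gigasealed patch during strong suction
            if self.is_gigasealed() and s.pressure_actual_mbar <= RUPTURE_PRESSURE_GATE_MBAR:
                self.rupture_impulse += abs(s.pressure_actual_mbar) * dt_s
                if self.rupture_impulse >= cell.rupture_threshold_mbar_s:
                    self.ruptured = True
        s.sim_time_s += dt_s
        self.read_resistance()
        self._log()
        return s

    def is_gigasealed(self, threshold_Mohm: float = 1000.0) -> bool:
        return self.baseline_R + self.seal_R >= threshold_Mohm

    def reset_patch(self) -> None:
        """Forget seal/rupture state, e.g. after cleaning and retraction."""
        self.seal_R = 0.0
        self.sealed_cell = None
        self.ruptured = False
        self.rupture_impulse = 0.0
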