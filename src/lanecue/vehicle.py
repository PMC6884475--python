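"""Constant-speed vehicle and the closed-loop trial runner.

The vehicle is a kinematic bicycle: the road-wheel angle is the steering
wheel angle divided by the steering ratio, the yaw rate is
``v * tan(delta) / wheelbase``, and the position advances ``v * dt`` along
the updated heading each step (semi-implicit Euler at a fixed step).  There
is no longitudinal control: speed is constant within a trial, as in a
simulator that needs no pedal input.

:func:`simulate_trial` closes the loop between a course, a steering
controller and the vehicle, producing a :class:`TrialLog` with one record
per simulation step.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Protocol

import numpy as np
import pandas as pd

from .course import RoadCourse

__all__ = [
    "VehicleParams",
    "VehicleState",
    "TrialLog",
    "SteeringController",
    "step",
    "simulate_trial",
    "DEFAULT_SPEED_MPS",
    "DEFAULT_DT",
]

#: Constant vehicle speed, m/s (80 km/h).
DEFAULT_SPEED_MPS = 80.0 / 3.6
#: Simulation time step, s.
DEFAULT_DT = 1.0 / 60.0


@dataclass(frozen=True)
class VehicleParams:
    """Kinematic-bicycle parameters (commodity-car defaults).

    ``steering_ratio`` converts steering-wheel angle to road-wheel angle;
    ``sw_max`` and ``sw_rate_max`` clamp and slew-limit the wheel.
    """

    wheelbase: float = 2.7
    steering_ratio: float = 15.0
    sw_max: float = 2.0 * math.pi
    sw_rate_max: float = 2.0 * math.pi

    def __post_init__(self):
        for name in ("wheelbase", "steering_ratio", "sw_max", "sw_rate_max"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class VehicleState:
    """Planar pose plus steering-wheel angle of the constant-speed vehicle."""

    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0
    speed: float = DEFAULT_SPEED_MPS
    sw_angle: float = 0.0


def step(
    state: VehicleState,
    sw_command: float,
    params: VehicleParams = VehicleParams(),
    dt: float = DEFAULT_DT,
) -> VehicleState:
    """Advance the vehicle one time step under a steering-wheel command.

    The command is clamped to ``±sw_max`` and slew-limited to
    ``sw_rate_max``; the heading is updated first and the position then
    advances ``speed * dt`` along the new heading, so the per-step
    displacement norm is exactly ``speed * dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isfinite(sw_command):
        raise ValueError("sw_command must be finite")
    sw_cmd = max(-params.sw_max, min(sw_command, params.sw_max))
    max_delta = params.sw_rate_max * dt
    sw = state.sw_angle + max(-max_delta, min(sw_cmd - state.sw_angle, max_delta))
    delta = sw / params.steering_ratio
    heading = state.heading + state.speed * math.tan(delta) / params.wheelbase * dt
    x = state.x + state.speed * math.cos(heading) * dt
    y = state.y + state.speed * math.sin(heading) * dt
    return replace(state, x=x, y=y, heading=heading, sw_angle=sw)


class SteeringController(Protocol):
    """Steering policy driven by the trial runner.

    ``reset`` is called once before the trial with the step count and the
    trial's random generator; ``command`` is called every step with the
    current time, vehicle state and road-relative observables and returns
    ``(sw_command, level_left_db, level_right_db)``.  Controllers without an
    auditory display return NaN ear levels.
    """

    def reset(self, n_steps: int, rng: np.random.Generator) -> None: ...

    def command(
        self,
        i: int,
        t: float,
        state: VehicleState,
        deviation: float,
        s_proj: float,
        tangent_heading: float,
        course: RoadCourse,
    ) -> tuple[float, float, float]: ...


_LOG_COLUMNS = (
    "t",
    "x",
    "y",
    "s_proj",
    "deviation",
    "sw_angle",
    "sw_velocity",
    "level_L",
    "level_R",
    "segment_kind",
)


@dataclass
class TrialLog:
    """Per-step record of one closed-loop trial.

    Column arrays all have length ``n_steps``; ``segment_kind`` is 1 where
    the vehicle's centreline projection lies in a bend, 0 on a straight.
    ``sw_velocity`` is the backward difference of ``sw_angle`` over ``dt``
    (zero at the first record).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    s_proj: np.ndarray
    deviation: np.ndarray
    sw_angle: np.ndarray
    sw_velocity: np.ndarray
    level_L: np.ndarray
    level_R: np.ndarray
    segment_kind: np.ndarray
    dt: float
    off_road: bool = False
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c) for c in _LOG_COLUMNS})
        df["segment_kind"] = np.where(self.segment_kind == 1, "arc", "straight")
        return df

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, dt: float | None = None) -> "TrialLog":
        df = pd.read_csv(path_or_buf)
        kind = (df["segment_kind"].to_numpy() == "arc").astype(np.int8)
        t = df["t"].to_numpy(float)
        if dt is None:
            dt = float(np.median(np.diff(t))) if len(t) > 1 else DEFAULT_DT
        return cls(
            t=t,
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            s_proj=df["s_proj"].to_numpy(float),
            deviation=df["deviation"].to_numpy(float),
            sw_angle=df["sw_angle"].to_numpy(float),
            sw_velocity=df["sw_velocity"].to_numpy(float),
            level_L=df["level_L"].to_numpy(float),
            level_R=df["level_R"].to_numpy(float),
            segment_kind=kind,
            dt=dt,
        )

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def simulate_trial(
    course: RoadCourse,
    controller: SteeringController,
    duration: float = 60.0,
    dt: float = DEFAULT_DT,
    params: VehicleParams = VehicleParams(),
    seed: int | np.random.SeedSequence | None = 0,
    speed: float = DEFAULT_SPEED_MPS,
    sanity_factor: float = 3.0,
) -> TrialLog:
    """Run one closed-loop trial and return its log.

    The vehicle starts on the lane centre at ``s = 0``, heading along the
    tangent, wheel centred.  Each step the vehicle position is projected
    onto the centreline, the controller is queried, and the vehicle is
    stepped; exactly ``ceil(duration / dt)`` records are logged.  If the
    vehicle ever strays beyond ``sanity_factor * lane_width`` from the
    centre the log is flagged ``off_road`` but the trial runs to completion,
    as a human trial would.

    Identical seeds (and a deterministic controller) reproduce the log
    bit for bit.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    n = math.ceil(duration / dt)
    rng = np.random.default_rng(seed)
    controller.reset(n, rng)

    x0, y0, h0, _ = course.pose(0.0)
    state = VehicleState(x=x0, y=y0, heading=h0, speed=speed, sw_angle=0.0)

    cols = {c: np.empty(n) for c in _LOG_COLUMNS if c != "segment_kind"}
    kind = np.empty(n, dtype=np.int8)
    off_road = False
    bound = sanity_factor * course.lane_width
    s_hint = 0.0
    prev_sw = 0.0

    project = course._project_full
    cmd = controller.command
    for i in range(n):
        t = i * dt
        dev, s_proj, h_tan, in_arc = project(state.x, state.y, s_hint)
        s_hint = s_proj
        if abs(dev) > bound:
            off_road = True
        sw_command, lev_l, lev_r = cmd(i, t, state, dev, s_proj, h_tan, course)
        cols["t"][i] = t
        cols["x"][i] = state.x
        cols["y"][i] = state.y
        state = step(state, sw_command, params, dt)
        cols["s_proj"][i] = s_proj
        cols["deviation"][i] = dev
        cols["sw_angle"][i] = state.sw_angle
        cols["sw_velocity"][i] = (state.sw_angle - prev_sw) / dt if i else 0.0
        cols["level_L"][i] = lev_l
        cols["level_R"][i] = lev_r
        kind[i] = 1 if in_arc else 0
        prev_sw = state.sw_angle
    return TrialLog(segment_kind=kind, dt=dt, off_road=off_road, **cols)
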