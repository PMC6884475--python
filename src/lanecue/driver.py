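"""Synthetic driver agents: the pipeline's participant model.

Human participants steer with two loosely coupled processes: a
*compensatory* feedback loop that nulls the lateral deviation perceived
from the near road, and an *anticipatory* feedforward that turns the wheel
for the curvature previewed on the far road about a second before the bend.
The agent implements exactly this two-level controller, plus the machinery
that makes it behave like a participant rather than a servo: sensory noise,
a perceptual sampling-and-hold stage, a reaction-time delay, first-order arm
dynamics, and motor noise.

Sensory conditions gate the channels:

* **ND** (normal driving): near-road deviation is visible (with visual
  noise); far-road curvature is visible.
* **VO** (visual occlusion): the near road is occluded — no deviation
  estimate at all; the compensatory term falls back to zero and only the
  heading loop restrains drift.  Far curvature stays visible (the upper
  scene is never occluded).
* **SS** (sensory substitution): near road occluded, but the deviation is
  recovered by decoding the binaural level pattern.  Decoding is noisy and
  the noise SD shrinks exponentially over training trials — the agent's
  model of learning to exploit the auditory channel:
  ``sigma_audio(t) = sigma_audio_min + (sigma_audio0 - sigma_audio_min) *
  exp(-learn_rate * t)``.

Individual differences come from :func:`sample_participant`, which jitters
every parameter around population means.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, fields, replace

import numpy as np

from . import audio
from .course import RoadCourse
from .vehicle import VehicleParams, VehicleState

__all__ = [
    "Condition",
    "Percept",
    "DriverParams",
    "PopulationSpec",
    "default_population",
    "perceive",
    "steer",
    "sample_participant",
    "DriverAgent",
]


class Condition(enum.Enum):
    """Sensory condition of a trial (not of a participant: pre/post test
    trials run every group under ND)."""

    ND = "ND"
    VO = "VO"
    SS = "SS"

    @property
    def near_available(self) -> bool:
        return self is Condition.ND

    @property
    def audio_available(self) -> bool:
        return self is Condition.SS


@dataclass(frozen=True)
class Percept:
    """One perceptual sample of the road, possibly degraded.

    ``near_deviation`` is None when the proximal road is occluded (VO, SS);
    ``audio_deviation`` is present only under SS.  ``far_curvature`` (the
    previewed bend curvature) and ``heading_error`` (vehicle heading minus
    path tangent) are always available.
    """

    far_curvature: float
    heading_error: float
    near_deviation: float | None = None
    audio_deviation: float | None = None

    @property
    def deviation_estimate(self) -> float:
        """Best available lateral-deviation estimate (0 when blind to it)."""
        if self.near_deviation is not None:
            return self.near_deviation
        if self.audio_deviation is not None:
            return self.audio_deviation
        return 0.0


@dataclass(frozen=True)
class DriverParams:
    """Two-level-controller parameters of one synthetic participant.

    Control gains
        ``k_ant`` — dimensionless gain on the steering-wheel angle that
        geometrically matches the previewed curvature (1.0 = exact
        feedforward); ``k_comp`` — steering-wheel rad per metre of perceived
        lateral deviation; ``k_head`` — steering-wheel rad per rad of
        heading error.  Both feedback terms act with negative sign (steer
        back toward the centre).
    Timing
        ``preview_time`` — how far ahead (s at current speed) the far road
        is sampled; ``reaction_delay`` — dead time between percept and wheel
        (a discrete delay line); ``perceive_interval`` — perceptual
        sample-and-hold period; ``arm_tau`` — first-order lag of the arm;
        ``est_tau`` — time constant of the running average the driver keeps
        over the (noisy) deviation estimate before acting on it.
    Noise (SDs)
        ``sigma_visual`` (m) on the seen deviation, ``sigma_far`` (1/m) on
        previewed curvature, ``sigma_heading`` (rad) on heading error,
        ``sigma_motor`` (steering-wheel rad, per step) on the executed
        command, and the audio-decoding noise schedule
        ``sigma_audio0 -> sigma_audio_min`` at rate ``learn_rate`` per
        training trial.
    """

    k_ant: float = 1.0
    k_comp: float = 0.12
    k_head: float = 3.5
    preview_time: float = 1.0
    reaction_delay: float = 0.2
    perceive_interval: float = 0.25
    arm_tau: float = 0.1
    est_tau: float = 0.5
    sigma_visual: float = 0.06
    sigma_far: float = 0.0006
    sigma_heading: float = 0.0045
    sigma_audio0: float = 1.2
    sigma_audio_min: float = 0.06
    learn_rate: float = 0.12
    sigma_motor: float = 0.012

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")
        if self.sigma_audio_min > self.sigma_audio0:
            raise ValueError("sigma_audio_min must not exceed sigma_audio0")

    def sigma_audio(self, trial_index: int) -> float:
        """Audio-decoding noise SD after ``trial_index`` training trials."""
        return self.sigma_audio_min + (
            self.sigma_audio0 - self.sigma_audio_min
        ) * math.exp(-self.learn_rate * trial_index)


def perceive(
    state: VehicleState,
    course: RoadCourse,
    condition: Condition,
    trial_index: int,
    params: DriverParams,
    rng: np.random.Generator,
    encoder: audio.EncoderParams = audio.EncoderParams(),
    deviation: float | None = None,
    s_proj: float | None = None,
    tangent_heading: float | None = None,
) -> Percept:
    """Sample a percept of the road from the current vehicle state.

    ``deviation``/``s_proj``/``tangent_heading`` may be supplied by a caller
    that has already projected the pose (the trial runner does); otherwise
    they are computed here.  ``trial_index`` is the 0-based training-trial
    counter driving the audio learning schedule.
    """
    if trial_index < 0:
        raise ValueError("trial_index must be >= 0")
    if deviation is None or s_proj is None or tangent_heading is None:
        deviation, s_proj, tangent_heading, _ = course._project_full(
            state.x, state.y, 0.0 if s_proj is None else s_proj
        )
    s_ahead = min(s_proj + state.speed * params.preview_time, course.total_length)
    far = course.curvature_at(s_ahead) + rng.normal(0.0, params.sigma_far)
    h_err = _wrap_pi(state.heading - tangent_heading) + rng.normal(
        0.0, params.sigma_heading
    )
    near = None
    heard = None
    if condition.near_available:
        near = deviation + rng.normal(0.0, params.sigma_visual)
    if condition.audio_available:
        decoded, _ = audio.decode(audio.encode(deviation, encoder), encoder)
        heard = decoded + rng.normal(0.0, params.sigma_audio(trial_index))
    return Percept(
        far_curvature=far, heading_error=h_err, near_deviation=near,
        audio_deviation=heard,
    )


def steer(
    percept: Percept,
    params: DriverParams,
    prev_sw: float,
    dt: float,
    rng: np.random.Generator,
    vehicle: VehicleParams = VehicleParams(),
) -> float:
    """One-shot steering command from a percept (no delay line, no arm lag).

    The target is the sum of the anticipatory term (the wheel angle whose
    kinematic-bicycle path curvature equals the previewed curvature, scaled
    by ``k_ant``), the compensatory term ``-k_comp * deviation_estimate``,
    and the heading term ``-k_head * heading_error``, plus motor noise.
    :class:`DriverAgent` wraps this law with the reaction-time delay line
    and arm dynamics for closed-loop use.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ff = params.k_ant * vehicle.steering_ratio * math.atan(
        vehicle.wheelbase * percept.far_curvature
    )
    target = (
        ff
        - params.k_comp * percept.deviation_estimate
        - params.k_head * percept.heading_error
    )
    return target + rng.normal(0.0, params.sigma_motor)


@dataclass(frozen=True)
class PopulationSpec:
    """Distribution of one :class:`DriverParams` field across participants:
    mean, jitter SD (normal), and truncation bounds."""

    mean: float
    jitter_sd: float
    lo: float = 0.0
    hi: float = math.inf


def default_population() -> dict[str, PopulationSpec]:
    """Population distributions for the default synthetic cohort.

    Means are the :class:`DriverParams` defaults; jitter SDs are roughly 10%
    of each mean (timing parameters a little tighter), truncated at validity
    bounds.  These values, together with the encoder and protocol defaults,
    define the study conditions the package reproduces.
    """
    base = DriverParams()
    rel = {
        "k_ant": 0.05,
        "k_comp": 0.12,
        "k_head": 0.10,
        "preview_time": 0.10,
        "reaction_delay": 0.10,
        "perceive_interval": 0.0,
        "arm_tau": 0.10,
        "est_tau": 0.10,
        "sigma_visual": 0.15,
        "sigma_far": 0.15,
        "sigma_heading": 0.15,
        "sigma_audio0": 0.15,
        "sigma_audio_min": 0.15,
        "learn_rate": 0.25,
        "sigma_motor": 0.15,
    }
    pop = {}
    for f in fields(base):
        mean = getattr(base, f.name)
        pop[f.name] = PopulationSpec(mean=mean, jitter_sd=rel[f.name] * mean, lo=1e-6)
    return pop


def sample_participant(
    group_seed: int,
    participant_index: int,
    population: dict[str, PopulationSpec] | None = None,
) -> DriverParams:
    """Draw one participant's parameters from the population distributions.

    Deterministic in ``(group_seed, participant_index)``.  Draws are normal
    around each mean with the spec's jitter SD, clipped to the spec's
    bounds; the audio-noise ordering constraint is restored by clipping
    ``sigma_audio_min`` at ``sigma_audio0``.
    """
    if population is None:
        population = default_population()
    rng = np.random.default_rng(
        np.random.SeedSequence([int(group_seed), int(participant_index)])
    )
    values = {}
    for f in fields(DriverParams):
        spec = population[f.name]
        v = rng.normal(spec.mean, spec.jitter_sd) if spec.jitter_sd > 0 else spec.mean
        values[f.name] = float(min(max(v, spec.lo), spec.hi))
    if values["sigma_audio_min"] > values["sigma_audio0"]:
        values["sigma_audio_min"] = values["sigma_audio0"]
    return DriverParams(**values)


class DriverAgent:
    """Closed-loop steering controller wrapping the two-level law.

    Implements the :class:`~lanecue.vehicle.SteeringController` protocol:
    percepts are refreshed every ``perceive_interval`` and held in between,
    commands pass through a ``reaction_delay`` delay line and a first-order
    arm lag, and under SS the ear levels presented at each step are
    reported back for logging.
    """

    def __init__(
        self,
        params: DriverParams,
        condition: Condition,
        trial_index: int = 0,
        vehicle: VehicleParams = VehicleParams(),
        encoder: audio.EncoderParams = audio.EncoderParams(),
        dt: float = 1.0 / 60.0,
    ):
        self.params = params
        self.condition = condition
        self.trial_index = trial_index
        self.vehicle = vehicle
        self.encoder = encoder
        self.dt = dt
        self._rng: np.random.Generator | None = None

    def reset(self, n_steps: int, rng: np.random.Generator) -> None:
        self._rng = rng
        self._percept: Percept | None = None
        self._hold = 0
        self._delay_buf: list[float] = []
        self._arm = 0.0
        # pre-drawn per-step motor noise keeps the stream layout stable
        self._motor_noise = rng.normal(0.0, self.params.sigma_motor, n_steps)
        p = self.params
        self._hold_steps = max(1, round(p.perceive_interval / self.dt))
        self._n_delay = round(p.reaction_delay / self.dt)
        # anticipatory alignment: the previewed curvature refers to the road
        # preview_time ahead, so the feedforward is buffered until the car
        # (net of reaction delay, arm lag and mean percept staleness) gets
        # there -- anticipation means correctly *timed* steering, not early
        # steering
        ff_lead = p.preview_time - p.reaction_delay - p.arm_tau - (
            self._hold_steps * self.dt / 2.0
        )
        self._n_ff = max(0, round(ff_lead / self.dt))
        self._ff_buf: list[float] = []
        self._est = 0.0
        self._beta = (
            1.0 - math.exp(-self.dt / p.est_tau) if p.est_tau > 0 else 1.0
        )
        self._alpha = (
            1.0 - math.exp(-self.dt / p.arm_tau) if p.arm_tau > 0 else 1.0
        )

    def command(
        self,
        i: int,
        t: float,
        state: VehicleState,
        deviation: float,
        s_proj: float,
        tangent_heading: float,
        course: RoadCourse,
    ) -> tuple[float, float, float]:
        p = self.params
        rng = self._rng
        if self._percept is None or self._hold >= self._hold_steps:
            self._percept = perceive(
                state,
                course,
                self.condition,
                self.trial_index,
                p,
                rng,
                encoder=self.encoder,
                deviation=deviation,
                s_proj=s_proj,
                tangent_heading=tangent_heading,
            )
            self._hold = 0
        self._hold += 1
        pc = self._percept
        ff_now = p.k_ant * self.vehicle.steering_ratio * math.atan(
            self.vehicle.wheelbase * pc.far_curvature
        )
        self._ff_buf.append(ff_now)
        ff = self._ff_buf.pop(0) if len(self._ff_buf) > self._n_ff else 0.0
        # slow running average over the noisy position estimate
        self._est += self._beta * (pc.deviation_estimate - self._est)
        target = (
            ff
            - p.k_comp * self._est
            - p.k_head * pc.heading_error
            + self._motor_noise[i]
        )
        # reaction-time dead time: fixed-length command delay line
        # (wheel rests until the first command emerges from the line)
        buf = self._delay_buf
        buf.append(target)
        delayed = buf.pop(0) if len(buf) > self._n_delay else 0.0
        # first-order arm lag
        self._arm += self._alpha * (delayed - self._arm)
        if self.condition.audio_available:
            lev = audio.encode(deviation, self.encoder)
            return self._arm, lev.left, lev.right
        return self._arm, math.nan, math.nan


def _wrap_pi(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi
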