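"""Full-protocol orchestration.

The protocol mirrors the study design: 45 synthetic participants, 15 per
training condition (ND, VO, SS).  Every participant runs 5 pretest trials,
40 training trials and 5 posttest trials of one minute each.  Pretest and
posttest trials always run under ND (full vision, meaningless audio), so
the training condition differs between groups only during the training
session.  Every trial drives a freshly generated random course.

Reproducibility: a single ``master_seed`` deterministically derives every
stream in the run through ``numpy.random.SeedSequence`` keyed on
``(master_seed, group, participant, session, trial)``, so the same config
always produces the same metrics table, and any single trial can be
re-simulated in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anova
from .audio import EncoderParams
from .course import (
    DEFAULT_BEND_LENGTH_RANGE,
    DEFAULT_CURV_RANGE,
    DEFAULT_LANE_WIDTH,
    DEFAULT_STRAIGHT_RANGE,
    generate_course,
)
from .driver import Condition, DriverAgent, default_population, sample_participant
from .metrics import trial_metrics
from .vehicle import VehicleParams, simulate_trial

__all__ = ["SimConfig", "run_experiment", "run_single_trial", "trial_seeds", "GROUPS", "SESSIONS"]

GROUPS = ("ND", "VO", "SS")
#: session name -> (trial-count config key, condition policy)
SESSIONS = ("pretest", "training", "posttest")

METRICS_COLUMNS = (
    "participant",
    "group",
    "session",
    "trial",
    "sdlp",
    "swv",
    "n_curves",
    "off_road",
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a full experiment run.

    Defaults reproduce the study protocol: 1/60 s steps, one-minute trials
    at 80 km/h, 5 + 40 + 5 trials, 15 participants per group, 3.5 m lane,
    bends of |curvature| in [1/180, 1/80] 1/m alternating with 50-150 m
    straights, and the -50 dB / 25 dB-per-m binaural encoder.
    """

    dt: float = 1.0 / 60.0
    trial_duration: float = 60.0
    speed_kmh: float = 80.0
    n_pretest: int = 5
    n_training: int = 40
    n_posttest: int = 5
    n_per_group: int = 15
    master_seed: int = 0
    course_length: float = 1500.0
    lane_width: float = DEFAULT_LANE_WIDTH
    curv_range: tuple[float, float] = DEFAULT_CURV_RANGE
    straight_range: tuple[float, float] = DEFAULT_STRAIGHT_RANGE
    bend_length_range: tuple[float, float] = DEFAULT_BEND_LENGTH_RANGE
    vehicle: VehicleParams = field(default_factory=VehicleParams)
    encoder: EncoderParams = field(default_factory=EncoderParams)
    persist_logs: bool = False
    out_dir: str | None = None

    def __post_init__(self):
        for name in ("dt", "trial_duration", "speed_kmh", "course_length"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_pretest", "n_training", "n_posttest", "n_per_group"):
            if not getattr(self, name) >= 1:
                raise ValueError(f"{name} must be at least 1")

    @property
    def speed_mps(self) -> float:
        return self.speed_kmh / 3.6

    def session_plan(self) -> list[tuple[str, int]]:
        return [
            ("pretest", self.n_pretest),
            ("training", self.n_training),
            ("posttest", self.n_posttest),
        ]

    def to_json(self, **kw) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "vehicle" in d and isinstance(d["vehicle"], dict):
            d["vehicle"] = VehicleParams(**d["vehicle"])
        if "encoder" in d and isinstance(d["encoder"], dict):
            d["encoder"] = EncoderParams(**d["encoder"])
        for key in ("curv_range", "straight_range", "bend_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls.from_dict(json.loads(text))


def trial_seeds(
    master_seed: int, group_idx: int, participant_idx: int, session_idx: int, trial_idx: int
) -> tuple[int, np.random.SeedSequence]:
    """Derive the (course seed, simulation seed sequence) for one trial.

    Pure in its arguments and collision-free across the protocol: the
    SeedSequence key encodes the full trial coordinates.
    """
    ss = np.random.SeedSequence(
        [int(master_seed), group_idx, participant_idx, session_idx, trial_idx]
    )
    course_ss, sim_ss = ss.spawn(2)
    course_seed = int(course_ss.generate_state(1, dtype=np.uint32)[0])
    return course_seed, sim_ss


def _participant_seed(master_seed: int, group_idx: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), 0x5EED, group_idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_single_trial(
    config: SimConfig,
    group: str,
    participant_idx: int,
    session: str,
    trial_idx: int,
    population=None,
):
    """Re-simulate one trial of the protocol in isolation.

    Returns ``(log, course, params)``; the log is bit-identical to the one
    produced inside :func:`run_experiment` for the same coordinates.
    """
    group_idx = GROUPS.index(group)
    session_idx = SESSIONS.index(session)
    params = sample_participant(
        _participant_seed(config.master_seed, group_idx), participant_idx, population
    )
    course_seed, sim_ss = trial_seeds(
        config.master_seed, group_idx, participant_idx, session_idx, trial_idx
    )
    course = generate_course(
        course_seed,
        total_length=config.course_length,
        curv_range=config.curv_range,
        straight_range=config.straight_range,
        bend_length_range=config.bend_length_range,
        lane_width=config.lane_width,
    )
    condition = Condition(group) if session == "training" else Condition.ND
    agent = DriverAgent(
        params,
        condition,
        trial_index=trial_idx if session == "training" else 0,
        vehicle=config.vehicle,
        encoder=config.encoder,
        dt=config.dt,
    )
    log = simulate_trial(
        course,
        agent,
        duration=config.trial_duration,
        dt=config.dt,
        params=config.vehicle,
        seed=sim_ss,
        speed=config.speed_mps,
    )
    return log, course, params


def run_experiment(
    config: SimConfig = SimConfig(),
    population=None,
    analyze: bool = True,
    progress: bool = False,
) -> tuple[pd.DataFrame, dict | None]:
    """Run the full protocol and (optionally) its statistical analysis.

    Returns ``(metrics, report)``: a per-trial metrics table with
    ``n_per_group * 3 * (n_pretest + n_training + n_posttest)`` rows, and
    the :func:`lanecue.anova.analyze_experiment` report (None when
    ``analyze`` is False).  If ``config.out_dir`` is set, writes
    ``metrics.csv``, ``results.json`` and ``config.json`` there (plus
    per-trial logs under ``logs/`` when ``persist_logs``).
    """
    if population is None:
        population = default_population()
    rows = []
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(config.to_json(indent=2))
        if config.persist_logs:
            (out_dir / "logs").mkdir(exist_ok=True)
    for group_idx, group in enumerate(GROUPS):
        pseed = _participant_seed(config.master_seed, group_idx)
        for pi in range(config.n_per_group):
            params = sample_participant(pseed, pi, population)
            pid = f"{group}-{pi:02d}"
            for session_idx, (session, n_trials) in enumerate(config.session_plan()):
                condition = Condition(group) if session == "training" else Condition.ND
                for ti in range(n_trials):
                    course_seed, sim_ss = trial_seeds(
                        config.master_seed, group_idx, pi, session_idx, ti
                    )
                    course = generate_course(
                        course_seed,
                        total_length=config.course_length,
                        curv_range=config.curv_range,
                        straight_range=config.straight_range,
                        bend_length_range=config.bend_length_range,
                        lane_width=config.lane_width,
                    )
                    agent = DriverAgent(
                        params,
                        condition,
                        trial_index=ti if session == "training" else 0,
                        vehicle=config.vehicle,
                        encoder=config.encoder,
                        dt=config.dt,
                    )
                    log = simulate_trial(
                        course,
                        agent,
                        duration=config.trial_duration,
                        dt=config.dt,
                        params=config.vehicle,
                        seed=sim_ss,
                        speed=config.speed_mps,
                    )
                    m = trial_metrics(log, course)
                    rows.append(
                        (pid, group, session, ti + 1, m.sdlp, m.swv, m.n_curves, m.off_road)
                    )
                    if out_dir and config.persist_logs:
                        log.to_csv(out_dir / "logs" / f"{pid}_{session}_{ti + 1:02d}.csv")
            if progress:
                print(f"[lanecue] {pid}: {sum(n for _, n in config.session_plan())} trials done")
    metrics = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    report = anova.analyze_experiment(metrics) if analyze else None
    if out_dir:
        metrics.to_csv(out_dir / "metrics.csv", index=False)
        if report is not None:
            anova.save_report(report, out_dir / "results.json")
            (out_dir / "summary.txt").write_text(anova.summarize_report(report))
    return metrics, report
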