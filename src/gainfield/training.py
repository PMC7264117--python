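"""Training schedule generation and the training loop.

Training exposes the network to randomized combinations of eye position and
retinal stimulus location.  An epoch visits every retinal location once; a
"period" clamps the stimulus at one retinal location while the eyes make a
sequence of fixations (300 ms each by default) at uniform random integer
positions in [-35, 35] degrees, joined by constant-velocity saccades
(400 deg/s).  With the defaults each period holds 15 fixations and 14
saccades, and training runs for 10 epochs.

The stated presentation time is 2 s per retinal location, which with 21
locations and 10 epochs gives the nominal total of 420 s of simulated time;
15 x 300 ms of fixation alone already exceeds 2 s, so the two stated
timings cannot both hold.  Both readings are available: the default
``fixation_defined`` mode keeps the 300 ms fixations (about 5.3 s per
period); ``nominal_2s`` rescales fixation durations so each period lasts
2 s.  ``nominal_training_duration`` always reports the nominal arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .selforg import (
    InputLayer,
    Network,
    competitive_rates,
    hebbian_update,
    input_rates,
    step_dynamics,
)

__all__ = [
    "ScheduleEvent",
    "TrainingConfig",
    "TrainingSchedule",
    "TrainingLog",
    "make_schedule",
    "nominal_training_duration",
    "schedule_steps",
    "run_training",
    "schedule_to_frame",
]


@dataclass(frozen=True)
class ScheduleEvent:
    """One fixation or saccade, with the stimulus clamped for its period."""

    kind: str  # "fixation" | "saccade"
    start: float  # seconds
    end: float
    retinal_x: float  # degrees, constant over the whole period
    eye_start: float
    eye_end: float
    epoch: int
    period: int
    transition: bool = False  # un-counted saccade entering a period

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 10
    retinal_range: tuple = (-10.0, 10.0)
    retinal_step: float = 1.0
    eye_range: tuple = (-35.0, 35.0)
    fixations_per_period: int = 15
    fixation_duration: float = 0.3  # seconds
    saccade_speed: float = 400.0  # degrees per second
    presentation_seconds: float = 2.0  # nominal time per retinal location
    schedule_mode: str = "fixation_defined"  # or "nominal_2s"
    shuffle_periods: bool = False

    def retinal_locations(self) -> np.ndarray:
        lo, hi = self.retinal_range
        n = int(round((hi - lo) / self.retinal_step))
        return lo + self.retinal_step * np.arange(n + 1)


@dataclass
class TrainingSchedule:
    events: list
    config: TrainingConfig
    seed: int

    def __len__(self) -> int:
        return len(self.events)

    @property
    def duration(self) -> float:
        return self.events[-1].end if self.events else 0.0


def nominal_training_duration(config: TrainingConfig = TrainingConfig()) -> float:
    """Nominal simulated time: locations x presentation seconds x epochs.

    This is the schedule's headline arithmetic (21 x 2 s x 10 = 420 s under
    the defaults) and is reported regardless of ``schedule_mode``.
    """
    return (
        len(config.retinal_locations())
        * config.presentation_seconds
        * config.epochs
    )


def make_schedule(seed, config: TrainingConfig = TrainingConfig()) -> TrainingSchedule:
    """Generate the randomized fixation/saccade event sequence.

    For every epoch and every retinal location (sequential order by default,
    shuffled per epoch if ``shuffle_periods``) the eyes visit
    ``fixations_per_period`` uniform random integer positions inside
    ``eye_range``, joined by constant-velocity saccades.  Each period is
    entered through an un-counted transition saccade from the previous eye
    position, so the fixation/saccade accounting within a period stays
    15/14.  Reproducible from ``seed``; the fixation-target stream is the
    third sub-stream of the global seed (matching ``init_network``'s
    expansion, so one global seed drives both independently).
    """
    if config.fixations_per_period < 1:
        raise ValueError("fixations_per_period must be >= 1")
    if config.saccade_speed <= 0:
        raise ValueError("saccade_speed must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(3)[2])
    lo, hi = config.eye_range

    fix_dur = config.fixation_duration
    events: list = []
    t = 0.0
    eye = 0.0
    period_counter = 0
    for epoch in range(config.epochs):
        locations = config.retinal_locations()
        if config.shuffle_periods:
            locations = rng.permutation(locations)
        for x in locations:
            targets = rng.integers(int(lo), int(hi) + 1,
                                   size=config.fixations_per_period).astype(float)
            if config.schedule_mode == "nominal_2s":
                sacc_time = (
                    abs(targets[0] - eye) + np.abs(np.diff(targets)).sum()
                ) / config.saccade_speed
                remaining = config.presentation_seconds - sacc_time
                if remaining <= 0:
                    raise ValueError(
                        "saccade time exceeds the nominal presentation window"
                    )
                fix_dur = remaining / config.fixations_per_period
            elif config.schedule_mode != "fixation_defined":
                raise ValueError(f"unknown schedule_mode {config.schedule_mode!r}")
            for i, target in enumerate(targets):
                if target != eye:
                    d = abs(target - eye) / config.saccade_speed
                    events.append(ScheduleEvent(
                        "saccade", t, t + d, float(x), eye, float(target),
                        epoch, period_counter, transition=(i == 0),
                    ))
                    t += d
                elif i > 0:
                    # zero-amplitude saccade between identical targets keeps
                    # the alternating structure; contributes no time
                    events.append(ScheduleEvent(
                        "saccade", t, t, float(x), eye, eye,
                        epoch, period_counter,
                    ))
                eye = float(target)
                events.append(ScheduleEvent(
                    "fixation", t, t + fix_dur, float(x), eye, eye,
                    epoch, period_counter,
                ))
                t += fix_dur
            period_counter += 1
    return TrainingSchedule(events=events, config=config,
                            seed=None if isinstance(seed, np.random.SeedSequence)
                            else int(seed))


def schedule_steps(schedule: TrainingSchedule, dt: float):
    """Discretize the schedule into per-step (x, y, event-index) arrays.

    Fixations contribute ``round(duration/dt)`` steps; saccade durations are
    rounded *up* to whole steps with the eye interpolating linearly so the
    endpoint is reached exactly.  Returns (xs, ys, event_idx) arrays.
    """
    xs, ys, idx = [], [], []
    for k, ev in enumerate(schedule.events):
        if ev.kind == "fixation":
            n = int(round(ev.duration / dt))
            if n:
                xs.append(np.full(n, ev.retinal_x))
                ys.append(np.full(n, ev.eye_start))
                idx.append(np.full(n, k))
        else:
            n = int(np.ceil(ev.duration / dt - 1e-12))
            if n:
                frac = np.arange(1, n + 1) / n
                xs.append(np.full(n, ev.retinal_x))
                ys.append(ev.eye_start + frac * (ev.eye_end - ev.eye_start))
                idx.append(np.full(n, k))
    if not xs:
        raise ValueError("schedule discretizes to zero steps")
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(idx)


@dataclass
class TrainingLog:
    """Per-period training diagnostics."""

    frame: pd.DataFrame  # epoch, period, retinal_x, mean_sparseness, mean_abs_dw

    def per_epoch(self) -> pd.DataFrame:
        return (
            self.frame.groupby("epoch")[["mean_sparseness", "mean_abs_dw"]]
            .mean()
            .reset_index()
        )


def run_training(
    net: Network,
    layer: InputLayer,
    schedule: TrainingSchedule,
    *,
    learn_during_saccades: bool = True,
) -> tuple:
    """Drive the network through a schedule, learning as it goes.

    At each Euler step: input rates for the current (stimulus, eye)
    condition -> integrator step -> competitive output rates -> Hebbian
    update with renormalization.  During saccades the eye position
    interpolates linearly; learning stays on unless
    ``learn_during_saccades`` is False.  The network is modified in place;
    returns ``(net, TrainingLog)`` with per-period mean output sparseness
    (fraction of outputs above rate 0.5) and mean per-synapse weight change.
    """
    if not schedule.events:
        raise ValueError("schedule is empty")
    xs, ys, idx = schedule_steps(schedule, net.dt)
    kinds = np.array([ev.kind for ev in schedule.events])
    periods = np.array([ev.period for ev in schedule.events])
    epochs = np.array([ev.epoch for ev in schedule.events])
    retx = np.array([ev.retinal_x for ev in schedule.events])

    n_syn = int(net.mask.sum())
    rows = []
    sparse_acc = dw_acc = 0.0
    steps_in_period = 0
    current_period = periods[idx[0]]

    def flush(period):
        ev_sel = periods == period
        rows.append((
            int(epochs[ev_sel][0]), int(period), float(retx[ev_sel][0]),
            sparse_acc / max(steps_in_period, 1),
            dw_acc / max(steps_in_period, 1),
        ))

    for step, (x, y, k) in enumerate(zip(xs, ys, idx)):
        if periods[k] != current_period:
            flush(current_period)
            current_period = periods[k]
            sparse_acc = dw_acc = 0.0
            steps_in_period = 0
        v_in = input_rates(layer, x, y)
        step_dynamics(net, v_in)
        v_out = competitive_rates(net)
        if learn_during_saccades or kinds[k] == "fixation":
            w_before = net.weights
            hebbian_update(net, v_in, v_out)
            dw_acc += float(np.abs(net.weights - w_before).sum()) / n_syn
        sparse_acc += float(np.mean(v_out > 0.5))
        steps_in_period += 1
        if not np.all(np.isfinite(net.weights)):
            ev = schedule.events[k]
            raise FloatingPointError(
                f"non-finite weights at t~{step * net.dt:.3f}s during {ev}"
            )
    flush(current_period)
    log = TrainingLog(frame=pd.DataFrame(
        rows, columns=["epoch", "period", "retinal_x",
                       "mean_sparseness", "mean_abs_dw"]
    ))
    return net, log


def schedule_to_frame(schedule: TrainingSchedule) -> pd.DataFrame:
    """Event table as a tidy frame (exportable as CSV)."""
    return pd.DataFrame(
        [
            {
                "kind": ev.kind,
                "start": ev.start,
                "end": ev.end,
                "retinal_x": ev.retinal_x,
                "eye_start": ev.eye_start,
                "eye_end": ev.eye_end,
                "epoch": ev.epoch,
                "period": ev.period,
                "transition": ev.transition,
            }
            for ev in schedule.events
        ]
    )
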