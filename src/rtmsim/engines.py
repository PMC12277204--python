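"""Firmware twin of the remind-to-move (RTM) wrist-worn cueing device.

Two device variants are modelled on a shared 2-s epoch clock (the device's
sensing granularity):

* **open-loop** — a vibration cue fires on a fixed schedule (every
  ``open_interval`` minutes, default 10) regardless of arm movement;
* **closed-loop** — an inactivity countdown (2 min for lower-functioning
  users, 5 min for higher-functioning users) arms at session start and
  whenever no movement is detected; any detected movement of the hemiparetic
  arm reloads the countdown, so a cue fires only after a continuous
  no-movement interval.

In both variants the cue is a 2-s on / 2-s off vibration pattern that
repeats until the wearer presses the acknowledge button; the press latency
is the logged reaction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

EPOCH_S = 2.0  # device epoch length, seconds


class Mode(str, Enum):
    OPEN_LOOP = "open_loop"
    CLOSED_LOOP = "closed_loop"


class ConfigurationError(ValueError):
    """Raised for invalid engine configurations."""


@dataclass(frozen=True)
class EngineConfig:
    """Parameters of one cueing engine.

    Parameters
    ----------
    mode
        ``open_loop`` (fixed schedule) or ``closed_loop`` (inactivity
        countdown).
    open_interval_min
        Open-loop cue period, minutes. Ignored by the closed-loop engine.
    countdown_min
        Closed-loop inactivity countdown, minutes (2 for lower functioning,
        5 for higher functioning). Ignored by the open-loop engine.
    vibration_on_s, vibration_off_s
        The cue's on/off vibration pattern, seconds. Metadata plus logging;
        the pattern has no feedback effect beyond the awaiting-ack state.
    vibration_freq_hz
        Motor vibration frequency. Metadata only, never simulated.
    tick_s
        Engine tick, seconds. The engine advances on the accelerometer's
        2-s epoch grid; all durations are rounded to whole ticks.
    open_loop_anchor
        ``"fixed"`` (default): the open-loop timer runs on a fixed grid from
        session start and is not re-anchored by acknowledgment. ``"ack"``:
        alternative dialect in which the interval restarts at acknowledgment.
    """

    mode: Mode
    open_interval_min: float = 10.0
    countdown_min: float = 2.0
    vibration_on_s: float = 2.0
    vibration_off_s: float = 2.0
    vibration_freq_hz: float = 196.0
    tick_s: float = EPOCH_S
    open_loop_anchor: str = "fixed"

    def __post_init__(self) -> None:
        if isinstance(self.mode, str) and not isinstance(self.mode, Mode):
            object.__setattr__(self, "mode", Mode(self.mode))
        if self.tick_s <= 0:
            raise ConfigurationError("tick_s must be positive")
        if self.open_interval_min <= 0:
            raise ConfigurationError("open_interval_min must be positive")
        if self.countdown_min <= 0:
            raise ConfigurationError("countdown_min must be positive")
        if self.countdown_min > self.open_interval_min:
            raise ConfigurationError(
                "closed-loop countdown presets are by design no longer than "
                "the open-loop interval"
            )
        if self.vibration_on_s <= 0 or self.vibration_off_s < 0:
            raise ConfigurationError("invalid vibration pattern durations")
        if self.open_loop_anchor not in ("fixed", "ack"):
            raise ConfigurationError("open_loop_anchor must be 'fixed' or 'ack'")

    def _whole_ticks(self, seconds: float) -> float:
        return max(1.0, round(seconds / self.tick_s)) * self.tick_s

    @property
    def open_interval_s(self) -> float:
        """Open-loop period in seconds, rounded to whole ticks."""
        return self._whole_ticks(self.open_interval_min * 60.0)

    @property
    def countdown_s(self) -> float:
        """Closed-loop countdown in seconds, rounded to whole ticks."""
        return self._whole_ticks(self.countdown_min * 60.0)

    @property
    def reload_s(self) -> float:
        """The timer reload value active for this mode."""
        return (
            self.open_interval_s if self.mode is Mode.OPEN_LOOP else self.countdown_s
        )


@dataclass(frozen=True)
class EngineState:
    """Evolving state of a cueing engine.

    ``timer_remaining_s`` counts down to the next scheduled cue;
    ``cue_active``/``awaiting_ack`` flag a running vibration pattern that has
    not yet been acknowledged (the two are always equal in this firmware:
    the pattern runs exactly while an acknowledgment is pending).
    """

    clock_s: float = 0.0
    timer_remaining_s: float = 0.0
    cue_active: bool = False
    awaiting_ack: bool = False
    cue_onset_s: float | None = None


@dataclass(frozen=True)
class StepResult:
    """What one engine tick emitted."""

    cue_fired: bool = False
    cue_onset_s: float | None = None
    cue_acknowledged: bool = False
    ack_clock_s: float | None = None


@dataclass(frozen=True)
class CueEvent:
    """One logged cue: onset, acknowledgment time (absent if never pressed)."""

    onset_s: float
    ack_s: float | None = None

    def __post_init__(self) -> None:
        if self.ack_s is not None and self.ack_s < self.onset_s:
            raise ValueError("ack_s must not precede onset_s")

    @property
    def reaction_s(self) -> float | None:
        """Button-press latency, or None for a never-acknowledged cue."""
        return None if self.ack_s is None else self.ack_s - self.onset_s


NEVER = math.inf  # acknowledgment delay meaning "button never pressed"


@dataclass(frozen=True)
class SessionTrace:
    """Inputs the engine consumes during one wearing session.

    ``movement_flags`` holds one boolean per 2-s epoch (movement detected on
    the hemiparetic arm in that epoch).  ``ack_policy`` maps a cue to its
    acknowledgment delay in seconds: a single float applies to every cue, a
    mapping is keyed by cue onset (missing onsets are never acknowledged),
    and ``math.inf`` (:data:`NEVER`) means the button is never pressed.
    """

    movement_flags: Sequence[bool]
    ack_policy: float | Mapping[float, float] = 0.0
    tick_s: float = EPOCH_S

    def __post_init__(self) -> None:
        if isinstance(self.ack_policy, (int, float)):
            if self.ack_policy < 0:
                raise ValueError("acknowledgment delay must be nonnegative")
        else:
            if any(d < 0 for d in self.ack_policy.values()):
                raise ValueError("acknowledgment delays must be nonnegative")

    @property
    def duration_s(self) -> float:
        return len(self.movement_flags) * self.tick_s

    def ack_delay(self, onset_s: float) -> float:
        """Delay before the acknowledge button is pressed for this cue."""
        if isinstance(self.ack_policy, (int, float)):
            return float(self.ack_policy)
        return float(self.ack_policy.get(onset_s, NEVER))


def init_engine(config: EngineConfig) -> EngineState:
    """Arm a fresh engine at session start (clock zero).

    Session start counts as the start of a no-movement interval, so the
    closed-loop countdown is armed immediately.
    """
    return EngineState(clock_s=0.0, timer_remaining_s=config.reload_s)


def acknowledge(state: EngineState, config: EngineConfig) -> EngineState:
    """Clear an active cue after a button press.

    The closed-loop countdown restarts from the full preset at
    acknowledgment (it is suspended while a cue awaits acknowledgment); in
    the ``"ack"`` open-loop dialect the interval restarts too.
    """
    timer = state.timer_remaining_s
    if config.mode is Mode.CLOSED_LOOP or config.open_loop_anchor == "ack":
        timer = config.reload_s
    return replace(
        state,
        timer_remaining_s=timer,
        cue_active=False,
        awaiting_ack=False,
        cue_onset_s=None,
    )


def step(
    state: EngineState,
    config: EngineConfig,
    moved_this_epoch: bool,
    ack_pressed: bool = False,
) -> tuple[EngineState, StepResult]:
    """Advance the engine one tick (one 2-s epoch).

    Open loop: the timer decrements unconditionally; at zero a cue fires and
    the timer reloads. Closed loop: detected movement reloads the countdown,
    otherwise it decrements; at zero a cue fires. While a cue awaits
    acknowledgment the vibration pattern repeats; only the button press
    (``ack_pressed``) stops it — movement does not auto-acknowledge, and the
    closed-loop countdown is suspended until acknowledgment.
    """
    tick = config.tick_s
    clock = state.clock_s + tick
    timer = state.timer_remaining_s
    awaiting = state.awaiting_ack
    onset = state.cue_onset_s

    fired = False
    fired_onset: float | None = None
    if not awaiting:
        if config.mode is Mode.OPEN_LOOP:
            timer -= tick
        elif moved_this_epoch:
            timer = config.countdown_s
        else:
            timer -= tick
        if timer <= 1e-9:
            fired = True
            fired_onset = clock
            awaiting = True
            onset = clock
            timer = config.reload_s
    elif config.mode is Mode.OPEN_LOOP and config.open_loop_anchor == "fixed":
        # fixed-grid dialect: the schedule keeps running under an active cue;
        # a cue scheduled while one is already vibrating is absorbed into it
        timer -= tick
        if timer <= 1e-9:
            timer = config.open_interval_s

    new_state = EngineState(
        clock_s=clock,
        timer_remaining_s=timer,
        cue_active=awaiting,
        awaiting_ack=awaiting,
        cue_onset_s=onset,
    )

    acked = False
    ack_clock: float | None = None
    if awaiting and ack_pressed:
        acked = True
        ack_clock = clock
        new_state = acknowledge(new_state, config)

    return new_state, StepResult(
        cue_fired=fired,
        cue_onset_s=fired_onset,
        cue_acknowledged=acked,
        ack_clock_s=ack_clock,
    )


def run_session(config: EngineConfig, trace: SessionTrace) -> list[CueEvent]:
    """Replay a full session deterministically and return all cue events.

    Acknowledgments are processed on the tick grid: a press scheduled at
    ``onset + delay`` takes effect at the first tick boundary reaching that
    time (a zero delay is processed within the firing tick), and the logged
    ``ack_s`` is the scheduled press time itself.
    """
    if trace.tick_s != config.tick_s:
        raise ConfigurationError("trace and engine tick lengths differ")
    state = init_engine(config)
    events: list[CueEvent] = []
    pending_ack: float | None = None  # scheduled press time of the open cue

    for moved in trace.movement_flags:
        ack_now = (
            pending_ack is not None
            and state.clock_s + config.tick_s >= pending_ack - 1e-9
        )
        state, out = step(state, config, bool(moved), ack_pressed=ack_now)
        if out.cue_acknowledged:
            events[-1] = replace(events[-1], ack_s=pending_ack)
            pending_ack = None
        if out.cue_fired:
            assert out.cue_onset_s is not None
            events.append(CueEvent(onset_s=out.cue_onset_s))
            delay = trace.ack_delay(out.cue_onset_s)
            if delay <= 0.0:
                state = acknowledge(state, config)
                events[-1] = replace(events[-1], ack_s=out.cue_onset_s)
            elif math.isfinite(delay):
                pending_ack = out.cue_onset_s + delay
            else:
                pending_ack = None  # never pressed
    return events


@dataclass(frozen=True)
class CueSummary:
    """Cue count and mean reaction time over acknowledged cues."""

    n_cues: int
    mean_reaction_s: float | None


def cue_counts_and_latencies(events: Sequence[CueEvent]) -> CueSummary:
    """Summarise a cue log: number of onsets and mean reaction time.

    The mean is taken over acknowledged cues only; it is None when no cue
    was acknowledged (including the empty log).
    """
    reactions = [e.reaction_s for e in events if e.reaction_s is not None]
    mean = float(sum(reactions) / len(reactions)) if reactions else None
    return CueSummary(n_cues=len(events), mean_reaction_s=mean)
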