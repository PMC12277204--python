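"""Synthetic hemiparetic-participant generator.

Produces 5 Hz tri-axial wrist-acceleration traces and cue-response behavior
with the statistical structure of post-stroke daily arm use:

* the affected arm rests (no detected movement) for about half of waking
  time;
* affected/unaffected activity-count ratios of about 1/3 for
  lower-functioning users (FTHUE 3-4) and 2/3 for higher-functioning users
  (FTHUE >= 5);
* each vibration cue prompts, with probability ``p_respond``, an exercise
  block of five task sets repeated five times (25 movement bouts);
* spontaneous arm use decays over the two-week intervention as early
  motivation fades, while closed-loop exposure builds a movement habit
  (avoidance conditioning) that counteracts the decay.

Movement micro-structure is a two-state (rest/active) Markov chain on the
2-s epoch grid — the discretization of an alternating-renewal bout process —
whose stationary rest probability is exactly the profile's
``rest_fraction``. Walking/gait epochs are never generated: the device's
outcome definition excludes walking activity by construction here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from . import engines
from .accelerometry import (
    DIFFS_PER_EPOCH,
    EPOCH_S,
    SAMPLES_PER_EPOCH,
    MovementThreshold,
)
from .engines import CueEvent, EngineConfig, Mode, SessionTrace


@dataclass(frozen=True)
class AgentProfile:
    """Behavioral parameters of one synthetic participant.

    Parameters
    ----------
    fthue_level
        Functional Test for the Hemiplegic Upper Extremity level (>= 3).
        Levels 3-4 are the lower-functioning stratum, >= 5 the higher one.
    rest_fraction
        Stationary probability that a 2-s epoch carries no spontaneous
        movement intent (default 0.5 of waking time).
    affected_ratio
        Expected affected/unaffected activity-count ratio. ``None`` selects
        the stratum default: 1/3 (lower) or 2/3 (higher functioning).
    p_respond
        Probability that a cue triggers the prescribed exercise block.
    sets_per_cue, reps_per_set
        The exercise dose per cue: five sets of tasks, five repetitions each.
    motivation_halflife_days
        Half-life of the early-period motivation decay applied to the
        spontaneous bout rate: rate x 2^(-(day-1)/halflife).
    habit_gain
        Per-day multiplicative increase of the spontaneous bout rate,
        (1+habit_gain)^(day-1), applied only under closed-loop exposure
        (the avoidance-conditioning habit).
    bout_mean_s
        Mean duration of a spontaneous movement bout, seconds.
    unaffected_intensity
        Probability that any one within-epoch sample difference of the
        unaffected arm crosses the counting threshold while moving; the
        affected arm moves at ``affected_ratio`` times this intensity.
    exercise_intensity
        Crossing probability during prescribed exercise repetitions
        (deliberate task movements, same for both strata).
    exercise_rep_epochs, exercise_gap_epochs
        Epochs of movement per repetition and of pause between repetitions.
    ack_delay_median_s, ack_delay_sigma
        Lognormal acknowledge-button latency (median in seconds, log-scale
        sigma). A median of 0 means the button is pressed instantly.
    """

    fthue_level: int = 3
    rest_fraction: float = 0.5
    affected_ratio: float | None = None
    p_respond: float = 0.8
    sets_per_cue: int = 5
    reps_per_set: int = 5
    motivation_halflife_days: float = 7.0
    habit_gain: float = 0.03
    bout_mean_s: float = 60.0
    unaffected_intensity: float = 0.6
    exercise_intensity: float = 0.9
    exercise_rep_epochs: int = 2
    exercise_gap_epochs: int = 1
    ack_delay_median_s: float = 2.0
    ack_delay_sigma: float = 0.5
    threshold: MovementThreshold = field(default_factory=MovementThreshold)

    def __post_init__(self) -> None:
        if self.fthue_level < 3:
            raise ValueError("fthue_level must be >= 3")
        if not 0.0 <= self.rest_fraction <= 1.0:
            raise ValueError("rest_fraction must be in [0, 1]")
        if not 0.0 <= self.p_respond <= 1.0:
            raise ValueError("p_respond must be in [0, 1]")
        ratio = self.affected_ratio
        if ratio is not None and not 0.0 < ratio <= 1.0:
            raise ValueError("affected_ratio must be in (0, 1]")
        if self.habit_gain < 0:
            raise ValueError("habit_gain must be >= 0")
        if self.bout_mean_s <= 0:
            raise ValueError("bout_mean_s must be positive")
        for p in (self.unaffected_intensity, self.exercise_intensity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("intensities are probabilities in [0, 1]")
        if self.ack_delay_median_s < 0:
            raise ValueError("ack_delay_median_s must be >= 0")

    @property
    def functioning(self) -> Literal["lower", "higher"]:
        return "lower" if self.fthue_level <= 4 else "higher"

    @property
    def ratio(self) -> float:
        """Resolved affected/unaffected ratio (stratum default if unset)."""
        if self.affected_ratio is not None:
            return self.affected_ratio
        return 1.0 / 3.0 if self.functioning == "lower" else 2.0 / 3.0

    @property
    def affected_intensity(self) -> float:
        return self.ratio * self.unaffected_intensity


@dataclass
class DaySimulation:
    """One co-simulated wearing day."""

    day: int
    epochs: pd.DataFrame
    trace: SessionTrace
    cue_events: list[CueEvent]
    samples: pd.DataFrame | None = None


def _markov_rates(profile: AgentProfile, rate_multiplier: float) -> tuple[float, float]:
    """Per-epoch (enter-active, exit-active) transition probabilities.

    The base enter rate is chosen so the stationary rest probability equals
    ``rest_fraction``; day-level motivation/habit factors multiply the enter
    rate (the spontaneous bout rate).
    """
    p_exit = min(1.0, EPOCH_S / profile.bout_mean_s)
    rho = profile.rest_fraction
    if rho >= 1.0:
        p_enter = 0.0
    elif rho <= 0.0:
        p_enter, p_exit = 1.0, 0.0
    else:
        p_enter = p_exit * (1.0 - rho) / rho
    return min(1.0, p_enter * rate_multiplier), p_exit


def day_rate_multiplier(
    profile: AgentProfile, day: int, closed_loop: bool
) -> float:
    """Motivation-decay x habit factor for the spontaneous bout rate."""
    decay = math.exp(-(day - 1) * math.log(2.0) / profile.motivation_halflife_days)
    habit = (1.0 + profile.habit_gain) ** (day - 1) if closed_loop else 1.0
    return decay * habit


def _exercise_pattern(profile: AgentProfile) -> list[bool]:
    """Epoch intents of one exercise block: sets x reps movement bouts."""
    rep = [True] * profile.exercise_rep_epochs + [False] * profile.exercise_gap_epochs
    return rep * (profile.sets_per_cue * profile.reps_per_set)


def _simulate(
    profile: AgentProfile,
    day: int,
    engine: EngineConfig | None,
    rng: np.random.Generator,
    session_hours: float,
    intensity: float,
    rate_multiplier: float,
    synthesize: bool,
) -> DaySimulation:
    n_epochs = int(round(session_hours * 3600.0 / EPOCH_S))
    p_enter, p_exit = _markov_rates(profile, rate_multiplier)

    u_state = rng.random(n_epochs)
    u_cross = rng.random((n_epochs, DIFFS_PER_EPOCH, 3))
    cross_spont = u_cross < intensity
    cross_ex = u_cross < profile.exercise_intensity
    moved_spont = cross_spont.any(axis=(1, 2))
    moved_ex = cross_ex.any(axis=(1, 2))

    # stationary start state of the rest/active chain
    pi_active = p_enter / (p_enter + p_exit) if (p_enter + p_exit) > 0 else 0.0
    active = bool(rng.random() < pi_active)

    pattern = _exercise_pattern(profile)
    exercise_queue: list[bool] = []
    instant_ack = profile.ack_delay_median_s == 0.0
    mu = math.log(profile.ack_delay_median_s) if not instant_ack else 0.0

    state = engines.init_engine(engine) if engine is not None else None
    events: list[CueEvent] = []
    ack_policy: dict[float, float] = {}
    pending_ack: float | None = None

    moved = np.zeros(n_epochs, dtype=bool)
    # 0 = rest intent, 1 = spontaneous movement, 2 = exercise repetition
    intent = np.zeros(n_epochs, dtype=np.int8)

    for i in range(n_epochs):
        if exercise_queue:
            ex = exercise_queue.pop(0)
            intent[i] = 2 if ex else 0
            moved_i = moved_ex[i] if ex else False
        else:
            if active:
                active = u_state[i] >= p_exit
            else:
                active = u_state[i] < p_enter
            intent[i] = 1 if active else 0
            moved_i = moved_spont[i] if active else False
        moved[i] = moved_i

        if state is None or engine is None:
            continue
        ack_now = (
            pending_ack is not None
            and state.clock_s + engine.tick_s >= pending_ack - 1e-9
        )
        state, out = engines.step(state, engine, bool(moved_i), ack_pressed=ack_now)
        if out.cue_acknowledged:
            events[-1] = replace(events[-1], ack_s=pending_ack)
            pending_ack = None
        if out.cue_fired:
            onset = out.cue_onset_s
            assert onset is not None
            delay = (
                0.0
                if instant_ack
                else float(np.exp(mu + profile.ack_delay_sigma * rng.standard_normal()))
            )
            ack_policy[onset] = delay
            events.append(CueEvent(onset_s=onset))
            if delay <= 0.0:
                state = engines.acknowledge(state, engine)
                events[-1] = replace(events[-1], ack_s=onset)
            else:
                pending_ack = onset + delay
            if not exercise_queue and rng.random() < profile.p_respond:
                exercise_queue = list(pattern)

    crossings = np.zeros_like(cross_spont)
    crossings[intent == 1] = cross_spont[intent == 1]
    crossings[intent == 2] = cross_ex[intent == 2]
    # a "moved" intent epoch can still log zero counts if no difference
    # crosses threshold; the device flag follows the counts
    counts = crossings.sum(axis=1)
    counts_mag = crossings.any(axis=2).sum(axis=1)
    epochs = pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "counts_x": counts[:, 0],
            "counts_y": counts[:, 1],
            "counts_z": counts[:, 2],
            "counts_mag": counts_mag,
            "moved": moved,
        }
    )
    trace = SessionTrace(
        movement_flags=tuple(bool(m) for m in moved), ack_policy=ack_policy
    )
    samples = (
        synthesize_samples(crossings, profile.threshold) if synthesize else None
    )
    return DaySimulation(
        day=day, epochs=epochs, trace=trace, cue_events=events, samples=samples
    )


def generate_day(
    profile: AgentProfile,
    day: int,
    engine: EngineConfig | None,
    seed: int | np.random.Generator,
    session_hours: float = 3.0,
    synthesize_samples: bool = True,
) -> DaySimulation:
    """Co-simulate one 3-hr wearing day of the affected arm.

    The agent and the cueing engine run in lockstep on the 2-s epoch grid:
    the engine sees the agent's detected-movement flag each epoch, and every
    cue it fires is acknowledged after a lognormal button latency and, with
    probability ``p_respond``, answered with the 25-repetition exercise
    block. ``engine=None`` simulates free-living behavior with no device
    feedback (used for calibration).

    Replaying the returned ``trace`` through
    :func:`rtmsim.engines.run_session` reproduces ``cue_events`` exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    closed = engine is not None and engine.mode is Mode.CLOSED_LOOP
    return _simulate(
        profile,
        day,
        engine,
        rng,
        session_hours,
        intensity=profile.affected_intensity,
        rate_multiplier=day_rate_multiplier(profile, day, closed),
        synthesize=synthesize_samples,
    )


def generate_unaffected_reference(
    profile: AgentProfile,
    day: int,
    seed: int | np.random.Generator,
    session_hours: float = 3.0,
    synthesize_samples: bool = True,
) -> DaySimulation:
    """Simulate the unaffected arm as the activity-count reference.

    Same rest/active structure as the affected arm but at full movement
    intensity, with no cueing device, motivation decay or habit dynamics:
    its expected counts anchor the affected/unaffected ratio calibration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _simulate(
        profile,
        day,
        None,
        rng,
        session_hours,
        intensity=profile.unaffected_intensity,
        rate_multiplier=1.0,
        synthesize=synthesize_samples,
    )


def synthesize_samples(
    crossings: np.ndarray, threshold: MovementThreshold = MovementThreshold()
) -> pd.DataFrame:
    """Render a crossing mask into a 5 Hz tri-axial sample stream.

    ``crossings`` has shape (n_epochs, 9, 3): which within-epoch sample
    differences exceed threshold on which axis. Each crossing is rendered as
    a +/-(2 x threshold) step with alternating sign (the path stays bounded);
    non-crossing differences are zero. Epoch-izing the result recovers the
    mask's per-axis counts exactly.
    """
    n_epochs = crossings.shape[0]
    amp = 2.0 * np.array([threshold.x, threshold.y, threshold.z])
    # alternate step signs within each epoch: +A, -A, +A, ...
    order = np.cumsum(crossings, axis=1)
    steps = np.where(crossings, np.where(order % 2 == 1, 1.0, -1.0), 0.0) * amp
    values = np.zeros((n_epochs, SAMPLES_PER_EPOCH, 3))
    values[:, 1:, :] = np.cumsum(steps, axis=1)
    flat = values.reshape(-1, 3)
    t = np.arange(n_epochs * SAMPLES_PER_EPOCH) / 5.0
    return pd.DataFrame(
        {"t_s": t, "ax": flat[:, 0], "ay": flat[:, 1], "az": flat[:, 2]}
    )
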