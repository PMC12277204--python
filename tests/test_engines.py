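"""Firmware-twin semantics: cue scheduling, acknowledgment, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtmsim.engines import (
    ConfigurationError,
    CueEvent,
    EngineConfig,
    Mode,
    SessionTrace,
    cue_counts_and_latencies,
    init_engine,
    run_session,
    step,
)


class TestInit:
    def test_open_loop_timer_armed_to_interval(self, open_cfg):
        state = init_engine(open_cfg)
        assert state.timer_remaining_s == 600.0
        assert state.clock_s == 0.0 and not state.cue_active

    def test_closed_loop_countdown_armed_at_session_start(self, closed_lower_cfg):
        # session start counts as the start of a no-movement interval
        assert init_engine(closed_lower_cfg).timer_remaining_s == 120.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tick_s": 0.0},
            {"open_interval_min": 0.0},
            {"countdown_min": -1.0},
            {"countdown_min": 20.0},  # longer than the open-loop interval
            {"open_loop_anchor": "bogus"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            EngineConfig(mode=Mode.OPEN_LOOP, **kwargs)


class TestStep:
    def test_movement_reloads_closed_loop_countdown(self, closed_lower_cfg):
        state = init_engine(closed_lower_cfg)
        state, out = step(state, closed_lower_cfg, moved_this_epoch=True)
        assert state.timer_remaining_s == 120.0
        assert not out.cue_fired

    def test_open_loop_fires_regardless_of_movement(self, open_cfg):
        state = init_engine(open_cfg)
        # wind the timer down to its final tick
        for _ in range(299):
            state, out = step(state, open_cfg, moved_this_epoch=True)
            assert not out.cue_fired
        state, out = step(state, open_cfg, moved_this_epoch=True)
        assert out.cue_fired and out.cue_onset_s == 600.0

    def test_cue_repeats_until_button_pressed(self, closed_lower_cfg):
        state = init_engine(closed_lower_cfg)
        for _ in range(60):
            state, out = step(state, closed_lower_cfg, moved_this_epoch=False)
        assert out.cue_fired
        for _ in range(5):
            state, out = step(state, closed_lower_cfg, moved_this_epoch=True,
                              ack_pressed=False)
            assert state.cue_active and state.awaiting_ack
        state, out = step(state, closed_lower_cfg, moved_this_epoch=False,
                          ack_pressed=True)
        assert out.cue_acknowledged and not state.cue_active

    def test_countdown_suspended_while_awaiting_ack(self, closed_lower_cfg):
        state = init_engine(closed_lower_cfg)
        for _ in range(60):
            state, _ = step(state, closed_lower_cfg, moved_this_epoch=False)
        timer_at_fire = state.timer_remaining_s
        for _ in range(10):
            state, out = step(state, closed_lower_cfg, moved_this_epoch=False)
            assert not out.cue_fired
        assert state.timer_remaining_s == timer_at_fire == 120.0


class TestRunSession:
    def test_open_loop_3hr_instant_ack_yields_18_cues(self, open_cfg,
                                                      immobile_3hr_trace):
        events = run_session(open_cfg, immobile_3hr_trace)
        assert [e.onset_s for e in events] == [600.0 * k for k in range(1, 19)]

    def test_closed_loop_immobile_cues_every_countdown(self, closed_lower_cfg,
                                                       immobile_3hr_trace):
        events = run_session(closed_lower_cfg, immobile_3hr_trace)
        assert len(events) == 90
        assert np.allclose(np.diff([e.onset_s for e in events]), 120.0)

    def test_single_movement_epoch_delays_first_cue(self, closed_lower_cfg):
        flags = [False] * 5400
        flags[29] = True  # the epoch ending at t = 60 s
        events = run_session(closed_lower_cfg,
                             SessionTrace(movement_flags=flags, ack_policy=0.0))
        assert events[0].onset_s == 180.0

    def test_onsets_strictly_increasing(self, closed_lower_cfg, rng):
        flags = rng.random(2000) < 0.3
        events = run_session(
            closed_lower_cfg, SessionTrace(movement_flags=tuple(flags),
                                           ack_policy=4.0)
        )
        onsets = [e.onset_s for e in events]
        assert all(b > a for a, b in zip(onsets, onsets[1:]))

    def test_unacknowledged_cue_logged_without_ack(self, closed_lower_cfg):
        trace = SessionTrace(movement_flags=(False,) * 70, ack_policy=math.inf)
        events = run_session(closed_lower_cfg, trace)
        assert len(events) == 1 and events[0].ack_s is None

    def test_replay_deterministic(self, closed_lower_cfg, rng):
        flags = tuple(bool(b) for b in rng.random(3000) < 0.4)
        trace = SessionTrace(movement_flags=flags, ack_policy=2.0)
        assert run_session(closed_lower_cfg, trace) == run_session(
            closed_lower_cfg, trace
        )


@st.composite
def movement_pair(draw):
    """Two traces, the second with movement in a superset of epochs."""
    n = draw(st.integers(min_value=200, max_value=1200))
    base = draw(st.lists(st.booleans(), min_size=n, max_size=n))
    extra = draw(st.lists(st.booleans(), min_size=n, max_size=n))
    more = [b or e for b, e in zip(base, extra)]
    return base, more


class TestProperties:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(movement_pair())
    def test_closed_loop_avoidance_is_monotone(self, pair):
        """More movement never earns more closed-loop cues (same ack policy)."""
        base, more = pair
        cfg = EngineConfig(mode=Mode.CLOSED_LOOP, countdown_min=2.0)
        n_base = len(run_session(cfg, SessionTrace(base, ack_policy=0.0)))
        n_more = len(run_session(cfg, SessionTrace(more, ack_policy=0.0)))
        assert n_more <= n_base

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(movement_pair())
    def test_open_loop_onsets_ignore_movement(self, pair):
        base, more = pair
        cfg = EngineConfig(mode=Mode.OPEN_LOOP, open_interval_min=2.0)
        ev_a = run_session(cfg, SessionTrace(base, ack_policy=0.0))
        ev_b = run_session(cfg, SessionTrace(more, ack_policy=0.0))
        assert ev_a == ev_b

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.booleans(), min_size=60, max_size=2000))
    def test_cue_count_bounds(self, flags):
        duration = len(flags) * 2.0
        closed = EngineConfig(mode=Mode.CLOSED_LOOP, countdown_min=2.0)
        open_ = EngineConfig(mode=Mode.OPEN_LOOP, open_interval_min=2.0)
        n_closed = len(run_session(closed, SessionTrace(flags, ack_policy=0.0)))
        n_open = len(run_session(open_, SessionTrace(flags, ack_policy=0.0)))
        assert n_closed <= math.floor(duration / closed.countdown_s)
        assert n_open == math.floor(duration / open_.open_interval_s)


class TestCueSummary:
    def test_empty_log(self):
        summary = cue_counts_and_latencies([])
        assert summary.n_cues == 0 and summary.mean_reaction_s is None

    def test_mean_reaction_time(self):
        events = [CueEvent(10.0, 11.0), CueEvent(30.0, 32.0), CueEvent(50.0, 53.0)]
        summary = cue_counts_and_latencies(events)
        assert summary.n_cues == 3 and summary.mean_reaction_s == 2.0

    def test_mean_over_acknowledged_cues_only(self):
        events = [CueEvent(10.0, 14.0), CueEvent(30.0, None)]
        summary = cue_counts_and_latencies(events)
        assert summary.n_cues == 2 and summary.mean_reaction_s == 4.0

    def test_ack_before_onset_rejected(self):
        with pytest.raises(ValueError):
            CueEvent(10.0, 5.0)
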