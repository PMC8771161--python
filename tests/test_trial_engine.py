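"""Poke merging and the five-way trial response classification."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lineup.scheduler import Phase, SessionConfig
from lineup.trial_engine import (
    BeamEvent,
    CommandKind,
    EventKind,
    MalformedStreamError,
    Poke,
    Response,
    merge_pokes,
    read_events_csv,
    render_command_trace,
    run_trial,
    sniff_time,
    write_events_csv,
)

from conftest import make_spec, pokes_to_events


class TestMergePokes:
    def test_single_poke_duration(self):
        events = pokes_to_events([(2, 1000, 4200)])
        assert merge_pokes(events) == [Poke(port=2, start_ms=1000, duration_ms=4200)]

    def test_flicker_within_gap_merges_across_it(self):
        events = [
            BeamEvent(0, 1000, EventKind.BREAK),
            BeamEvent(0, 1200, EventKind.RESTORE),
            BeamEvent(0, 1250, EventKind.BREAK),
            BeamEvent(0, 1500, EventKind.RESTORE),
        ]
        assert merge_pokes(events, debounce_gap_ms=100) == [
            Poke(port=0, start_ms=1000, duration_ms=500)
        ]

    def test_gap_at_or_above_debounce_stays_split(self):
        events = pokes_to_events([(0, 1000, 200), (0, 1300, 200)])
        assert len(merge_pokes(events, debounce_gap_ms=100)) == 2

    def test_empty_stream(self):
        assert merge_pokes([]) == []

    def test_restore_without_break_is_malformed(self):
        with pytest.raises(MalformedStreamError):
            merge_pokes([BeamEvent(0, 500, EventKind.RESTORE)])

    def test_double_break_is_malformed(self):
        with pytest.raises(MalformedStreamError):
            merge_pokes(
                [BeamEvent(0, 100, EventKind.BREAK), BeamEvent(0, 200, EventKind.BREAK)]
            )

    def test_unterminated_break_closes_at_trial_end(self):
        events = [BeamEvent(1, 2000, EventKind.BREAK)]
        assert merge_pokes(events, trial_end_ms=6500) == [
            Poke(port=1, start_ms=2000, duration_ms=4500)
        ]


class TestRunTrialExamples:
    def test_correct_alert_on_target_hold(self, p3_config):
        spec = make_spec(target_port=2)
        events = pokes_to_events([(0, 1000, 600), (1, 2400, 500), (2, 3700, 4300)])
        result = run_trial(spec, events, p3_config)
        assert result.response is Response.CORRECT_ALERT
        assert result.rewarded
        assert result.alert_port == 2
        assert result.latency_ms == 1000
        # the alert fires the instant the 4-s criterion is reached
        assert result.end_ms == 3700 + 4000

    def test_blank_trial_all_clear_not_food_rewarded(self, p3_config):
        spec = make_spec(is_blank=True)
        events = pokes_to_events([(0, 1000, 800), (1, 2600, 800), (2, 4200, 800)])
        result = run_trial(spec, events, p3_config)
        assert result.response is Response.ALL_CLEAR_CORRECT
        assert not result.rewarded
        assert result.alert_port is None
        # the window is anchored to the last beam restore
        assert result.end_ms == 5000 + 4000

    def test_target_trial_all_ports_sampled_without_alert_is_miss(self, p3_config):
        spec = make_spec(target_port=1)
        events = pokes_to_events([(0, 1000, 800), (1, 2600, 800), (2, 4200, 800)])
        result = run_trial(spec, events, p3_config)
        assert result.response is Response.MISS
        assert result.alert_port is None

    def test_phase2_false_alert_terminates_without_reward(self, p2_config):
        spec = make_spec(target_port=1)
        events = pokes_to_events([(0, 1000, 4100)])
        result = run_trial(spec, events, p2_config)
        assert result.response is Response.FALSE_ALERT
        assert result.alert_port == 0
        assert not result.rewarded
        assert result.end_ms == 1000 + 4000

    def test_timeout_when_not_all_ports_searched(self, p3_config):
        spec = make_spec(target_port=2)
        events = pokes_to_events([(0, 1000, 600), (1, 2400, 500)])
        result = run_trial(spec, events, p3_config)
        assert result.response is Response.TIMEOUT
        assert result.end_ms == 45000

    def test_empty_stream_with_timeout(self, p3_config):
        result = run_trial(make_spec(), [], p3_config)
        assert result.response is Response.TIMEOUT
        assert result.latency_ms is None
        assert result.n_entries == 0

    def test_phase1_false_alert_logged_but_trial_continues(self):
        config = SessionConfig(phase=Phase.P1_ASSIST, blank_rate=0.0, seed=0)
        spec = make_spec(target_port=1)
        # distractor hold first, then the dog finds the target
        events = pokes_to_events([(0, 1000, 4200), (1, 6000, 4200)])
        result = run_trial(spec, events, config)
        assert result.response is Response.FALSE_ALERT
        assert not result.rewarded
        assert result.end_ms == 6000 + 4000  # runs until the correct hold
        assert len(result.pokes) == 2

    def test_visiting_third_port_at_deadline_counts_as_within_limit(self, p3_config):
        spec = make_spec(target_port=2, is_blank=False)
        events = pokes_to_events([(0, 1000, 600), (1, 2400, 500), (2, 45000, 600)])
        result = run_trial(spec, events, p3_config)
        assert result.response is not Response.TIMEOUT


class TestSniffTime:
    def test_alert_hold_excluded_from_sniffing(self, p3_config):
        spec = make_spec(target_port=2)
        events = pokes_to_events([(0, 1000, 600), (1, 2400, 500), (2, 3700, 4300)])
        result = run_trial(spec, events, p3_config)
        per_port, cumulative = sniff_time(result)
        assert cumulative == 600 + 500  # 4300-ms alert poke excluded
        assert per_port == (600, 500, 0)

    def test_all_clear_sniffing_counts_everything(self, p3_config):
        spec = make_spec(is_blank=True)
        events = pokes_to_events([(0, 1000, 800), (1, 2600, 800), (2, 4200, 800)])
        _, cumulative = sniff_time(run_trial(spec, events, p3_config))
        assert cumulative == 2400

    def test_no_pokes_zero_sniff(self, p3_config):
        _, cumulative = sniff_time(run_trial(make_spec(), [], p3_config))
        assert cumulative == 0


class TestHardwareLog:
    def test_reward_commands_iff_correct_alert(self, p3_config):
        spec = make_spec(target_port=0)
        correct = run_trial(spec, pokes_to_events([(0, 1000, 4500)]), p3_config)
        kinds = [c.kind for c in correct.hardware_log]
        assert kinds.count(CommandKind.BEEP) == 1
        assert kinds.count(CommandKind.FEEDER_PULSE) == 1

        wrong = run_trial(spec, pokes_to_events([(1, 1000, 4500)]), p3_config)
        kinds = [c.kind for c in wrong.hardware_log]
        assert CommandKind.BEEP not in kinds
        assert CommandKind.FEEDER_PULSE not in kinds

    def test_panel_fan_and_valves_once_per_trial(self, p3_config):
        result = run_trial(make_spec(), pokes_to_events([(1, 1000, 4500)]), p3_config)
        kinds = [c.kind for c in result.hardware_log]
        assert kinds.count(CommandKind.PANEL_UP) == 1
        assert kinds.count(CommandKind.PANEL_DOWN) == 1
        assert kinds.count(CommandKind.FAN_ON) == 1
        assert kinds.count(CommandKind.VALVE_OPEN) == 3
        assert kinds.count(CommandKind.VALVE_CLOSE) == 3
        fan = [c for c in result.hardware_log if c.kind is CommandKind.FAN_ON][0]
        assert fan.duration_s == 15.0

    def test_command_trace_renders_ordered_text(self, p3_config):
        result = run_trial(make_spec(target_port=0), pokes_to_events([(0, 1000, 4500)]), p3_config)
        trace = render_command_trace(result.hardware_log)
        lines = trace.splitlines()
        assert lines[0].endswith("PANEL_UP")
        assert any("FEEDER_PULSE" in line for line in lines)
        assert "FAN_ON" in lines[-1]


# ---------------------------------------------------------------------------
# Exhaustive small-instance oracle: a rule-by-rule 100-ms-tick simulator,
# independent of the engine's event-sweep implementation, over all
# sequential streams of up to 3 pokes on a port/duration grid.

TICK_MS = 100


def _tick_oracle(spec, pokes, config):
    """Classify by literally stepping a clock and re-checking each rule."""
    hold_ms = int(config.hold_criterion_s * 1000)
    window_ms = int(config.all_clear_window_s * 1000)
    timeout_ms = (
        None
        if config.effective_timeout_s is None
        else int(config.effective_timeout_s * 1000)
    )
    horizon = max(
        [timeout_ms or 0, window_ms]
        + [start + dur + window_ms for _, start, dur in pokes]
    )
    intervals = {(port, start, start + dur) for port, start, dur in pokes}

    visited: set[int] = set()
    hold_start: int | None = None
    hold_port: int | None = None
    last_restore: int | None = None
    for t in range(0, horizon + TICK_MS, TICK_MS):
        active = [iv for iv in intervals if iv[1] <= t < iv[2]]
        if active:
            port, start, _ = active[0]
            visited.add(port)
            hold_port, hold_start = port, start
            last_restore = None
        elif hold_start is not None and last_restore is None:
            last_restore = t  # beam restored on this tick boundary
        # rule 1: a continuous hold reaching criterion classifies the trial
        if active and t - hold_start >= hold_ms:
            on_target = (not spec.is_blank) and hold_port == spec.target_port
            return (
                Response.CORRECT_ALERT if on_target else Response.FALSE_ALERT,
                hold_port,
            )
        # rule 2: all ports sampled, no beam broken for the all-clear window
        if (
            not active
            and len(visited) == 3
            and last_restore is not None
            and t - last_restore >= window_ms
        ):
            return (
                Response.ALL_CLEAR_CORRECT if spec.is_blank else Response.MISS,
                None,
            )
        # rule 3: search time limit elapses with ports unvisited
        if timeout_ms is not None and t >= timeout_ms and len(visited) < 3:
            return Response.TIMEOUT, None
    # stream over, limits exhausted without a response
    return Response.TIMEOUT, None


def _grid_streams():
    """All sequential streams of 0-3 pokes; durations straddle the 4-s
    criterion; times are chosen so no two rule instants ever coincide."""
    ports = (0, 1, 2)
    durations = (600, 4500)
    for n in range(0, 4):
        for combo in itertools.product(itertools.product(ports, durations), repeat=n):
            pokes, t = [], 1000
            for port, dur in combo:
                pokes.append((port, t, dur))
                t += dur + 1100
            yield pokes


@pytest.mark.parametrize("is_blank", [False, True])
def test_engine_agrees_with_tick_oracle_on_small_grid(is_blank, p3_config):
    n_checked = 0
    for pokes in _grid_streams():
        spec = make_spec(target_port=1, is_blank=is_blank)
        result = run_trial(spec, pokes_to_events(pokes), p3_config)
        expected_response, expected_port = _tick_oracle(spec, pokes, p3_config)
        assert result.response is expected_response, pokes
        assert result.alert_port == expected_port, pokes
        n_checked += 1
    assert n_checked == 1 + 6 + 36 + 216


# ---------------------------------------------------------------------------
# Property tests


@st.composite
def sequential_streams(draw):
    n = draw(st.integers(0, 4))
    pokes, t = [], draw(st.integers(100, 3000))
    for _ in range(n):
        port = draw(st.integers(0, 2))
        dur = draw(st.integers(150, 6000))
        pokes.append((port, t, dur))
        t += dur + draw(st.integers(150, 3000))
    return pokes


@settings(max_examples=150, derandomize=True)
@given(pokes=sequential_streams(), target=st.integers(0, 2), blank=st.booleans())
def test_taxonomy_is_total_and_result_internally_consistent(pokes, target, blank):
    config = SessionConfig(seed=0)
    spec = make_spec(target_port=target, is_blank=blank)
    result = run_trial(spec, pokes_to_events(pokes), config)
    assert result.response in Response
    assert result.rewarded == (result.response is Response.CORRECT_ALERT)
    assert result.n_entries == len(result.pokes)
    if result.pokes:
        assert result.latency_ms == min(p.start_ms for p in result.pokes)
    if result.response in (Response.MISS, Response.ALL_CLEAR_CORRECT):
        assert result.alert_port is None
    # classification is a pure function of its inputs
    again = run_trial(spec, pokes_to_events(pokes), config)
    assert again.response is result.response
    assert again.end_ms == result.end_ms


def test_events_csv_round_trip(tmp_path):
    events = pokes_to_events([(0, 1000, 600), (2, 2000, 4300)])
    path = write_events_csv(events, tmp_path / "events.csv")
    assert read_events_csv(path) == events
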