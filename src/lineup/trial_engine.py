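"""Single-trial scoring over infrared beam-break events.

The apparatus observes a trial only through the IR beam at each port
entrance: a BREAK when the dog's nose enters, a RESTORE when it leaves.
This module turns a raw beam-event stream into merged nose pokes, applies
the phase rules, and classifies the response:

CORRECT_ALERT
    a continuous nose hold of at least the criterion duration at the
    target port (beep + feeder pulse issued at the instant the criterion
    is reached).
FALSE_ALERT
    a criterion hold at a distractor port, or any criterion hold on a
    blank trial.  In phase 1 it is logged and the trial continues; in
    phases 2-3 the trial terminates without reward.
ALL_CLEAR_CORRECT / MISS
    the dog sampled all three ports and then withheld alerting for the
    all-clear window; correct on blank trials, a miss on target trials.
MISS / TIMEOUT
    TIMEOUT is recorded when the search time limit elapses before all
    three ports have been sampled.

Timing conventions: all times are integer milliseconds from panel raise.
A hold reaches criterion inclusively (duration >= criterion) and the alert
fires at ``poke_start + criterion``, not at poke end, mirroring the live
feeder.  Consecutive beam breaks on one port separated by less than the
debounce gap are one merged poke whose duration spans the gap.  The
all-clear clock arms once every port has been entered at least once, is
anchored to the most recent RESTORE that left all beams clear, and is
reset by any subsequent BREAK.  Ties at a single instant resolve in the
order alert > all-clear > timeout, and an entry at exactly the time limit
still counts as searching "within" it.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .scheduler import Phase, SessionConfig, TrialSpec

__all__ = [
    "EventKind",
    "BeamEvent",
    "Poke",
    "Response",
    "CommandKind",
    "HardwareCommand",
    "TrialResult",
    "MalformedStreamError",
    "merge_pokes",
    "run_trial",
    "sniff_time",
    "write_events_csv",
    "read_events_csv",
    "render_command_trace",
]


class EventKind(str, Enum):
    BREAK = "BREAK"
    RESTORE = "RESTORE"


class Response(str, Enum):
    CORRECT_ALERT = "CORRECT_ALERT"
    FALSE_ALERT = "FALSE_ALERT"
    ALL_CLEAR_CORRECT = "ALL_CLEAR_CORRECT"
    MISS = "MISS"
    TIMEOUT = "TIMEOUT"


class CommandKind(str, Enum):
    VALVE_OPEN = "VALVE_OPEN"
    VALVE_CLOSE = "VALVE_CLOSE"
    PANEL_UP = "PANEL_UP"
    PANEL_DOWN = "PANEL_DOWN"
    FAN_ON = "FAN_ON"
    FEEDER_PULSE = "FEEDER_PULSE"
    BEEP = "BEEP"


class MalformedStreamError(ValueError):
    """Raised on an ill-formed beam-event stream (e.g. RESTORE with no BREAK)."""


@dataclass(frozen=True)
class BeamEvent:
    """A single IR beam transition at one port, in ms from panel raise."""

    port: int
    t_ms: int
    kind: EventKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", EventKind(self.kind))


@dataclass(frozen=True)
class Poke:
    """A merged nose poke: one continuous (debounced) beam interruption."""

    port: int
    start_ms: int
    duration_ms: int


@dataclass(frozen=True)
class HardwareCommand:
    kind: CommandKind
    t_ms: int
    port: int | None = None
    channel: str | None = None
    duration_s: float | None = None


@dataclass(frozen=True)
class TrialResult:
    """Classified outcome of one trial plus its behavioral measures."""

    response: Response
    alert_port: int | None
    latency_ms: int | None
    entries_by_port: tuple[int, ...]
    sniff_ms_by_port: tuple[int, ...]
    pokes: tuple[Poke, ...]
    rewarded: bool
    hardware_log: tuple[HardwareCommand, ...]
    end_ms: int

    @property
    def cumulative_sniff_ms(self) -> int:
        return sum(self.sniff_ms_by_port)

    @property
    def n_entries(self) -> int:
        return sum(self.entries_by_port)


# ---------------------------------------------------------------------------
# Poke merging


def _raw_segments(
    events: Iterable[BeamEvent],
) -> tuple[dict[int, list[list[int | None]]], int]:
    """Per-port (break, restore-or-None) segments, validating the stream.

    Returns the segments and the timestamp of the last event (0 if empty).
    """
    segments: dict[int, list[list[int | None]]] = {}
    open_ports: set[int] = set()
    last_t = 0
    prev_t: int | None = None
    for ev in events:
        if prev_t is not None and ev.t_ms < prev_t:
            raise MalformedStreamError(
                f"event timestamps must be non-decreasing (t={ev.t_ms} after {prev_t})"
            )
        prev_t = ev.t_ms
        last_t = ev.t_ms
        segs = segments.setdefault(ev.port, [])
        if ev.kind is EventKind.BREAK:
            if ev.port in open_ports:
                raise MalformedStreamError(
                    f"port {ev.port}: BREAK at {ev.t_ms} while beam already broken"
                )
            open_ports.add(ev.port)
            segs.append([ev.t_ms, None])
        else:
            if ev.port not in open_ports:
                raise MalformedStreamError(
                    f"port {ev.port}: RESTORE at {ev.t_ms} without a prior BREAK"
                )
            open_ports.discard(ev.port)
            segs[-1][1] = ev.t_ms
    return segments, last_t


def merge_pokes(
    events: Iterable[BeamEvent],
    debounce_gap_ms: int = 100,
    trial_end_ms: int | None = None,
) -> list[Poke]:
    """Merge beam events into debounced nose pokes, sorted by start time.

    Same-port pokes separated by less than ``debounce_gap_ms`` become one
    poke spanning first BREAK to last RESTORE (IR sensors flicker).  An
    unterminated BREAK is closed at ``trial_end_ms`` (default: the last
    event timestamp).
    """
    events = list(events)
    segments, last_t = _raw_segments(events)
    end = last_t if trial_end_ms is None else trial_end_ms
    pokes: list[Poke] = []
    for port, segs in segments.items():
        merged: list[list[int]] = []
        for start, stop in segs:
            stop_ms = max(end, start) if stop is None else stop
            if merged and start - merged[-1][1] < debounce_gap_ms:
                merged[-1][1] = max(merged[-1][1], stop_ms)
            else:
                merged.append([start, stop_ms])
        for start, stop in merged:
            if stop > start:
                pokes.append(Poke(port=port, start_ms=start, duration_ms=stop - start))
    pokes.sort(key=lambda p: (p.start_ms, p.port))
    return pokes


# ---------------------------------------------------------------------------
# Trial classification


def _quiet_intervals(events: Sequence[BeamEvent]) -> list[tuple[int, float]]:
    """Intervals [restore_t, next_break_t) during which no beam is broken.

    Uses raw (un-debounced) events: any BREAK resets the all-clear clock.
    The final interval extends to infinity (end of stream = silence).
    """
    intervals: list[tuple[int, float]] = []
    n_open = 0
    quiet_since: int | None = None
    for ev in events:
        if ev.kind is EventKind.BREAK:
            if n_open == 0 and quiet_since is not None:
                intervals.append((quiet_since, ev.t_ms))
                quiet_since = None
            n_open += 1
        else:
            n_open -= 1
            if n_open == 0:
                quiet_since = ev.t_ms
    if quiet_since is not None:
        intervals.append((quiet_since, float("inf")))
    return intervals


def run_trial(
    spec: TrialSpec, events: Iterable[BeamEvent], config: SessionConfig
) -> TrialResult:
    """Score one trial from its beam-event stream.

    Pure in (spec, events, config): identical inputs give identical
    results.  Streams that end before any terminating condition (operator
    abort with the line-up unsearched) are scored TIMEOUT.
    """
    events = sorted(events, key=lambda ev: ev.t_ms)
    _raw_segments(events)  # validate before doing anything else
    stream_end = events[-1].t_ms if events else 0

    hold_ms = int(round(config.hold_criterion_s * 1000))
    window_ms = int(round(config.all_clear_window_s * 1000))
    timeout = config.effective_timeout_s
    timeout_ms = None if timeout is None else int(round(timeout * 1000))

    pokes_all = merge_pokes(events, config.debounce_gap_ms, trial_end_ms=stream_end)

    # Candidate terminal instants -----------------------------------------
    # Alerts: each criterion-length merged poke fires at start + criterion.
    alerts = [
        (p.start_ms + hold_ms, p) for p in pokes_all if p.duration_ms >= hold_ms
    ]
    alerts.sort(key=lambda a: a[0])

    # All-clear: first quiet interval of window length once all ports seen.
    first_break: dict[int, int] = {}
    for ev in events:
        if ev.kind is EventKind.BREAK:
            first_break.setdefault(ev.port, ev.t_ms)
    all_visited = len(first_break) >= config.n_ports
    allclear_t: int | None = None
    if all_visited:
        for start, stop in _quiet_intervals(events):
            if stop - start >= window_ms:
                allclear_t = start + window_ms
                break

    # Timeout: the time limit elapses with the line-up not fully searched.
    timeout_t: int | None = None
    if timeout_ms is not None:
        third_visit = (
            max(sorted(first_break.values())[: config.n_ports])
            if all_visited
            else None
        )
        if third_visit is None or third_visit > timeout_ms:
            timeout_t = timeout_ms

    # Terminal selection ---------------------------------------------------
    response: Response | None = None
    alert_port: int | None = None
    alert_poke: Poke | None = None
    end_ms: int | None = None
    p1 = config.phase is Phase.P1_ASSIST

    def beats(t: int, kind_rank: int) -> bool:
        """Does a candidate at time t with the given priority rank win?"""
        for other_t, other_rank in (
            (allclear_t, 1),
            (timeout_t, 2),
        ):
            if other_t is not None and (
                other_t < t or (other_t == t and other_rank < kind_rank)
            ):
                return False
        return True

    if alerts:
        t_first, poke = alerts[0]
        if beats(t_first, 0):
            on_target = (not spec.is_blank) and poke.port == spec.target_port
            if on_target:
                response, alert_port, alert_poke, end_ms = (
                    Response.CORRECT_ALERT,
                    poke.port,
                    poke,
                    t_first,
                )
            else:
                response, alert_port, alert_poke = (
                    Response.FALSE_ALERT,
                    poke.port,
                    poke,
                )
                if p1:
                    # Phase 1: logged only; the trial runs on until the dog
                    # finds the target or the handler ends the trial.
                    end_ms = stream_end
                    for t_a, pk in alerts[1:]:
                        if (not spec.is_blank) and pk.port == spec.target_port:
                            end_ms = t_a
                            break
                else:
                    end_ms = t_first

    if response is None and allclear_t is not None and (
        timeout_t is None or allclear_t <= timeout_t
    ):
        response = Response.ALL_CLEAR_CORRECT if spec.is_blank else Response.MISS
        end_ms = allclear_t

    if response is None and timeout_t is not None:
        response, end_ms = Response.TIMEOUT, timeout_t

    if response is None:
        # Stream exhausted with no terminating condition: the trial ended
        # without a scoreable response (operator abort); score TIMEOUT.
        response, end_ms = Response.TIMEOUT, stream_end

    assert end_ms is not None

    # Behavioral measures --------------------------------------------------
    kept = [p for p in pokes_all if p.start_ms <= end_ms]
    dropped = len(pokes_all) - len(kept)
    if dropped:
        warnings.warn(
            f"{dropped} poke(s) began after trial end (t={end_ms} ms); ignored",
            stacklevel=2,
        )

    entries = [0] * config.n_ports
    sniff = [0] * config.n_ports
    for p in kept:
        entries[p.port] += 1
        sniff[p.port] += p.duration_ms
    if alert_poke is not None and alert_poke in kept:
        # The alert hold itself does not count as sniffing.
        sniff[alert_poke.port] -= alert_poke.duration_ms
    latency = min((p.start_ms for p in kept), default=None)

    rewarded = response is Response.CORRECT_ALERT
    log: list[HardwareCommand] = [HardwareCommand(CommandKind.PANEL_UP, 0)]
    for port, channel in enumerate(spec.channel_by_port):
        log.append(HardwareCommand(CommandKind.VALVE_OPEN, 0, port=port, channel=channel))
    if rewarded:
        log.append(HardwareCommand(CommandKind.BEEP, end_ms))
        log.append(HardwareCommand(CommandKind.FEEDER_PULSE, end_ms))
    for port, channel in enumerate(spec.channel_by_port):
        log.append(
            HardwareCommand(CommandKind.VALVE_CLOSE, end_ms, port=port, channel=channel)
        )
    log.append(HardwareCommand(CommandKind.PANEL_DOWN, end_ms))
    log.append(HardwareCommand(CommandKind.FAN_ON, end_ms, duration_s=config.iti_fan_s))

    return TrialResult(
        response=response,
        alert_port=alert_port,
        latency_ms=latency,
        entries_by_port=tuple(entries),
        sniff_ms_by_port=tuple(sniff),
        pokes=tuple(kept),
        rewarded=rewarded,
        hardware_log=tuple(log),
        end_ms=end_ms,
    )


def sniff_time(result: TrialResult) -> tuple[tuple[int, ...], int]:
    """Per-port and cumulative sniffing time (ms), excluding the alert hold.

    Cumulative sniff = sum of all poke durations minus the duration of the
    alert-triggering poke, if any.
    """
    return result.sniff_ms_by_port, result.cumulative_sniff_ms


# ---------------------------------------------------------------------------
# Event stream CSV I/O and the hardware command trace


def write_events_csv(events: Sequence[BeamEvent], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_ms", "port", "kind"])
        for ev in events:
            writer.writerow([ev.t_ms, ev.port + 1, ev.kind.value])
    return path


def read_events_csv(path: str | Path) -> list[BeamEvent]:
    path = Path(path)
    events: list[BeamEvent] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = {"t_ms", "port", "kind"} - set(reader.fieldnames or ())
        if missing:
            raise MalformedStreamError(f"event file missing columns: {sorted(missing)}")
        for row in reader:
            events.append(
                BeamEvent(
                    port=int(row["port"]) - 1,
                    t_ms=int(row["t_ms"]),
                    kind=EventKind(row["kind"]),
                )
            )
    return events


def render_command_trace(log: Iterable[HardwareCommand]) -> str:
    """Render a hardware log as an ordered text trace (for golden files)."""
    lines = []
    for cmd in log:
        parts = [f"{cmd.t_ms:>8d} ms  {cmd.kind.value}"]
        if cmd.port is not None:
            parts.append(f"port={cmd.port + 1}")
        if cmd.channel is not None:
            parts.append(f"channel={cmd.channel}")
        if cmd.duration_s is not None:
            parts.append(f"duration={cmd.duration_s:g}s")
        lines.append(" ".join(parts))
    return "\n".join(lines)
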