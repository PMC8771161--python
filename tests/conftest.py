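import numpy as np
import pytest

from lineup.scheduler import Phase, SessionConfig, TrialSpec
from lineup.trial_engine import (
    BeamEvent,
    EventKind,
    HardwareCommand,
    Poke,
    Response,
    TrialResult,
)


@pytest.fixture
def p3_config() -> SessionConfig:
    """Standard fully-trained phase-3 session: 40 trials, 4-s hold,
    45-s timeout, 10% blanks."""
    return SessionConfig(seed=0)


@pytest.fixture
def p2_config() -> SessionConfig:
    return SessionConfig(phase=Phase.P2_BLIND, blank_rate=0.0, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_spec(target_port=1, is_blank=False, index=0) -> TrialSpec:
    channels = tuple(
        "smokeless_powder" if (not is_blank and p == target_port) else "gauze"
        for p in range(3)
    )
    return TrialSpec(
        index=index,
        is_blank=is_blank,
        target_port=None if is_blank else target_port,
        channel_by_port=channels,
    )


def pokes_to_events(pokes: list[tuple[int, int, int]]) -> list[BeamEvent]:
    """(port, start_ms, duration_ms) triplets -> a sorted beam-event stream."""
    events = []
    for port, start, dur in pokes:
        events.append(BeamEvent(port=port, t_ms=start, kind=EventKind.BREAK))
        events.append(BeamEvent(port=port, t_ms=start + dur, kind=EventKind.RESTORE))
    return sorted(events, key=lambda ev: ev.t_ms)


def make_result(
    response: Response,
    alert_port: int | None = None,
    latency_ms: int | None = 1000,
    pokes: tuple[Poke, ...] = (),
    entries=(1, 1, 1),
    sniff=(400, 400, 400),
) -> TrialResult:
    """Minimal classified result for analysis-level tests."""
    return TrialResult(
        response=response,
        alert_port=alert_port,
        latency_ms=latency_ms,
        entries_by_port=tuple(entries),
        sniff_ms_by_port=tuple(sniff),
        pokes=pokes,
        rewarded=response is Response.CORRECT_ALERT,
        hardware_log=(),
        end_ms=20000,
    )
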