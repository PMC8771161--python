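"""Simulated hardware backend: a parameterized virtual dog.

The trial engine only ever sees IR beam events, so the virtual dog is
event-level, not kinematic: it emits BREAK/RESTORE pairs directly.  On
each trial the agent waits a sampled search-onset latency, then visits
ports in its visit-policy order.  At the target port (when target odor is
actually being delivered) it produces a criterion-length hold with
probability ``p_detect``; at any other port it produces one with
probability ``p_false_alert``; otherwise it sniffs for a sub-criterion
duration and moves on.  After an alert hold it stops; after visiting all
ports without alerting it falls silent, so the engine scores an all-clear
or a miss.

The odor-unplugged control test is modeled as the agent losing access to
target identity: with ``odor_connected=False`` every port behaves as a
non-target, mirroring the physical disconnection of the odor jars.

Default parameters emulate a fully trained dog at the end of phase 3:
high detection probability, rare false alerts, ~11 s search-onset
latency, and sub-half-second sniffs per port.  The agent does not learn
across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .scheduler import Phase, SessionConfig, TrialSpec, generate_session_plan
from .trial_engine import BeamEvent, EventKind, TrialResult, run_trial

__all__ = [
    "VisitPolicy",
    "AgentParams",
    "uniform_random_alert_agent",
    "simulate_trial_events",
    "run_simulated_session",
]


class VisitPolicy(str, Enum):
    LEFT_TO_RIGHT = "LEFT_TO_RIGHT"
    RANDOM_ORDER = "RANDOM_ORDER"


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of the virtual dog.

    p_detect
        Probability of a criterion hold at the target port when target
        odor is delivered there.
    p_false_alert
        Per-port probability of a criterion hold at a port not delivering
        target odor.
    latency_mean_s / latency_sd_s
        Search-onset delay from panel raise to the first port entry.
    sniff_mean_s / sniff_sd_s
        Duration of a non-alert poke (clipped below the hold criterion).
    transit_mean_s / transit_sd_s
        Travel time between consecutive ports.
    hold_overshoot_s
        How far past the criterion an alert hold lasts.
    """

    p_detect: float = 0.95
    p_false_alert: float = 0.02
    latency_mean_s: float = 11.0
    latency_sd_s: float = 3.0
    sniff_mean_s: float = 0.4
    sniff_sd_s: float = 0.15
    transit_mean_s: float = 0.8
    transit_sd_s: float = 0.2
    visit_policy: VisitPolicy = VisitPolicy.LEFT_TO_RIGHT
    hold_overshoot_s: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "visit_policy", VisitPolicy(self.visit_policy))
        for name in ("p_detect", "p_false_alert"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("latency_mean_s", "sniff_mean_s", "transit_mean_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hold_overshoot_s < 0:
            raise ValueError("hold_overshoot_s must be non-negative")


def uniform_random_alert_agent(**overrides) -> AgentParams:
    """Agent that alerts exactly once per trial at a uniformly random port.

    Visiting ports in random order and alerting unconditionally at the
    first port visited makes the alerted port uniform over the three
    ports, so long-run accuracy on target-present trials is the 1/3
    chance level of the line-up.
    """
    params = dict(
        p_detect=1.0,
        p_false_alert=1.0,
        visit_policy=VisitPolicy.RANDOM_ORDER,
    )
    params.update(overrides)
    return AgentParams(**params)


def _positive_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float | None = None
) -> float:
    x = rng.normal(mean, sd)
    if hi is not None:
        x = min(x, hi)
    return max(x, lo)


def simulate_trial_events(
    agent: AgentParams,
    spec: TrialSpec,
    config: SessionConfig,
    odor_connected: bool = True,
    rng: np.random.Generator | None = None,
) -> list[BeamEvent]:
    """Emit the beam-event stream of one simulated trial."""
    if rng is None:
        rng = np.random.default_rng(agent.seed)

    order = list(range(config.n_ports))
    if agent.visit_policy is VisitPolicy.RANDOM_ORDER:
        order = [int(p) for p in rng.permutation(config.n_ports)]

    hold_ms = int(round(config.hold_criterion_s * 1000))
    # Sub-criterion sniffs stay clear of the alert boundary and of zero.
    sniff_cap_ms = max(hold_ms - max(50, config.debounce_gap_ms), 50)
    effective_target = (
        spec.target_port if (not spec.is_blank and odor_connected) else None
    )

    t = int(round(1000 * _positive_normal(rng, agent.latency_mean_s, agent.latency_sd_s, 0.05)))
    events: list[BeamEvent] = []
    for port in order:
        if port == effective_target:
            alert = rng.random() < agent.p_detect
        else:
            alert = rng.random() < agent.p_false_alert
        if alert:
            dur = hold_ms + int(round(1000 * agent.hold_overshoot_s))
        else:
            dur = int(
                round(
                    1000
                    * _positive_normal(
                        rng, agent.sniff_mean_s, agent.sniff_sd_s, 0.05
                    )
                )
            )
            dur = min(dur, sniff_cap_ms)
        events.append(BeamEvent(port=port, t_ms=t, kind=EventKind.BREAK))
        events.append(BeamEvent(port=port, t_ms=t + dur, kind=EventKind.RESTORE))
        if alert:
            break
        transit = int(
            round(
                1000
                * _positive_normal(rng, agent.transit_mean_s, agent.transit_sd_s, 0.2)
            )
        )
        t += dur + max(transit, config.debounce_gap_ms + 50)
    return events


def run_simulated_session(
    agent: AgentParams,
    config: SessionConfig,
    rng: np.random.Generator | None = None,
    odor_connected: bool = True,
) -> tuple[list[TrialSpec], list[TrialResult]]:
    """Run a full closed-loop simulated session.

    Generates the counterbalanced plan, lets the virtual dog produce beam
    events for every trial, and scores each trial with the engine.  Fully
    deterministic for a fixed config seed (or caller-supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    plan = generate_session_plan(config, rng)
    results = [
        run_trial(
            spec,
            simulate_trial_events(agent, spec, config, odor_connected, rng),
            config,
        )
        for spec in plan
    ]
    return plan, results
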