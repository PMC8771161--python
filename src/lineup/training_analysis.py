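"""Performance metrics and training-phase progression.

A session summary partitions every trial into one of four outcomes
(correct, false alert, miss, timeout); correct responses are alerts to
the target port plus all-clears on blank trials.  Daily performance is
the unweighted mean of that day's session proportions.

The progression rules shape the nose-hold criterion from 0.25 s to 4 s
and advance phases P1 -> P2 -> P3:

* while shaping with the food odor, the criterion steps up 0.5 s after
  every session in which the dog independently activated the IR beams,
  to 2 s (the first step aligns 0.25 s onto the 0.5-s grid);
* at 2 s with the food target, a daily performance of at least 85%
  switches the target to the main odor, dropping the criterion to 1 s
  for the single transition session (after which it returns to 2 s);
* with the main odor, two consecutive sessions at 85%+ start the 0.5-s
  steps from 2 s toward 4 s, one step per subsequent 85%+ session;
* 85%+ at the 4-s criterion advances the phase (an optional flag skips
  phase 2, as done for the second cohort); phases 2 and 3 each require
  two consecutive 85%+ sessions;
* any sub-criterion session resets the consecutive counter and leaves
  the state unchanged — regression to easier training is an operator
  decision, never automatic.

"85%" is compared as >= 0.85 after rounding to 4 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .trial_engine import Response, TrialResult
from .scheduler import Phase

__all__ = [
    "SessionSummary",
    "PhaseState",
    "session_summary",
    "daily_performance",
    "advance_training",
    "chance_level",
    "FOOD_TARGET",
    "MAIN_TARGET",
]

FOOD_TARGET = "hotdog"
MAIN_TARGET = "smokeless_powder"

PERFORMANCE_CRITERION = 0.85
MAX_HOLD_S = 4.0
SHAPING_CAP_S = 2.0
TRANSITION_HOLD_S = 1.0


@dataclass(frozen=True)
class SessionSummary:
    n_trials: int
    proportion_correct: float
    proportion_false_alert: float
    proportion_miss: float
    proportion_timeout: float
    mean_latency_ms: float
    mean_cumulative_sniff_ms: float
    mean_entries_per_trial: float


@dataclass(frozen=True)
class PhaseState:
    """Where a dog stands in the training progression."""

    phase: Phase = Phase.P1_ASSIST
    target_channel: str = FOOD_TARGET
    hold_criterion_s: float = 0.25
    consecutive_sessions_at_criterion: int = 0
    assist_mode: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", Phase(self.phase))
        c = self.hold_criterion_s
        on_grid = abs(c / 0.5 - round(c / 0.5)) < 1e-9 and 0.5 <= c <= MAX_HOLD_S
        if not (c == 0.25 or on_grid):
            raise ValueError(
                f"hold_criterion_s must be 0.25 or a 0.5-s step up to 4.0, got {c}"
            )

    @property
    def fully_trained(self) -> bool:
        return (
            self.phase is Phase.P3_BLANKS
            and self.consecutive_sessions_at_criterion >= 2
        )


def session_summary(results: Sequence[TrialResult]) -> SessionSummary:
    """Aggregate one session's trial results.

    Correct = alerts to the target plus all-clears on blanks.  Mean
    latency is taken over trials with a defined latency only (a trial
    with no entries contributes nothing).
    """
    if not results:
        raise ValueError("cannot summarize an empty session")
    n = len(results)
    counts = {resp: 0 for resp in Response}
    for res in results:
        counts[res.response] += 1
    latencies = [r.latency_ms for r in results if r.latency_ms is not None]
    return SessionSummary(
        n_trials=n,
        proportion_correct=(
            counts[Response.CORRECT_ALERT] + counts[Response.ALL_CLEAR_CORRECT]
        )
        / n,
        proportion_false_alert=counts[Response.FALSE_ALERT] / n,
        proportion_miss=counts[Response.MISS] / n,
        proportion_timeout=counts[Response.TIMEOUT] / n,
        mean_latency_ms=float(np.mean(latencies)) if latencies else float("nan"),
        mean_cumulative_sniff_ms=float(
            np.mean([r.cumulative_sniff_ms for r in results])
        ),
        mean_entries_per_trial=float(np.mean([r.n_entries for r in results])),
    )


def daily_performance(
    summaries_by_day: Mapping[object, Sequence[SessionSummary | float]],
) -> dict[object, float]:
    """One performance value per day: the unweighted mean of that day's
    session proportions (a single session passes through unchanged)."""
    out: dict[object, float] = {}
    for day, sessions in summaries_by_day.items():
        values = [
            s.proportion_correct if isinstance(s, SessionSummary) else float(s)
            for s in sessions
        ]
        if not values:
            continue
        out[day] = float(np.mean(values))
    return out


def chance_level(n_ports: int) -> float:
    """Accuracy expected of a random alerter: 1/n_ports (33% on 3 ports)."""
    if n_ports < 1:
        raise ValueError("n_ports must be >= 1")
    return 1.0 / n_ports


def _met(performance: float) -> bool:
    return round(performance, 4) >= PERFORMANCE_CRITERION


def _next_shaping_step(criterion: float, cap: float) -> float:
    if criterion == 0.25:
        return 0.5
    return min(cap, criterion + 0.5)


def advance_training(
    state: PhaseState,
    performance: float,
    independent_ir: bool = False,
    skip_phase2: bool = False,
) -> PhaseState:
    """Apply one session's (or day's) outcome to the training state.

    ``performance`` is the session or daily proportion correct;
    ``independent_ir`` records whether the dog activated the IR beams on
    its own throughout the session (gates the early shaping steps);
    ``skip_phase2`` advances P1 graduates straight to P3.
    """
    met = _met(performance)
    counter = state.consecutive_sessions_at_criterion + 1 if met else 0

    if state.phase is Phase.P1_ASSIST:
        if state.target_channel == FOOD_TARGET:
            if state.hold_criterion_s < SHAPING_CAP_S:
                if independent_ir:
                    return replace(
                        state,
                        hold_criterion_s=_next_shaping_step(
                            state.hold_criterion_s, SHAPING_CAP_S
                        ),
                        consecutive_sessions_at_criterion=counter,
                    )
                return replace(state, consecutive_sessions_at_criterion=counter)
            if met:  # 2-s food criterion reached: switch to the main odor
                return replace(
                    state,
                    target_channel=MAIN_TARGET,
                    hold_criterion_s=TRANSITION_HOLD_S,
                    consecutive_sessions_at_criterion=0,
                )
            return replace(state, consecutive_sessions_at_criterion=0)

        # Main odor in phase 1.
        if state.hold_criterion_s == TRANSITION_HOLD_S:
            # The assisted 1-s transition session always completes; the
            # criterion returns to 2 s regardless of its score.
            return replace(
                state,
                hold_criterion_s=SHAPING_CAP_S,
                consecutive_sessions_at_criterion=counter,
            )
        if state.hold_criterion_s == SHAPING_CAP_S:
            if counter >= 2:  # two consecutive sessions at 85%+: start stepping
                return replace(
                    state,
                    hold_criterion_s=SHAPING_CAP_S + 0.5,
                    consecutive_sessions_at_criterion=counter,
                )
            return replace(state, consecutive_sessions_at_criterion=counter)
        if state.hold_criterion_s < MAX_HOLD_S:
            if met:
                return replace(
                    state,
                    hold_criterion_s=state.hold_criterion_s + 0.5,
                    consecutive_sessions_at_criterion=counter,
                )
            return replace(state, consecutive_sessions_at_criterion=0)
        # 4-s criterion: graduate from phase 1.
        if met:
            return replace(
                state,
                phase=Phase.P3_BLANKS if skip_phase2 else Phase.P2_BLIND,
                assist_mode=False,
                consecutive_sessions_at_criterion=0,
            )
        return replace(state, consecutive_sessions_at_criterion=0)

    if state.phase is Phase.P2_BLIND:
        if counter >= 2:
            return replace(
                state,
                phase=Phase.P3_BLANKS,
                consecutive_sessions_at_criterion=0,
            )
        return replace(state, consecutive_sessions_at_criterion=counter)

    # Phase 3: the counter tracks progress toward "fully trained".
    return replace(state, consecutive_sessions_at_criterion=counter)
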