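"""Session planning for the three-port olfactometer line-up.

A session is a sequence of trials.  On a target trial one port delivers the
target odorant and the remaining ports deliver distractors; on a blank trial
every port delivers a distractor.  The planner guarantees two balance
properties that the live apparatus relies on for double-blind testing:

* the target port is counterbalanced, so per-port target counts never differ
  by more than one across the session, and
* blank trials are placed at a fixed per-block rate (e.g. one blank inside
  every consecutive block of ten trials at a 10% blank rate).

Distractor channels are drawn independently and uniformly per olfactometer
per trial, so the two (or, on blanks, three) distractors may coincide.
All randomness flows through a single seeded ``numpy.random.Generator``,
making a plan a pure function of its configuration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Phase",
    "ConfigError",
    "SessionConfig",
    "TrialSpec",
    "DEFAULT_DISTRACTORS",
    "dilution_fraction",
    "counterbalance_ports",
    "place_blanks",
    "generate_session_plan",
    "write_plan_csv",
    "read_plan_csv",
]


class Phase(str, Enum):
    """Training phase of a session.

    P1_ASSIST
        Shaping phase: the operator interface may display the target port
        and incorrect responses have no programmed consequence.
    P2_BLIND
        Double-blind phase: a criterion hold on a distractor port
        terminates the trial without reward.
    P3_BLANKS
        Double-blind phase with blank (target-absent) trials and a search
        time limit; withholding on a blank scores an all-clear.
    """

    P1_ASSIST = "P1_ASSIST"
    P2_BLIND = "P2_BLIND"
    P3_BLANKS = "P3_BLANKS"


class ConfigError(ValueError):
    """Raised when a session configuration violates an invariant."""


#: Default distractor channels: common laboratory odor-preparation materials
#: plus a novel strong odorant (dilute limonene).
DEFAULT_DISTRACTORS = ("empty_vial", "gauze", "glove", "mineral_oil", "limonene")


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one line-up session.

    Defaults reflect the standard fully-trained configuration: 40 trials,
    4-s nose-hold alert criterion, 45-s search limit, 10% blanks placed one
    per block of 10, 1 LPM odor line diluted into 2 LPM clean air (33%
    dilution), and a 15-s inter-trial exhaust-fan period.
    """

    n_trials: int = 40
    n_ports: int = 3
    target_channel: str = "smokeless_powder"
    distractor_channels: tuple[str, ...] = DEFAULT_DISTRACTORS
    blank_rate: float = 0.10
    blank_block_size: int = 10
    hold_criterion_s: float = 4.0
    timeout_s: float | None = 45.0
    all_clear_window_s: float = 4.0
    iti_fan_s: float = 15.0
    odor_flow_lpm: float = 1.0
    clean_flow_lpm: float = 2.0
    phase: Phase = Phase.P3_BLANKS
    seed: int = 0
    debounce_gap_ms: int = 100
    #: the search time limit is a phase-3 rule by default; set True to
    #: enforce it in every phase.
    timeout_all_phases: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", Phase(self.phase))
        object.__setattr__(
            self, "distractor_channels", tuple(self.distractor_channels)
        )
        if self.n_trials < 1:
            raise ConfigError(f"n_trials must be positive, got {self.n_trials}")
        if self.n_ports != 3:
            raise ConfigError(
                f"the line-up has exactly 3 ports, got n_ports={self.n_ports}"
            )
        if not self.distractor_channels:
            raise ConfigError("distractor_channels must be non-empty")
        if self.target_channel in self.distractor_channels:
            raise ConfigError(
                f"target channel {self.target_channel!r} must be disjoint "
                "from distractor channels"
            )
        if not 0.0 <= self.blank_rate <= 1.0:
            raise ConfigError(f"blank_rate must lie in [0, 1], got {self.blank_rate}")
        if self.blank_block_size < 1:
            raise ConfigError("blank_block_size must be a positive integer")
        per_block = self.blank_rate * self.blank_block_size
        if abs(per_block - round(per_block)) > 1e-9:
            raise ConfigError(
                f"blank_rate {self.blank_rate} x block size {self.blank_block_size} "
                f"= {per_block} blanks per block is not an integer"
            )
        if self.hold_criterion_s <= 0:
            raise ConfigError("hold_criterion_s must be positive")
        if self.timeout_s is not None and self.hold_criterion_s > self.timeout_s:
            raise ConfigError(
                "hold_criterion_s must not exceed timeout_s when a timeout is set"
            )
        if self.all_clear_window_s <= 0:
            raise ConfigError("all_clear_window_s must be positive")
        if self.odor_flow_lpm < 0 or self.clean_flow_lpm < 0:
            raise ConfigError("flows must be non-negative")
        if self.odor_flow_lpm + self.clean_flow_lpm <= 0:
            raise ConfigError("total airflow must be positive")
        if self.debounce_gap_ms < 0:
            raise ConfigError("debounce_gap_ms must be non-negative")

    @property
    def effective_timeout_s(self) -> float | None:
        """Search time limit in force for this session's phase, or None."""
        if self.timeout_s is None:
            return None
        if self.phase is Phase.P3_BLANKS or self.timeout_all_phases:
            return self.timeout_s
        return None

    @property
    def dilution(self) -> float:
        """Fraction of total port airflow carried by the odor line."""
        return dilution_fraction(self.odor_flow_lpm, self.clean_flow_lpm)

    def replace(self, **changes) -> "SessionConfig":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial.

    ``channel_by_port`` is a tuple of channel ids indexed by 0-based port.
    On a blank trial ``target_port`` is None and every port carries a
    distractor (odor load at the ports stays constant across trial types).
    """

    index: int
    is_blank: bool
    target_port: int | None
    channel_by_port: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_by_port", tuple(self.channel_by_port))
        if self.is_blank != (self.target_port is None):
            raise ValueError("is_blank must hold exactly when target_port is None")
        if self.target_port is not None and not (
            0 <= self.target_port < len(self.channel_by_port)
        ):
            raise ValueError(f"target_port {self.target_port} out of range")


def dilution_fraction(odor_flow_lpm: float, clean_flow_lpm: float) -> float:
    """Fraction of the total port airflow contributed by the odor line.

    With the standard 1 LPM odor line merged into a 2 LPM continuous clean
    line this is 1/3: a 33% air dilution of the jar headspace.
    """
    if odor_flow_lpm < 0 or clean_flow_lpm < 0:
        raise ValueError("flows must be non-negative")
    total = odor_flow_lpm + clean_flow_lpm
    if total == 0:
        raise ValueError("total airflow is zero; dilution undefined")
    return odor_flow_lpm / total


def counterbalance_ports(
    n_target_trials: int, n_ports: int, rng: np.random.Generator
) -> list[int]:
    """Counterbalanced, shuffled target-port assignment.

    Builds the most balanced multiset of port ids (per-port counts differ
    by at most one; which ports receive the remainder is randomized), then
    shuffles it.  Deterministic balance, no rejection sampling.
    """
    if n_ports < 1:
        raise ValueError(f"n_ports must be >= 1, got {n_ports}")
    if n_target_trials < 0:
        raise ValueError("n_target_trials must be non-negative")
    base, rem = divmod(n_target_trials, n_ports)
    counts = np.full(n_ports, base, dtype=int)
    if rem:
        counts[rng.choice(n_ports, size=rem, replace=False)] += 1
    seq = np.repeat(np.arange(n_ports), counts)
    rng.shuffle(seq)
    return [int(p) for p in seq]


def place_blanks(
    n_trials: int,
    blank_rate: float,
    block_size: int,
    rng: np.random.Generator,
) -> set[int]:
    """Choose blank-trial indices, a fixed number inside each block.

    Each consecutive block of ``block_size`` trials receives exactly
    ``blank_rate * block_size`` blanks at random positions within the block
    (a trailing partial block receives the rounded pro-rata count).
    """
    if not 0.0 <= blank_rate <= 1.0:
        raise ConfigError(f"blank_rate must lie in [0, 1], got {blank_rate}")
    if block_size < 1:
        raise ConfigError("block_size must be a positive integer")
    per_block = blank_rate * block_size
    if abs(per_block - round(per_block)) > 1e-9:
        raise ConfigError(
            f"blank_rate {blank_rate} x block size {block_size} is not an "
            "integral per-block blank count"
        )
    per_block = int(round(per_block))
    blanks: set[int] = set()
    for start in range(0, n_trials, block_size):
        size = min(block_size, n_trials - start)
        k = per_block if size == block_size else int(round(blank_rate * size))
        if k > size:
            raise ConfigError("more blanks than trials in a block")
        if k:
            picks = rng.choice(size, size=k, replace=False)
            blanks.update(start + int(i) for i in picks)
    return blanks


def generate_session_plan(
    config: SessionConfig, rng: np.random.Generator | None = None
) -> list[TrialSpec]:
    """Generate the full randomized, counterbalanced plan for one session.

    Randomization follows the live program's three questions per trial:
    (1) is the trial blank, (2) if not, which port carries the target
    (counterbalanced), and (3) which distractor each non-target
    olfactometer draws (independent uniform draws).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    blanks = place_blanks(
        config.n_trials, config.blank_rate, config.blank_block_size, rng
    )
    n_target = config.n_trials - len(blanks)
    port_seq = counterbalance_ports(n_target, config.n_ports, rng)
    distractors = config.distractor_channels

    plan: list[TrialSpec] = []
    target_i = 0
    for i in range(config.n_trials):
        if i in blanks:
            target_port = None
        else:
            target_port = port_seq[target_i]
            target_i += 1
        channels = []
        for port in range(config.n_ports):
            if port == target_port:
                channels.append(config.target_channel)
            else:
                channels.append(str(rng.choice(distractors)))
        plan.append(
            TrialSpec(
                index=i,
                is_blank=target_port is None,
                target_port=target_port,
                channel_by_port=tuple(channels),
            )
        )
    return plan


# ---------------------------------------------------------------------------
# Plan CSV export/import.  Ports are rendered 1-based in files, as on the
# operator interface; blank trials leave target_port empty.

_PLAN_COLUMNS = (
    "trial_index",
    "is_blank",
    "target_port",
    "channel_port1",
    "channel_port2",
    "channel_port3",
)


def write_plan_csv(plan: Sequence[TrialSpec], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PLAN_COLUMNS)
        for spec in plan:
            writer.writerow(
                [
                    spec.index,
                    int(spec.is_blank),
                    "" if spec.target_port is None else spec.target_port + 1,
                    *spec.channel_by_port,
                ]
            )
    return path


def read_plan_csv(path: str | Path) -> list[TrialSpec]:
    path = Path(path)
    plan: list[TrialSpec] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_PLAN_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ConfigError(f"plan file missing columns: {sorted(missing)}")
        for row in reader:
            target = row["target_port"]
            plan.append(
                TrialSpec(
                    index=int(row["trial_index"]),
                    is_blank=bool(int(row["is_blank"])),
                    target_port=None if target == "" else int(target) - 1,
                    channel_by_port=(
                        row["channel_port1"],
                        row["channel_port2"],
                        row["channel_port3"],
                    ),
                )
            )
    return plan
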