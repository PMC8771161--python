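"""Session data files and run configuration.

Each session produces one RFC-4180 CSV named ``<dog>_<ISO8601>.csv`` with
one row per completed trial: the odors presented in each port, the trial
start time, the latency to first nose entry, per-port entry counts and
sniff durations, the full poke list, the classified response, and whether
the trial was rewarded.  Session-level metadata (dog, session start, seed,
phase, schema version) is repeated on every row so a file is
self-describing and round-trips without a sidecar.

The poke list is serialized as semicolon-separated ``port:start_ms:dur_ms``
triplets with 1-based ports.  Unknown columns are preserved on read as
opaque extras, and a ``schema_version`` column supports forward
compatibility.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Sequence

import yaml

from .hardware_sim import AgentParams
from .scheduler import ConfigError, Phase, SessionConfig, TrialSpec
from .trial_engine import Poke, Response, TrialResult

__all__ = [
    "SCHEMA_VERSION",
    "SessionMetadata",
    "TrialRow",
    "SessionRecord",
    "SchemaError",
    "session_filename",
    "write_session_csv",
    "read_session_csv",
    "load_config",
]

SCHEMA_VERSION = "1"

_MANDATORY_COLUMNS = (
    "schema_version",
    "dog",
    "session_start",
    "seed",
    "phase",
    "trial_index",
    "trial_start_s",
    "is_blank",
    "odor_port1",
    "odor_port2",
    "odor_port3",
    "target_port",
    "response",
    "rewarded",
    "latency_ms",
    "entries_port1",
    "entries_port2",
    "entries_port3",
    "sniff_ms_port1",
    "sniff_ms_port2",
    "sniff_ms_port3",
    "pokes",
)


class SchemaError(ValueError):
    """Raised when a session file does not match the expected schema."""


@dataclass(frozen=True)
class SessionMetadata:
    dog: str
    session_start: dt.datetime
    seed: int
    phase: Phase

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", Phase(self.phase))


@dataclass(frozen=True)
class TrialRow:
    """One parsed trial row of a session file."""

    trial_index: int
    trial_start_s: float
    is_blank: bool
    odors_by_port: tuple[str, str, str]
    target_port: int | None
    response: Response
    rewarded: bool
    latency_ms: int | None
    entries_by_port: tuple[int, int, int]
    sniff_ms_by_port: tuple[int, int, int]
    pokes: tuple[Poke, ...]
    extras: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class SessionRecord:
    #: None for a header-only file (session started but no trial completed)
    metadata: SessionMetadata | None
    trials: tuple[TrialRow, ...]


def session_filename(dog: str, session_start: dt.datetime) -> str:
    """``<dog>_<ISO8601>.csv`` with filesystem-safe time separators."""
    stamp = session_start.strftime("%Y-%m-%dT%H%M%S")
    return f"{dog}_{stamp}.csv"


def _encode_pokes(pokes: Sequence[Poke]) -> str:
    return ";".join(f"{p.port + 1}:{p.start_ms}:{p.duration_ms}" for p in pokes)


def _decode_pokes(text: str) -> tuple[Poke, ...]:
    if not text:
        return ()
    out = []
    for triplet in text.split(";"):
        port, start, dur = triplet.split(":")
        out.append(Poke(port=int(port) - 1, start_ms=int(start), duration_ms=int(dur)))
    return tuple(out)


def _trial_starts(results: Sequence[TrialResult], iti_fan_s: float) -> list[float]:
    """Session-clock start offset of each trial (s from session start).

    Consecutive trials are separated by the previous trial's duration plus
    the inter-trial fan period.
    """
    starts, t = [], 0.0
    for res in results:
        starts.append(round(t, 3))
        t += res.end_ms / 1000.0 + iti_fan_s
    return starts


def write_session_csv(
    plan: Sequence[TrialSpec],
    results: Sequence[TrialResult],
    metadata: SessionMetadata,
    path: str | Path | None = None,
    out_dir: str | Path = ".",
    iti_fan_s: float = 15.0,
) -> Path:
    """Write one session to CSV; returns the file path.

    When ``path`` is omitted the file is named ``<dog>_<ISO8601>.csv``
    inside ``out_dir``.
    """
    if len(plan) != len(results):
        raise ValueError("plan and results must have the same length")
    if path is None:
        path = Path(out_dir) / session_filename(metadata.dog, metadata.session_start)
    path = Path(path)
    starts = _trial_starts(results, iti_fan_s)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANDATORY_COLUMNS)
        for spec, res, start in zip(plan, results, starts):
            writer.writerow(
                [
                    SCHEMA_VERSION,
                    metadata.dog,
                    metadata.session_start.isoformat(),
                    metadata.seed,
                    metadata.phase.value,
                    spec.index,
                    start,
                    int(spec.is_blank),
                    *spec.channel_by_port,
                    "" if spec.target_port is None else spec.target_port + 1,
                    res.response.value,
                    int(res.rewarded),
                    "" if res.latency_ms is None else res.latency_ms,
                    *res.entries_by_port,
                    *res.sniff_ms_by_port,
                    _encode_pokes(res.pokes),
                ]
            )
    return path


def read_session_csv(path: str | Path) -> SessionRecord:
    """Parse a session file into typed records.

    Missing mandatory columns raise :class:`SchemaError` naming the
    column; truncated rows raise with the offending row number.  Unknown
    columns are carried along as opaque extras.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or ()
        for col in _MANDATORY_COLUMNS:
            if col not in header:
                raise SchemaError(f"session file missing mandatory column {col!r}")
        extra_cols = [c for c in header if c not in _MANDATORY_COLUMNS]
        metadata: SessionMetadata | None = None
        trials: list[TrialRow] = []
        for line_no, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in _MANDATORY_COLUMNS):
                raise SchemaError(f"truncated row at line {line_no} of {path.name}")
            try:
                if metadata is None:
                    metadata = SessionMetadata(
                        dog=row["dog"],
                        session_start=dt.datetime.fromisoformat(row["session_start"]),
                        seed=int(row["seed"]),
                        phase=Phase(row["phase"]),
                    )
                target = row["target_port"]
                latency = row["latency_ms"]
                trials.append(
                    TrialRow(
                        trial_index=int(row["trial_index"]),
                        trial_start_s=float(row["trial_start_s"]),
                        is_blank=bool(int(row["is_blank"])),
                        odors_by_port=(
                            row["odor_port1"],
                            row["odor_port2"],
                            row["odor_port3"],
                        ),
                        target_port=None if target == "" else int(target) - 1,
                        response=Response(row["response"]),
                        rewarded=bool(int(row["rewarded"])),
                        latency_ms=None if latency == "" else int(latency),
                        entries_by_port=tuple(
                            int(row[f"entries_port{i}"]) for i in (1, 2, 3)
                        ),
                        sniff_ms_by_port=tuple(
                            int(row[f"sniff_ms_port{i}"]) for i in (1, 2, 3)
                        ),
                        pokes=_decode_pokes(row["pokes"]),
                        extras=tuple((c, row[c]) for c in extra_cols),
                    )
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, SchemaError):
                    raise
                raise SchemaError(
                    f"unparseable row at line {line_no} of {path.name}: {exc}"
                ) from exc
    return SessionRecord(metadata=metadata, trials=tuple(trials))


# ---------------------------------------------------------------------------
# Config files


_SESSION_KEYS = {f.name for f in dc_fields(SessionConfig)}
_AGENT_KEYS = {f.name for f in dc_fields(AgentParams)}


def load_config(path: str | Path) -> tuple[SessionConfig, AgentParams]:
    """Load a YAML run configuration.

    The file holds optional ``session:`` and ``agent:`` mappings; any
    omitted key takes its documented default, so a minimal file need only
    set a seed.  A bare top-level ``seed`` is accepted as shorthand.
    Invariant violations surface as :class:`ConfigError`.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path.name} must be a mapping")

    session_raw = dict(raw.get("session") or {})
    agent_raw = dict(raw.get("agent") or {})
    if "seed" in raw:
        session_raw.setdefault("seed", raw["seed"])
    unknown = set(raw) - {"session", "agent", "seed"}
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    unknown = set(session_raw) - _SESSION_KEYS
    if unknown:
        raise ConfigError(f"unknown session config keys: {sorted(unknown)}")
    unknown = set(agent_raw) - _AGENT_KEYS
    if unknown:
        raise ConfigError(f"unknown agent config keys: {sorted(unknown)}")

    try:
        config = SessionConfig(**session_raw)
        agent = AgentParams(**agent_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return config, agent
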