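"""Photoionization-detector trace analysis for odor-delivery validation.

The delivery/clearance check parks a fast PID sensor in an odor port and
cycles the odor valve 30 s on / 30 s off, forty times, sampling the PID
voltage and a valve-state (stimulation) channel at 30 Hz.  This module
provides the full analysis chain for such records:

* a synthetic trace generator (first-order exponential odor
  onset/decay, white sensor noise, linear baseline drift, and an
  optional dropped-packet gap emulating DAQ data loss);
* zero-phase low-pass Butterworth filtering with the cutoff given as a
  fraction of the Nyquist frequency;
* stimulation-epoch extraction;
* per-cycle additive drift correction that re-references every cycle's
  pre-onset baseline to the first cycle's; and
* per-epoch metrics: baseline and plateau means, rise latency (time to
  90% of plateau) and clearance latency (time back to within 10% of
  baseline above baseline).

Dropped-packet gaps are detectable as sample spacings above twice the
nominal period; gap samples are simply absent and are never interpolated.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "PIDTrace",
    "EpochSummary",
    "synth_pid_trace",
    "lowpass",
    "extract_epochs",
    "drift_correct",
    "epoch_metrics",
    "find_gaps",
    "write_pid_csv",
    "read_pid_csv",
]


@dataclass(frozen=True)
class PIDTrace:
    """A PID record: sample times (s), voltages, and the binary valve state."""

    t_s: np.ndarray
    voltage: np.ndarray
    stim: np.ndarray
    fs: float = 30.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        v = np.asarray(self.voltage, dtype=float)
        s = np.asarray(self.stim, dtype=int)
        if not (len(t) == len(v) == len(s)):
            raise ValueError("t_s, voltage and stim must have equal lengths")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("t_s must be strictly increasing")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "voltage", v)
        object.__setattr__(self, "stim", s)

    def __len__(self) -> int:
        return len(self.t_s)


@dataclass(frozen=True)
class EpochSummary:
    """Per-cycle delivery metrics; NaN latency marks an undefined metric."""

    onset_t: float
    offset_t: float
    baseline_mean: float
    plateau_mean: float
    rise_latency_s: float
    clearance_latency_s: float


def synth_pid_trace(
    n_cycles: int = 40,
    on_s: float = 30.0,
    off_s: float = 30.0,
    fs: float = 30.0,
    rise_tau_s: float = 0.5,
    noise_sd: float = 0.0,
    drift_slope: float = 0.0,
    dropped_gap: tuple[float, float] | None = None,
    baseline_v: float = 0.05,
    amplitude_v: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PIDTrace:
    """Generate a synthetic PID validation trace.

    Each cycle is an off-period followed by an on-period (so every onset
    has a full pre-onset baseline window).  The voltage follows a
    first-order exponential approach toward ``baseline + amplitude*stim``
    with time constant ``rise_tau_s`` (``<= 0`` gives an ideal square
    wave), plus linear drift ``drift_slope`` (V/s) and Gaussian noise.
    ``dropped_gap=(start_s, duration_s)`` deletes the samples inside that
    interval, emulating a lost DAQ packet.
    """
    if n_cycles < 1 or on_s <= 0 or off_s <= 0 or fs <= 0:
        raise ValueError("n_cycles, on_s, off_s and fs must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    dt = 1.0 / fs
    n_off = int(round(off_s * fs))
    n_on = int(round(on_s * fs))
    stim_cycle = np.r_[np.zeros(n_off, dtype=int), np.ones(n_on, dtype=int)]
    stim = np.tile(stim_cycle, n_cycles)
    n = len(stim)
    t = np.arange(n) * dt

    target = baseline_v + amplitude_v * stim.astype(float)
    if rise_tau_s > 0:
        alpha = math.exp(-dt / rise_tau_s)
        # v[i] = target[i] + (v[i-1] - target[i]) * alpha, v[-1] = baseline
        v = sp_signal.lfilter([1 - alpha], [1, -alpha], target, zi=[baseline_v * alpha])[0]
    else:
        v = target.copy()
    v = v + drift_slope * t
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)

    if dropped_gap is not None:
        gap_start, gap_dur = dropped_gap
        keep = ~((t >= gap_start) & (t < gap_start + gap_dur))
        t, v, stim = t[keep], v[keep], stim[keep]

    return PIDTrace(t_s=t, voltage=v, stim=stim, fs=fs)


def find_gaps(trace: PIDTrace) -> list[int]:
    """Indices i where the spacing t[i+1]-t[i] exceeds twice the nominal
    sample period (dropped packets)."""
    dt = np.diff(trace.t_s)
    return [int(i) for i in np.flatnonzero(dt > 2.0 / trace.fs)]


def lowpass(trace: PIDTrace, cutoff_scalar: float = 0.05, order: int = 2) -> PIDTrace:
    """Zero-phase low-pass Butterworth filter of the voltage channel.

    ``cutoff_scalar`` is the cutoff as a fraction of the Nyquist
    frequency (fs/2).  The filter is order-2 and applied
    forward-backward (filtfilt), so the output has no phase lag and the
    same length as the input.
    """
    if not 0.0 < cutoff_scalar < 1.0:
        raise ValueError(f"cutoff_scalar must lie in (0, 1), got {cutoff_scalar}")
    b, a = sp_signal.butter(order, cutoff_scalar)
    padlen = 3 * max(len(a), len(b))
    if len(trace) <= padlen:
        raise ValueError(
            f"trace of {len(trace)} samples is shorter than the filter "
            f"warm-up ({padlen} samples)"
        )
    filtered = sp_signal.filtfilt(b, a, trace.voltage)
    return replace(trace, voltage=filtered)


def extract_epochs(stim: np.ndarray | PIDTrace) -> list[tuple[int, int]]:
    """(onset, offset) sample-index pairs, one per contiguous stim-on run.

    ``offset`` is exclusive (the first off sample after the run).  When a
    full :class:`PIDTrace` is passed, a dropped-packet time gap also
    terminates a run, so the epoch count survives a gap anywhere inside
    an off-period — even one that swallowed the off-period entirely and
    left two on-runs adjacent in the sample array.  A bare stim array is
    segmented purely sample-wise.
    """
    if isinstance(stim, PIDTrace):
        gap_breaks = sorted(find_gaps(stim))
        stim = stim.stim
    else:
        gap_breaks = []
    stim = np.asarray(stim).astype(int)
    edges = np.flatnonzero(np.diff(np.r_[0, stim, 0]))
    epochs: list[tuple[int, int]] = []
    for a, b in zip(edges[::2], edges[1::2]):
        start = int(a)
        for g in gap_breaks:
            if start <= g < b - 1:  # gap strictly inside the on-run
                epochs.append((start, int(g + 1)))
                start = int(g + 1)
        epochs.append((start, int(b)))
    return epochs


def _baseline_slice(
    trace: PIDTrace, onset_idx: int, window_s: float
) -> np.ndarray:
    """Indices of the pre-onset baseline window (samples within
    ``window_s`` before the onset time), falling back to the nearest
    available pre-onset samples when a gap emptied the window."""
    t_onset = trace.t_s[onset_idx]
    mask = (trace.t_s >= t_onset - window_s) & (trace.t_s < t_onset)
    idx = np.flatnonzero(mask)
    if idx.size == 0 and onset_idx > 0:
        warnings.warn(
            f"empty baseline window before onset at t={t_onset:.2f}s "
            "(dropped packets); using nearest pre-onset samples",
            stacklevel=3,
        )
        n_fallback = max(1, int(round(window_s * trace.fs)) // 4)
        idx = np.arange(max(0, onset_idx - n_fallback), onset_idx)
    return idx


def drift_correct(
    trace: PIDTrace,
    epochs: Sequence[tuple[int, int]],
    baseline_window_s: float = 30.0,
) -> PIDTrace:
    """Per-cycle additive baseline re-referencing.

    For every cycle, the mean voltage of the window before odor onset is
    the cycle's baseline; the correction adds, uniformly to that cycle's
    off and on samples, the offset that makes its baseline equal the
    first cycle's.  A single-epoch trace is returned unchanged (its
    offset is zero by construction).
    """
    if not epochs:
        return trace
    v = trace.voltage.copy()
    baselines = []
    for onset, _ in epochs:
        idx = _baseline_slice(trace, onset, baseline_window_s)
        baselines.append(float(np.mean(trace.voltage[idx])) if idx.size else math.nan)
    ref = baselines[0]
    for i, (onset, offset) in enumerate(epochs):
        start = epochs[i - 1][1] if i > 0 else 0
        stop = offset if i < len(epochs) - 1 else len(v)
        if not math.isnan(baselines[i]):
            v[start:stop] += ref - baselines[i]
    return replace(trace, voltage=v)


def epoch_metrics(
    trace: PIDTrace,
    epochs: Sequence[tuple[int, int]],
    baseline_window_s: float = 30.0,
    plateau_fraction: float = 0.5,
    rise_level: float = 0.9,
    clearance_level: float = 0.1,
) -> list[EpochSummary]:
    """Per-epoch baseline, plateau, and rise/clearance latencies.

    The plateau is the mean over the last ``plateau_fraction`` of the
    on-period.  Rise latency is the time from onset until the voltage
    first reaches ``rise_level`` of the plateau-above-baseline step;
    clearance latency is the time from offset until it first falls back
    within ``clearance_level`` of that step above baseline.  Epochs too
    short to define a plateau get NaN metrics.
    """
    v, t = trace.voltage, trace.t_s
    out: list[EpochSummary] = []
    for i, (onset, offset) in enumerate(epochs):
        idx = _baseline_slice(trace, onset, baseline_window_s)
        baseline = float(np.mean(v[idx])) if idx.size else math.nan
        n_on = offset - onset
        if n_on < 2 or math.isnan(baseline):
            out.append(
                EpochSummary(
                    onset_t=float(t[onset]),
                    offset_t=float(t[min(offset, len(t) - 1)]),
                    baseline_mean=baseline,
                    plateau_mean=math.nan,
                    rise_latency_s=math.nan,
                    clearance_latency_s=math.nan,
                )
            )
            continue
        plateau_start = offset - max(1, int(round(n_on * plateau_fraction)))
        plateau = float(np.mean(v[plateau_start:offset]))
        step = plateau - baseline

        rise_thresh = baseline + rise_level * step
        on_v = v[onset:offset]
        above = np.flatnonzero(on_v >= rise_thresh)
        rise = float(t[onset + above[0]] - t[onset]) if above.size else math.nan

        clear_thresh = baseline + clearance_level * step
        next_onset = epochs[i + 1][0] if i < len(epochs) - 1 else len(v)
        off_v = v[offset:next_onset]
        if off_v.size:
            below = np.flatnonzero(off_v <= clear_thresh)
            clearance = (
                float(t[offset + below[0]] - t[offset]) if below.size else math.nan
            )
            offset_t = float(t[offset])
        else:
            clearance, offset_t = math.nan, float(t[-1])
        out.append(
            EpochSummary(
                onset_t=float(t[onset]),
                offset_t=offset_t,
                baseline_mean=baseline,
                plateau_mean=plateau,
                rise_latency_s=rise,
                clearance_latency_s=clearance,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Trace CSV I/O


def write_pid_csv(trace: PIDTrace, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_s", "voltage", "stim"])
        for t, v, s in zip(trace.t_s, trace.voltage, trace.stim):
            writer.writerow([f"{t:.6f}", f"{v:.8f}", int(s)])
    return path


def read_pid_csv(path: str | Path, fs: float = 30.0) -> PIDTrace:
    path = Path(path)
    t, v, s = [], [], []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = {"t_s", "voltage", "stim"} - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"PID file missing columns: {sorted(missing)}")
        for row in reader:
            t.append(float(row["t_s"]))
            v.append(float(row["voltage"]))
            s.append(int(row["stim"]))
    return PIDTrace(t_s=np.array(t), voltage=np.array(v), stim=np.array(s), fs=fs)
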