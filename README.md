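# lineup

An automated three-port olfactometer "line-up" controller for detection-dog
research, re-built as a hardware-agnostic Python package with a fully
simulated backend.

In a line-up task a dog searches a row of sampling ports for a target
odorant (here, double-base smokeless powder) among distractors, and
reports a find with an **alert** — a sustained nose hold in a port,
measured by an infrared beam at the port entrance.  Computer-driven
randomization of which port carries the target makes every trial
double-blind.  This package implements everything the control computer
does, for researchers who want to run, simulate, or re-analyze such
experiments:

* **scheduler** — randomized, counterbalanced session plans: over a
  session the target appears in each of the 3 ports a near-equal number
  of times (e.g. 13–14 times each in 40 trials), blank (target-absent)
  trials are placed at a fixed per-block rate (one per block of 10 at
  10%), and each non-target olfactometer draws its distractor
  independently and uniformly;
* **trial_engine** — a per-trial state machine over beam events:
  debounced poke merging, inclusive hold-criterion detection
  (alert fires at `poke_start + criterion`), and the five-way response
  taxonomy `CORRECT_ALERT / FALSE_ALERT / ALL_CLEAR_CORRECT / MISS /
  TIMEOUT` with phase-dependent consequences;
* **hardware_sim** — the hardware command contract (valves, panel, fans,
  feeder, beep) plus a parameterized virtual dog (`p_detect`,
  `p_false_alert`, latency/sniff distributions, visit policy) that closes
  the loop, including the odor-unplugged control test;
* **session_io** — session CSVs (one row per trial: odors by port,
  latency to first entry, per-port entries and sniff times, full poke
  list, response, reward) and YAML run configuration;
* **training_analysis** — session/daily performance summaries and the
  shaping rules that step the nose-hold criterion from 0.25 s to 4 s and
  advance training phases P1 → P2 → P3;
* **pid_signal** — photoionization-detector trace analysis for
  odor-delivery validation: synthetic trace generation, zero-phase
  low-pass Butterworth filtering (cutoff 0.05 × Nyquist), per-cycle
  baseline drift correction, stimulation-epoch extraction, and
  rise/clearance latency metrics.

## Worked example

Simulate one phase-3 session (40 trials, 4-s hold, 45-s search limit,
10% blanks) with the default virtual dog and summarize it:

```text
$ lineup simulate --seed 7 --dog Buster --out demo
session written to demo/Buster_2026-09-20T175429.csv
40 trials: 97.5% correct, 2.5% false alerts, 0.0% misses, 0.0% timeouts
```

The default agent detects the target with probability 0.95 and false
alerts at 0.02 per distractor port, so a 40-trial session typically lands
in the mid-90s percent correct — 39/40 here, with the 4 blank trials
scored as correct all-clears.  Each CSV row records one trial, e.g.

```text
1,Buster,...,7,P3_BLANKS,1,33.436,0,glove,smokeless_powder,limonene,2,CORRECT_ALERT,1,8616,1,1,0,101,0,0,1:8616:101;2:9424:4500
```

trial 1 carried the target in port 2; the dog first poked port 1 at
8.616 s (latency), sniffed it for 101 ms, then held port 2 for 4.5 s —
a rewarded correct alert.  The poke list (`port:start_ms:duration_ms`)
preserves every entry.

Validate odor delivery with the synthetic PID protocol (valve 30 s on /
30 s off, repeated 40 times, sampled at 30 Hz):

```text
$ lineup pid --cycles 40 --on 30 --off 30 --seed 1
40 epochs; mean rise latency 1.11 s; mean clearance latency 1.05 s
```

All 40 stimulation epochs are recovered; with the default first-order
sensor time constant of 0.5 s the signal reaches 90% of plateau ~1.1 s
after valve opening (τ·ln 10 ≈ 1.15 s) and clears equally fast — odor is
present essentially only while the valve is open.

The same machinery is available as a library:

```python
from lineup import SessionConfig, AgentParams, run_simulated_session, session_summary

config = SessionConfig(seed=7)
plan, results = run_simulated_session(AgentParams(), config)
print(session_summary(results).proportion_correct)   # 0.975
```

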