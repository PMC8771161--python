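# Methods

## The task and what the software controls

Three olfactometers each feed one sampling port.  Per trial, one port
delivers the target odorant (double-base smokeless powder in the
reference protocol) and the others deliver distractors drawn from a
five-item pool (empty vial, cotton gauze, latex glove, mineral oil, and
limonene diluted 10⁻³ v/v in mineral oil); on a blank trial no port
carries the target.  The odor line runs at 1 LPM into a 2 LPM continuous
clean line, a 33% air dilution (`dilution_fraction = odor/(odor+clean)`).
A motorized panel exposes the ports at trial start; IR beams at the port
entrances are the only behavioral sensor.  The dog's alert is a
continuous nose hold of at least the criterion duration (4 s when fully
trained).

## Scheduling

Randomization answers three questions per trial: blank or not, which
port carries the target, and which distractor each non-target
olfactometer presents.

* **Counterbalancing** builds the most-balanced multiset of port ids
  (per-port counts differ by ≤ 1; remainder ports chosen at random) and
  shuffles it — deterministic balance rather than rejection sampling.
  Over 40 target trials each port hosts the target 13–14 times.
* **Blank placement** puts exactly `blank_rate × block_size` blanks at
  random positions inside each consecutive block (one per block of 10 at
  the standard 10%).  Non-integral per-block counts are a configuration
  error.
* **Distractors** are drawn independently and uniformly per olfactometer
  per trial, so two ports may present the same distractor — as on the
  physical apparatus.
* On blank trials all three ports deliver distractors (rather than clean
  air), keeping total odor load constant across trial types; the
  protocol leaves this open and either choice only affects channel
  bookkeeping.

One seeded `numpy` generator drives the whole session (plan and virtual
dog), so a session is a pure function of its configuration.  Ports are
0-based internally and rendered 1-based in CSVs and the CLI.

## Trial classification

All times are integer milliseconds from panel raise, avoiding float
ambiguity at the criterion boundary; the criterion is inclusive
(hold ≥ criterion) and the alert fires at the instant it is reached
(`poke_start + criterion`), as the live feeder would, not at poke end.

* **Debouncing.** Same-port pokes separated by < 100 ms (default) merge
  into one poke spanning the gap; IR sensors flicker.  Criterion holds
  never accumulate across distinct pokes — a single continuous (merged)
  hold is required, matching a physical hold sensor.
* **Consequences by phase.** P1: a false alert is logged but the trial
  continues until a correct hold or stream end; no beep/feeder commands
  are issued for it (handler-mediated reinforcement is out of scope, so
  `rewarded` strictly implies a correct alert).  P2/P3: a false alert
  terminates the trial unrewarded.
* **All-clear.** The clock arms once all three ports have ≥ 1 poke, is
  anchored to the most recent RESTORE that left every beam clear, and
  restarts on any BREAK; it fires after 4 s of silence.  Anchoring to
  port *exit* (rather than entry into the last port) is a deliberate
  reading of an ambiguous rule — it guarantees the window measures
  genuine withholding.  On blanks this scores `ALL_CLEAR_CORRECT`
  (advancing to the next trial is the only reinforcer); on target trials
  it is a `MISS`.
* **Timeout.** If the 45-s limit elapses before all three ports have
  been entered, `TIMEOUT` is scored.  An entry at exactly the limit
  counts as within it.  The limit is enforced in phase 3 by default
  (`timeout_all_phases` extends it), since earlier phases had no
  specified termination time.  A stream that simply ends with no
  terminating condition (operator abort) is also scored `TIMEOUT`,
  keeping the taxonomy total.
* **Tie-breaking** at a single instant: alert > all-clear > timeout.
* **Measures.** Latency = first poke start; entries = merged pokes per
  port; cumulative sniff time = total poke duration minus the entire
  alert-triggering poke.  Pokes beginning after trial end are dropped
  with a warning; the alert poke's overshoot past trial end is kept.

## The virtual dog

The agent is event-level, not kinematic — the engine only ever sees beam
events.  Per trial it samples a search-onset latency, visits ports
left-to-right or in random shuffled order, and at each port produces
either an alert hold (criterion + overshoot) or a sub-criterion sniff,
then stops after an alert or falls silent after the last port.  The
alert decision is Bernoulli: `p_detect` at the target port when odor is
actually delivered, `p_false_alert` elsewhere.  The odor-unplugged
control test sets `odor_connected=False`, which demotes the target port
to a non-target — the agent loses access to target identity exactly as
the physical disconnection removes the odor cue.

Defaults emulate a fully trained dog at the end of phase 3: `p_detect`
0.95, `p_false_alert` 0.02, latency ~N(11 s, 3 s) (trained dogs pace
themselves before searching), sniffs ~N(0.4 s, 0.15 s) per port, transit
~N(0.8 s, 0.2 s), 0.5-s hold overshoot.  Normal draws are truncated to
stay positive and sniffs are capped safely below the criterion so
non-alert pokes never trigger by accident.

What the simulator deliberately does not reproduce: learning within or
across sessions, port revisits and perseveration (real dogs early in
training make > 4 entries per trial; the agent makes ≤ 3), odor-plume
physics, and handler interventions.  Passing tests therefore demonstrate
the correctness of scheduling, scoring, logging and analysis — not that
real dogs behave like the agent.

A useful special case: `uniform_random_alert_agent()` (alert always, at
the first port of a random visit order) alerts exactly once per trial at
a uniformly random port, so its long-run target-trial accuracy is the
line-up's 1/3 chance level; the acceptance script measures this
empirically over 10,000 trials.

## Training progression

Performance is the proportion of correct responses (target alerts plus
blank-trial all-clears); two sessions in one day average, unweighted,
into a daily value.  The criterion comparison "85%" is `>= 0.85` after
rounding to 4 decimals.  Rules, applied one session (or day) at a time:

1. shaping with the food odor: +0.5 s per session with independent IR
   use, from 0.25 s to 2 s (the first step goes 0.25 → 0.5 s so the
   criterion stays on the 0.25/0.5-s grid; a literal +0.5 from 0.25
   would visit off-grid values);
2. ≥ 85% daily at the 2-s food criterion switches the target to the main
   odor with the criterion dropped to 1 s for the single assisted
   transition session, after which it returns to 2 s (the only permitted
   criterion decrease);
3. with the main odor, the first step off 2 s requires two consecutive
   ≥ 85% sessions; each later 0.5-s step to 4 s requires one;
4. ≥ 85% at 4 s graduates phase 1 (a `skip_phase2` flag reproduces the
   cohort that went straight to phase 3); phases 2 and 3 each require
   two consecutive ≥ 85% sessions;
5. any sub-criterion session resets the consecutive counter and changes
   nothing else — regressions to easier training are operator commands,
   never automatic.

Under these rules a perfect performer needs 15 sessions to finish (13
when phase 2 is skipped); the test suite traces this by hand.  No
hypothesis testing is provided: the metrics are descriptive.

## PID signal analysis

The validation protocol parks a fast PID in a port and cycles the valve
30 s on / 30 s off, 40 times, sampling voltage and valve state at 30 Hz
(72,000 samples).  The synthetic generator emits each cycle as
off-then-on so every onset owns a full 30-s pre-onset baseline window;
the voltage is a first-order exponential response (default τ = 0.5 s;
τ = 0 gives an ideal square wave) plus linear baseline drift and white
noise, with an optional deleted interval emulating a dropped DAQ packet.

* **Filtering**: order-2 Butterworth at 0.05 × Nyquist, applied
  forward-backward (`filtfilt`) for zero phase.  The cutoff is the
  protocol-specified parameter; order and phase handling are standard
  choices the protocol leaves open.
* **Epoch extraction**: contiguous stim-on runs; when the full trace is
  supplied, a dropped-packet gap (sample spacing > 2/fs) also terminates
  a run, so the epoch count survives a gap anywhere in an off-period —
  including one that swallowed the off-period entirely.  A gap inside an
  on-period splits that epoch; gaps are reported by `find_gaps` and
  never interpolated.
* **Drift correction**: per cycle, an additive offset re-references the
  mean of the 30 s before onset to the first cycle's baseline, applied
  uniformly to that cycle's off and on samples.  Re-referencing to the
  *first* cycle is one consistent reading of the offset rule; any common
  reference differs only by a global constant.  An emptied baseline
  window (gap) falls back to the nearest pre-onset samples with a
  warning.
* **Metrics**: baseline = pre-onset window mean; plateau = mean of the
  last 50% of the on-period; rise latency = time from onset to 90% of
  the plateau-above-baseline step (τ·ln 10 for a first-order response,
  recovered within 5% on noiseless fixtures); clearance latency = time
  from offset back to within 10% of the step above baseline.  Epochs too
  short to define a plateau yield NaN metrics.

Two numerical caveats, verified empirically: drift correction is the
identity on a zero-drift *square-wave* trace, but with τ > 0 the
clearance transient leaks into the baseline windows of cycles ≥ 1 (cycle
0 has no preceding on-period), giving small nonzero offsets even without
drift; and filtering and drift correction commute exactly only when the
offsets vanish (e.g. a single epoch) — on multi-cycle fixtures the two
orders differ at the cycle-boundary-transient scale (≲ 1% of the step
amplitude) because the zero-phase filter smears the piecewise-constant
correction at cycle edges.

## Problem sizes and determinism

Stochastic checks use 10,000 simulated trials (chance-level and
detection-rate checks, compared within 3 binomial standard errors),
5,000 trials for parameter recovery (±0.02), and 40-cycle PID fixtures —
sizes at which binomial noise is well below the tolerances while a full
run stays interactive.  Every random draw flows from explicit seeds;
hypothesis property tests run derandomized.

## Known limitations

Only the 3-port geometry is implemented (guarded in configuration).  No
real-time serial/Bluetooth hardware backend ships — the command contract
is the integration surface.  The session CSV schema is a faithful
reconstruction of the documented field list, not a byte-level clone of
any particular lab's files.  The agent's visit policies are deliberate
simplifications of real search behavior.
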