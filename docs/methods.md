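# Methods

## The engine model

`looplab` models a hard real-time experiment loop as a deterministic cycle
scheduler.  One cycle at system frequency `f` (default 20 kHz, period
`1/f = 50 µs`) performs, in order:

1. **acquire** — every enabled analog-input channel samples its signal
   source at `t = k/f` and publishes `clip(gain·raw + offset, lo, hi)`;
2. **execute** — every loaded, unpaused module runs its `execute` step
   once, in load order; each input port receives the *sum* of all
   connected outputs (the many-to-one rule), an unconnected input reads
   0.0, and summation runs in ascending connection-id order so
   floating-point results are reproducible;
3. **drain** — the event queue is drained FIFO; each event invokes every
   module's `update` hook under the matching lifecycle state
   (INIT/MODIFY/PERIOD/PAUSED/UNPAUSED).  Events posted *during* the drain
   are deferred to the next cycle, bounding same-cycle cascades;
4. **emit** — every enabled output channel emits the clipped gathered
   value, timestamped `t`.

Structural requests (pause, parameter edits, frequency changes,
load/unload) apply at the next cycle boundary; a frequency change invokes
every module's PERIOD hook before the next cycle's executes.  NaN produced
on a port propagates and is flagged in the run log, never silently clamped
— model blow-ups should be visible, not hidden.

**Time.** The primary mode is simulated time: the clock is the cycle
counter times the period and no sleeping occurs, so a run is a pure
function of (workspace, duration, seed) and two identical runs produce
byte-identical recorder files.  A `wallclock` mode sleeps to each deadline
for demonstrations; it has no hard-RT guarantee (that would require a
real-time scheduling framework, which is deliberately out of scope — the
package reproduces the observable contract of the RT thread, not kernel
preemption).  The platform's three threads (RT, UI, storage) collapse to
one logical process: the recorder and benchmark collectors are observers
called synchronously after each cycle.

**Intra-cycle ordering.** Modules execute in load order.  A module reads
same-cycle values from modules loaded before it and previous-cycle values
from modules loaded after it; permuting load order therefore shifts a
downstream observer by exactly one cycle and never changes the set of
values (property-tested).  This one-cycle skew is this package's contract;
a real platform's intra-cycle ordering is an implementation detail users
should not rely on either.

**Chunked fast path.** For workspaces with no modules and pure AI→AO
routing, `Engine.run` evaluates cycles in vectorized blocks (250 000 cycles
per numpy operation).  The arithmetic is the same scale/sum/clip applied
elementwise, and the equivalence with the per-cycle path is asserted
bitwise in the tests.  This is what makes the 30-minute, 36-million-cycle
loopback characterization run in seconds.

## Latency measurement

An external-sampler harness reproduces a bench measurement: both the
analog input signal and the zero-order-hold reconstruction of the output
line are evaluated on a 250 kHz grid (in chunks, so arbitrarily long runs
never materialize the grid), rising edges are detected at half amplitude,
and each input edge is matched to the first subsequent output edge.  In
simulated time, an edge strictly inside a cycle is acquired at the next
cycle's acquire step and emitted that same cycle, so loopback latency is
exactly one engine period; latencies are reported in seconds and in whole
periods (ceiling, with one sampler tick of rounding tolerance).  An input
edge with no matching output before the next input edge counts as a missed
event.  The hard-RT verdict on latency is `missed == 0` and
`max latency ≤ 2 periods`.

## Benchmarks

Per cycle: realized period `p_k` (from successive cycle-start timestamps,
or fed directly as the nominal period in simulated mode), jitter
`j_k = p_k − nominal` (signed; the summary also reports `max |j|` since
either convention is common), and computation time `c_k`.  The hard-RT
rule is `max p_k ≤ 2 × nominal`, boundary inclusive.  In simulated mode
`p_k ≡ nominal` by construction and `c_k` is an informational wall-clock
measurement excluded from all determinism guarantees and test assertions.

## Recording

Each trial is an HDF5 group `/Trial N` with `Synchronous Data` (2-D
float64, column names as an attribute), `Parameters` (per module, per
parameter: the initial snapshot value plus a (time, value) change table —
values stored as full-precision strings so floats round-trip exactly),
`System Settings` (enabled AI channel configurations), and `Tags`
((time, text) pairs).  Times are float64 seconds of simulated time; no
wall-clock timestamps are stored, which is what makes files reproducible.
Downsampling by factor `k` keeps cycles ≡ 0 (mod k) — plain decimation
with no anti-alias filter, matching the semantics of a global downsample
option rather than a DSP resampler.  Files use no custom filters and open
in any standard HDF5 tool.  The group and dataset names are this package's
own dialect (the grouping concept is standard; exact names are not), so
they are documented rather than claimed compatible with any other tool's
output.

## Workspace persistence

`<workspace version="1">` with `<engine frequency mode seed/>`,
`<daq><channel .../></daq>`, `<modules><module id type><param/><state/>`
and `<connections><connection src="owner.port" dst="owner.port"/>`.
Floats are serialized with `repr` (shortest round-tripping form); loading
a file with an unregistered module type fails atomically, listing the
registered types.  Round-trip identity is property-tested on randomized
workspaces.

## The neuron, detector, and clamp

The Hodgkin–Huxley point neuron uses the classic squid-axon
parameterization (Cm = 1 µF/cm², gNa = 120, gK = 36, gL = 0.3 mS/cm²,
ENa = 50, EK = −77, EL = −54.4 mV; resting potential ≈ −65 mV) — the model
family is standard and the constants are exposed as parameters.
Integration is RK4 on the engine period with automatic halving to ≤ 25 µs
substeps (two substeps at 20 kHz): the spike upstroke is stiff enough that
a single 50 µs RK4 step distorts spike timing.  Gates are clamped to
[0, 1] after every substep; the rate-function singularities at
V = −40 and −55 mV use an `expm1` form with the analytic limit.  Spike
times agree with an independent 1 µs forward-Euler reference within 1 ms,
and halving the step moves them by less than 1 ms (convergence check).
The stimulus port maps volts to current density at 10 (µA/cm²)/V by
default — a convention parameter, since command-voltage scaling is
hardware-specific.

The spike detector fires on an upward threshold crossing while armed,
emits a 5 V TTL pulse for the configured width (which must span at least
one engine period), then disarms until the potential falls back below
threshold *and* the refractory period elapses — plain threshold crossing
plus hysteresis, the minimal robust reading of "threshold-crossing event".

The dynamic clamp computes `I = −G_leak (V − E_leak)` in pA from the
latest sampled membrane potential every cycle, positive current =
depolarizing, so a negative `G_leak` injects depolarizing current above
`E_leak` and raises excitability.  `E_leak` defaults to the model's
resting potential (−65 mV) and is a parameter.  The command scale is
1 V/nA; in the bundled rheobase experiment the loop uses 0.3 V/nA with the
10 (µA/cm²)/V stimulus port, a composite coupling of 0.003 mS/cm² per nS —
equivalent to a ~3×10⁻⁴ cm² membrane — chosen so that ±60 nS is a strong,
clearly directional perturbation while the total leak stays positive
(stability of the virtual cell, not of the claim, is what bounds it).
Rheobase is measured by bisection (to 0.05 µA/cm²) on 300 ms closed-loop
runs at 20 kHz.

## Auditory-feedback detection

A circular buffer holds the trailing audio.  In **idle** mode only the RMS
of the last 10 ms is evaluated, at 1 kHz; when it exceeds the threshold
(sound present) the detector switches to **triggered** mode, where each
evaluation instant also computes the spectrogram of the most recent 20 ms
and its Pearson correlation with the template spectrogram.  Correlation
above threshold, outside the refractory period, is a detection and starts
feedback playback; the detector returns to idle when the RMS falls below
threshold and playback has finished.  Correlation of a zero-variance
spectrogram is defined as 0 (silence can never match), and the refractory
defaults to the feedback duration.  STFT settings — Hann window of 128
samples, hop 64, band 500–10 000 Hz at the 30 kHz rate — are this
package's defaults (they resolve harmonic stacks at the 20 ms window) and
are all configurable, as is the correlation threshold (default 0.7).
Streaming detection is asserted equal to an independently coded offline
full scan of the same recording, and on clean synthetic songs the hit rate
is 1.0 with zero false positives.  That property says the *online
machinery* loses nothing relative to offline analysis; it does not predict
detection rates on real song, where acoustic variability between
renditions — absent from the generator — is the limiting factor.

## Alpha-gated stimulation

EEG at 2 kHz passes a causal 6th-order Butterworth band-pass (8–12 Hz,
second-order sections; stability checked at design time).  "Mean
oscillation power with a 1 s window" is read as the mean squared filtered
sample over the trailing second (a Hilbert-envelope variant is available
behind a flag; for narrow-band signals they agree).  Calibration takes one
power value per second over 60 s eyes-open and 60 s eyes-closed, and sets
`θ = 1.05 × (mean P_EO + mean P_EC)/2`.  The controller then evaluates the
trailing 1 s power at each 4 s epoch boundary (0.25 Hz); strictly
exceeding θ turns stimulation on for the first 2 s of the epoch that
starts at that boundary — the decision always lags the power it is based
on by construction ("the next epoch"), power exactly equal to θ leaves
stimulation off, and the 40 Hz command starts at a zero crossing.  The
dose-matched random arm delivers the same number of stimulation epochs at
seeded-random epoch positions, independent of measured power.  The
streaming controller and the chunk-vectorized session processor are
sample-for-sample identical (the IIR state is carried across chunks), and
causality is tested directly: corrupting future samples never changes past
output.

## Synthetic data

The generators define the study conditions and are pure functions of
(spec, seed):

* **Trigger trains** — 1800 events over 30 minutes by default, 5 Vpp
  rectangular pulses of 0.5 s (half the nominal 1 s event pitch, i.e. a
  50% duty square at the mean rate); "randomly triggered" is modeled as
  uniform spreading of the spare time with a 0.25 s minimum gap, since
  only the count and duration are prescribed by the protocol.
* **Songs** — sequences of spectrally distinct syllables (harmonic stacks
  at 800 and 1700 Hz, a 2–4.5 kHz sweep; 40–60 ms, Hann-enveloped) with
  80 ± 10 ms gaps; inter-syllable distinctness (pairwise spectrogram
  correlation < 0.5) is itself tested.  Real birdsong varies between
  renditions; this generator deliberately does not, so detection-rate
  results on it are a ceiling, not an estimate.
* **EEG** — 1/f (pink) background (spectrally shaped white noise, SD
  0.5 V) plus a 10 Hz sinusoid at 0.5 V (eyes open) or 2 V (eyes closed),
  alternating every 30 s after a 60 s + 60 s calibration pair, 12 minutes
  total.  The amplitudes are chosen to give cleanly separable alpha
  states, so epoch gating on this surrogate is exact; real EEG alpha
  fluctuates within states, which this surrogate does not model.  An
  optional 40 Hz artifact can be mixed in; no artifact rejection is
  implemented.

## Problem sizes in the tests

The acceptance suite runs the loopback characterization at full scale
(30 simulated minutes, 36 M cycles, 450 M sampler points, analyzed in
chunks) because the chunked engine path makes it cheap.  Pipeline
equivalence tests use a ~60 s song and 2–6 minute EEG sessions; the
neuron reference comparison covers 200 ms of sustained spiking, which
spans several spikes — all sizes chosen as the smallest that exercise the
property being asserted.

## Known limitations

No kernel preemption, interrupts, memory locking, or genuine scheduling
jitter is modeled — `wallclock` mode is a demonstration, not a real-time
system.  Ports carry one scalar per cycle (buffered data stays inside
modules).  The HDF5 and XML dialects are versioned and self-defined.  The
biological findings the protocols come from (plasticity statistics, real
finch detection rates, human EEG suppression effects) depend on real
preparations and are out of scope; the package validates the machinery,
not the biology.
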