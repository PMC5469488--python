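# looplab

A deterministic, simulated-time re-implementation of a hard real-time
closed-loop electrophysiology engine, with the standard closed-loop
protocols built on top of it.

Closed-loop experiment platforms run an iterative hard real-time (RT) loop:
on every cycle of the RT period the system wakes, acquires new samples from
the data-acquisition (DAQ) hardware, executes the processing defined by the
loaded modules, and emits the computed outputs — all within a fixed budget
(50 µs at the common 20 kHz system frequency).  `looplab` reproduces the
*observable semantics* of such a platform without a real-time kernel: the
clock is the cycle counter times the period, so every run is an exactly
reproducible function of (workspace, duration, seed).  That makes the
architecture itself — module lifecycle, dataflow, event queue, recording —
testable on any machine, and makes the engine usable as a simulation
environment for protocol development.

## What is implemented

- **Engine** — per-cycle `acquire → execute → drain events → emit`
  scheduling; modules execute in load order; events posted during execution
  are delivered to every module's `update` hook once all module
  computations of that cycle are complete; pause/unpause, live parameter
  edits, frequency changes, and module load/unload apply at cycle
  boundaries without halting acquisition.  Module-free AI→AO workspaces run
  through a chunked vectorized evaluator (value-identical to the per-cycle
  path), so half-hour characterization runs take seconds.
- **Dataflow** — scalar ports, one-to-one / one-to-many / many-to-one
  connections with summation of fan-in (unconnected inputs read 0), and a
  versioned XML workspace file that round-trips the engine configuration,
  channel configurations, modules with parameter and state values, and
  connections.
- **Virtual DAQ** — per-channel gain/offset/range scaling for AI, clipped
  AO emission, digital lines as 0/5 V levels, and an external 250 kHz
  sampler harness that measures input→output latency per event by matching
  half-amplitude rising edges.
- **Recorder** — HDF5 trials (`/Trial N`) holding the synchronous data
  matrix, a parameter snapshot with timestamped change tables, channel
  settings, and free-text tags; global downsampling stores
  `ceil(n_cycles / k)` rows.
- **Benchmarks** — per-cycle RT period, jitter, and computation time, with
  the hard-RT rule: the realized period must never exceed twice the
  nominal period.
- **Protocol modules** — signal generator; Hodgkin–Huxley point neuron
  (RK4 with automatic substepping, classic squid constants
  `C_m = 1 µF/cm², g_Na = 120, g_K = 36, g_L = 0.3 mS/cm²`);
  threshold-crossing spike detector with TTL output and refractory;
  dynamic-clamp leak conductance `I = −G_leak (V − E_leak)`.
- **Auditory-feedback pipeline** — circular buffer, idle/triggered modes
  gated by the RMS of the last 10 ms (evaluated at 1 kHz), spectrogram of
  the most recent 20 ms correlated against a template spectrogram, and
  feedback playback on detection.
- **Alpha-feedback stimulation pipeline** — causal 6th-order Butterworth
  band-pass at 8–12 Hz, mean alpha power over 1 s windows, two-phase
  (eyes-open / eyes-closed) calibration with
  `θ = 1.05 × (mean P_EO + mean P_EC)/2`, and 0.25 Hz epoch gating of a
  40 Hz stimulation command for the first 2 s of each above-threshold
  epoch, with a dose-matched random control arm.
- **Fixtures** — seeded generators for random trigger trains, synthetic
  birdsong with ground-truth syllable tables, and synthetic EEG with an
  eyes-open/eyes-closed alpha schedule.

## Worked example

Closed-loop dynamic clamp on the model neuron: a negative virtual leak
conductance cancels part of the cell's natural leak and should lower the
minimal current needed to make it fire (its rheobase).

```python
from looplab.modules.protocols import closed_loop_rheobase

for g in (0.0, -60.0, +60.0):
    print(f"G_leak = {g:+.0f} nS  ->  rheobase {closed_loop_rheobase(g):.2f} uA/cm^2")
```

prints

```
G_leak = +0 nS  ->  rheobase 2.25 uA/cm^2
G_leak = -60 nS  ->  rheobase 1.55 uA/cm^2
G_leak = +60 nS  ->  rheobase 3.05 uA/cm^2
```

— adding −60 nS of leak raises excitability (rheobase drops from 2.25 to
1.55 µA/cm²), +60 nS suppresses it, each measured by bisection on a live
closed loop (DC source + clamp → neuron → spike detector) at 20 kHz.

The same workspaces can be driven from the command line:

```sh
looplab fixtures pulses --out pulses.csv        # seeded trigger train
looplab validate workspace.xml                  # schema + port-graph check
looplab run workspace.xml --duration 30min --out data.h5
looplab export data.h5 --trial 1 --csv trace.csv
looplab daf --in song.wav --template syllable.wav --out detections.csv
```

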