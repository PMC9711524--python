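# pulsesync

Simulation and synchrony analysis of an excitable dual-feedback gene circuit
driven by phytohormone pulses.

Synthetic biologists can place an engineered activator–repressor pair (IacR,
an auto-activating transcription factor, and MarR, a repressor produced from
the same promoter) under the control of two external chemicals: auxin (IAA)
destabilises the activator and salicylate (SA) destabilises the repressor.
Grown in a microfluidic device and fed alternating ("antithetic") hormone
pulses, thousands of yeast communities then express a reporter — or a
potassium channel — in macroscopically coordinated pulses.  `pulsesync`
provides the computational side of such experiments for modellers and data
analysts:

* **`pulsesync.circuit`** — the deterministic circuit model

  dIacR/dt = a1 + b1·IacR²/(K_A² + IacR² + (γ·MarR)²) − d1·(1 + εI·IAA(t))·IacR
  dMarR/dt = a2 + b2·IacR²/(K_B² + IacR²) − d2·(1 + εM·SA(t))·MarR

  with a stiff adaptive integrator (stimulus edges as breakpoints),
  closed-form nullclines validated against the vector field, fixed-point
  location, regime classification (steady / excitable / oscillatory), a
  bifurcation scan over the turnover ratio d1/d2, and the two-pulse
  refractory-period protocol.  A calibrated excitable parameter set
  (`EXCITABLE_PARAMS`) ships with the package.
* **`pulsesync.synth`** — a generator of synthetic multi-community
  fluorescence recordings (amplitude variability, phase jitter, skipped
  cycles, drift, noise; presets for tight, loose, and absent coupling),
  plus a mechanistic variant that simulates one jittered circuit per
  community.
* **`pulsesync.analysis`** — the trace-analysis pipeline: dual-channel
  normalisation green/(green+red), linear detrending, Savitzky–Golay
  smoothing (window 15), 0–1 rescaling, run-length peak detection
  (nups = ndowns = 6), inter-peak periods, cross-community phase drift, the
  synchrony index 1 − R (R = mean |peak-time deviation| / expected period),
  cumulative autocorrelation, and FFT power spectra.
* **`pulsesync` CLI** — `simulate`, `nullclines`, `classify`, `scan`,
  `refractory`, `generate`, `analyze` subcommands with JSON configs and
  reproducibility manifests.

## Worked example

Entrain the calibrated excitable circuit with 2-hour antithetic pulses and
push the simulated reporter through the analysis pipeline:

```python
from pulsesync import (EXCITABLE_PARAMS, StimulusProgram, CommunityTraces,
                       simulate, analyze, classify_regime)

stim = StimulusProgram.antithetic(period=2.0, duration=24.0)   # SA then IAA
traj = simulate(EXCITABLE_PARAMS, stim)                        # 10-min sampling
traces = CommunityTraces(values=traj.iacr[None, :], time_h=traj.time_h)
report = analyze(traces, expected_period=2.0)

print("median period:", report.period_median)          # -> 2.0
print("ACF dominant period:", report.acf.dominant_period_h)  # -> 2.0
print("n peaks:", report.peak_set.n_peaks)             # -> 11
print(classify_regime(EXCITABLE_PARAMS).label)         # -> excitable
```

The circuit fires exactly one reporter pulse per forcing cycle (11 peaks in
24 h), so the median inter-peak interval equals the 2-h forcing period, and
the unforced circuit is classified excitable (a super-threshold kick of the
activator triggers a single ~3.6× excursion that returns to rest).

The same pipeline applied to synthetic multi-community recordings
reproduces the tight-versus-loose coupling contrast:

```python
from pulsesync import PRESETS, generate_traces

closed = PRESETS["closed_loop"].replace(seed=7, n_communities=28, period=2.0, duration=24.0)
print(analyze(generate_traces(closed), expected_period=2.0).synchrony.median)  # -> 0.976

open_ = PRESETS["open_loop"].replace(seed=7, n_communities=28, period=2.0, duration=24.0)
print(analyze(generate_traces(open_), expected_period=2.0).synchrony.median)   # -> 0.811
```

Or from the shell:

```bash
pulsesync generate --preset closed_loop --n 28 --period 2 --duration 24 --seed 7 --out traces.csv
pulsesync analyze --traces traces.csv --period 2 --out report.json
pulsesync scan --lo 0.1 --hi 10 --points 25 --out scan.csv
```

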