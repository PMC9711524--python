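# Methods

## The circuit model

`pulsesync.circuit` integrates a two-variable model of a synthetic
dual-feedback gene circuit in yeast: a transcriptional activator (IacR) that
activates its own promoter cooperatively, and a repressor (MarR), produced
from the same promoter, that competes with activation by inflating the Hill
denominator.  Two phytohormone inputs act on protein stability: auxin (IAA)
accelerates activator turnover and salicylate (SA) accelerates repressor
turnover:

    dIacR/dt = a1 + b1·IacR² / (K_A² + IacR² + (γ·MarR)²) − d1·(1 + εI·IAA(t))·IacR
    dMarR/dt = a2 + b2·IacR² / (K_B² + IacR²)             − d2·(1 + εM·SA(t))·MarR

Concentrations are in arbitrary units, time in hours, turnover rates in 1/h,
and hormone levels are dimensionless in [0, 1] by default.  The model is
deterministic; no stochastic (Gillespie/Langevin) variant is provided, and no
membrane-potential equation is modelled — the reporter proxy is IacR itself
(all circuit genes share one promoter, so promoter activity and the
destabilised reporter track the activator).

### Nullclines

With hormones off, the MarR-nullcline is the closed form
`MarR**(I) = (a2 + b2·I²/(K_B²+I²))/d2`.  The IacR-nullcline is obtained by
inverting the activation Hill term:

    (γ·MarR*)² = b1·I² / (d1·I − a1) − K_A² − I²,

defined where `d1·I > a1` and the right-hand side is nonnegative; elsewhere
the nullcline has no nonnegative MarR solution and is reported as NaN.  Every
returned point is validated against the vector field itself (residual
`|dIacR/dt| < 1e-8`, scaled); the closed form is never trusted on its own.
Fixed points are located as sign changes of `dIacR/dt` along the
MarR-nullcline and polished by bracketed root finding.

### Integration

`simulate` uses LSODA (stiff-capable, adaptive) at `rtol=1e-8`,
`atol=1e-10`.  Square-wave and pulse edges are collected from the stimulus
program and used as integration breakpoints: the solver is restarted at each
discontinuity, so edges are never smeared by steps straddling them.  Output
is sampled from the dense solution on a uniform grid, default `1/6 h`
(mirroring a 10-min imaging cadence).  Square waves are right-continuous,
with a `1e-9`-period snap so that float dirt at an edge takes the level of
that edge.  Trajectories from nonnegative initial conditions are nonnegative
up to solver tolerance; values below `−1e-6` (relative) raise, smaller
negative dust is clipped to zero.

The fixed-step RK4 cross-check used in the tests holds the hormone levels
constant within each step at the step's left-edge value; with step size
dividing the waveform period this is exact for square forcing, making the
two integration routes genuinely comparable at `1e-4` relative tolerance.

## Calibrated default parameters

The supplementary parameter table of the study this model accompanies is not
available, so the package ships its own calibrated set, found by a documented
procedure and then frozen:

| parameter | value | role / rationale |
|-----------|-------|------------------|
| a1        | 0.042 | basal activator production; sets the relaunch speed after an auxin crush and, jointly with b1, the distance of rest from the fold |
| a2        | 0.03  | basal repressor production; small versus the feedback arm so the repressor genuinely de-represses under long auxin steps |
| b1        | 18.0  | activator self-activation; b1/d1 ≈ 11 sets the excursion ceiling, ~200× the rest level |
| b2        | 2.46  | repressor production; fast enough to brake an excursion within ~2 h, slow enough not to chase down a super-threshold kick |
| K_A       | 0.05  | activation threshold scale, far below γ·MarR at rest so repression dominates the effective threshold |
| K_B       | 0.15  | repressor-arm half-max, ≈3× the rest IacR level, so repressor production falls substantially when the activator is crushed |
| γ         | 1.0   | weight of MarR in the activation denominator (scale convention) |
| d1        | 1.65  | activator turnover (1/h); sets the pulse timescale (~0.6 h) |
| d2        | 0.2421878 | repressor turnover; d1/d2 = 10^(5/6) ≈ 6.81 places the set inside the excitable band of the standard two-decade ratio scan |
| εI        | 5.0   | auxin effect on d1: crushes IacR with a ~6-min time constant while leaving the post-release level above the slow saddle-node bottleneck, so release responses are prompt |
| εM        | 70.0  | salicylate effect on d2: clears MarR within a 15-min half-cycle, required for 1:1 locking at 30-min forcing |

Procedure: the production/Hill constants were chosen from a frozen-repressor
(cubic root) analysis targeting a rest state on the lower activation branch
with a quasi-threshold ≈1.4× rest and an excursion ceiling >50× rest; the
turnover pair was then scanned until (i) the unforced system settles, (ii) a
2.0-relative kick fires a single >3× excursion that returns to rest, (iii)
the two-decade d1/d2 scan shows steady, oscillatory and excitable bands, and
(iv) antithetic square forcing entrains 1:1 at 0.5, 1, 2 and 3 h.  The
frozen set satisfies all four with margins (the excursion is 3.6× rest and
the labels survive ±5% jitter of a1 and d2).  εI and εM differ because their
jobs differ: fast SA clearing of MarR is required for high-frequency
entrainment, while a strong εI would push the auxin-crushed IacR level so
low that post-release responses crawl through the saddle-node ghost for
many hours.

### Regime classification

`classify_regime` simulates the unforced system from (0, 0) over a 48-h
window.  *Oscillatory*: ≥3 peaks in the second half with inter-peak CV <
0.1, sustained amplitude (last peak ≥ half the first), and peak-to-peak
swing above 20% of the tail median — the last condition rejects the
numerically tiny ringing of a weakly damped focus, whose 48-h label would
otherwise disagree with the long-horizon attractor.  *Excitable*: the
unforced system settles, and raising IacR by the `perturbation` fraction
(default 2.0, i.e. a kick to 3× rest) produces an excursion that grows
beyond the kick, exceeds 3× rest, and returns to rest within the window.
*Steady*: everything else.

The default kick deserves a note.  In this two-variable reduction the
quasi-threshold is the middle root of the frozen-repressor cubic; demanding
a threshold within 50% of rest forces the rest state within ~2% of its
saddle-node fold, where escape is slow (rate ∝ d1 × kick margin) and the
repressor's response to the kick re-stabilises the rest state before escape
completes.  Every parameter set we found with a sub-1.5× threshold was
numerically fragile — classification flipped under <1% parameter changes.
A kick of 2.0 probes the same all-or-none physics with robust margins, so it
is the shipped default.

`bifurcation_scan` re-classifies the circuit along a grid of turnover ratios
(vary-d2 by default: `d2 = d1/ratio`).  On the calibrated set the canonical
25-point log grid over [0.1, 10] reads steady (≤3.2), oscillatory
(3.8–5.6), excitable (6.8–10), in contiguous bands.

### Refractory protocol

`refractory_protocol` applies two long auxin-only steps (12 h by default)
separated by a gap.  During a step the activator is crushed and the
repressor decays toward its basal level; at release the activator rebounds
into a de-repressed field and fires one pulse — the model's account of a
"response at hormone removal".  Response amplitudes are measured per pulse
as the maximum IacR above rest within `[pulse start, next pulse start)`
(the last window extends to the end of the run).  On the calibrated set the
second response recovers to within 10% of the first for gaps ≥ 5/d1 (~3 h).

**Known limitation.**  The complementary suppression property — a second
12-h step after only a 2-h gap eliciting <20% of the first response — is
*not* reproduced, and our analysis indicates it cannot be within this
two-variable model while kick excitability holds: suppression requires the
repressor raised by the first response to stay above the firing threshold
through the entire second 12-h step (M_burst/M_threshold > e^(12·d2)) while
climbing that high within the 2-h gap (production ≳ 5/h), and a repressor
that fast reabsorbs any super-threshold activator kick.  The corresponding
acceptance check is left failing rather than tuned around.

## Synthetic community traces

`pulsesync.synth` emulates multi-community microfluidic recordings at the
extracted-trace level (no image synthesis): 20–60 communities, 10-min
sampling, pulsatile signal entrained to the stimulus period.  Each community
trace is

    baseline + drift·t + Σ_cycles amp_draw · kernel(t − kT − jitter) · Bernoulli(1−skip) + noise,

with a difference-of-exponentials kernel (rise 0.1·T, decay 0.25·T —
pulse-like and asymmetric), lognormal amplitude draws (positivity), Gaussian
additive noise, and linear drift.  Presets: `closed_loop` (jitter SD 0.05·T,
skip 0.02), `open_loop` (jitter SD 0.25·T, skip 0.3, doubled amplitude
spread), `control` (no pulses).  The preset values are package conventions
bracketing a tight-versus-loose coupling contrast; they are not fits to any
real recording.  Per-community RNG substreams derive from (seed, community
index), so a community's trace is independent of cohort size.

`generate_from_model` instead simulates the ODE circuit per community with
each kinetic rate scaled by an independent unit-mean lognormal factor
(CV = `heterogeneity`), using IacR as the reporter.

What the generator does *not* emulate: cell growth and segmentation
artefacts, photobleaching, non-linear reporter maturation, cross-community
coupling, and any fitted noise magnitudes.  Passing round-trip tests
therefore demonstrate correctness of the analysis chain, not validity of
the noise model for real data.

## Trace analysis pipeline

Stage order and defaults follow the standard reduction for this kind of
recording: optional dual-channel normalisation `green/(green+red)`; linear
least-squares detrend per community; Savitzky–Golay smoothing (window 15
samples, polynomial order 4 — the filter length is the method's stated
value, the order is the default of the routine the method names); per-trace
min–max rescaling to [0, 1]; run-length peak calling (a sample is a peak iff
preceded by ≥ nups non-decreasing and followed by ≥ ndowns non-increasing
steps, both 6 by default, height ≥ 0.2 on the rescaled signal); inter-peak
periods; cross-community phase drift; synchrony index; cumulative
autocorrelation; FFT power spectral density.

Conventions chosen where the method leaves room (all exposed as config):

* **Peak width** — full width at half prominence on the signal the peaks
  were called on (scale-free under the per-trace affine rescale).
* **Amplitudes** — read off the smoothed (pre-rescale) signal at the called
  peak times, since min–max rescaling destroys amplitude information.
* **Phase drift / synchrony** — peaks are assigned to cycles by rounding
  against the circular-mean phase, each cycle's reference is the
  cross-community median peak time (a fixed stimulus clock is available via
  `reference="clock"`), a community's peak matches a cycle when within half
  a period of the reference, and the per-community index is
  `max(0, 1 − mean|deviation|/T)`.  Identical trains give 1; a community
  deviating by T/2 every cycle gives 0.5.
* **ACF** — biased (divide-by-n) estimator on the mean-centred trace,
  normalised to 1 at lag 0; the cumulative curve is the mean over
  communities; constant traces are excluded with a warning.
* **PSD** — one-sided periodogram (density scaling) of the mean-centred
  traces; dominant period = 1/argmax over nonzero frequencies.
* **"Organized"** — a recording is flagged unstructured when the highest
  positive-lag local maximum of the cumulative ACF falls below 0.2; the
  control preset lands near zero, entrained presets near 0.6+.

### Sampling-interval interactions

The run-length rule needs ≥ nups + ndowns = 12 samples between successive
peaks.  At 10-min sampling that is exactly one 2-h period, so for 2-h data
the rule operates at its parity limit: any timing jitter produces intervals
of 11 samples that cannot host a peak pair, ~25–40% of peaks are dropped,
and the surviving inter-peak intervals are biased one sample long (a pooled
median of 2.17 h for 2.00-h truth — reproducible across seeds).  For 1-h
periods the rule is unsatisfiable at 10-min sampling.  Analyses of simulated
trajectories at 1-h and 30-min forcing therefore sample at 2 min, where the
same pipeline recovers the forcing period exactly; the synthetic-preset
round-trip keeps the 10-min study cadence and is asserted to one sampling
interval.

## Problem sizes and runtimes

Default test and acceptance runs use 24–30-h simulations at 10-min or 2-min
output, 20–30 communities, 25-point regime scans, and 50 paired seeds for
the preset synchrony contrast; the full test suite runs in well under a
minute on one core, and `scripts/acceptance.py` in a few seconds.
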