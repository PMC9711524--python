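"""Synthetic community-trace generator.

Emulates the statistical structure of microfluidic mean-fluorescence
recordings: tens of communities sampled every 10 min for up to tens of hours,
each showing pulsatile reporter signal entrained to a periodic stimulus, with
community-to-community amplitude variability, per-peak amplitude variability,
phase jitter, occasional skipped cycles, slow baseline drift, and additive
noise.  Two routes are provided: a phenomenological kernel generator
(:func:`generate_traces`) and a mechanistic one that simulates the circuit
model per community with jittered parameters (:func:`generate_from_model`).

The preset noise levels are artifact conventions bracketing the qualitative
open-loop vs closed-loop contrast; they are not fits to any real recording.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np

from .circuit import CircuitParams, simulate, rest_state
from .stimulus import StimulusProgram
from .traces import CommunityTraces

__all__ = ["GeneratorConfig", "ConfigError", "generate_traces", "generate_from_model", "PRESETS"]


class ConfigError(ValueError):
    """Invalid generator configuration; message lists offending fields."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the phenomenological trace generator.

    Times are hours; amplitudes arbitrary fluorescence units.  The pulse
    kernel is a difference of exponentials with rise/decay times scaled to
    the stimulus period, giving the asymmetric burst shape seen in pulsatile
    reporter data.
    """

    n_communities: int = 28
    duration: float = 24.0
    period: float = 2.0
    kernel_rise_frac: float = 0.1
    kernel_decay_frac: float = 0.25
    amplitude: float = 1.0
    community_amplitude_cv: float = 0.3
    peak_amplitude_cv: float = 0.15
    jitter_sd_frac: float = 0.05
    skip_probability: float = 0.02
    baseline: float = 1.0
    drift_per_hour: float = 0.01
    noise_sd: float = 0.05
    dt: float = 1.0 / 6.0
    seed: int = 0
    preset: str | None = None
    pulses: bool = True

    def __post_init__(self) -> None:
        bad = []
        if self.n_communities < 1:
            bad.append("n_communities")
        if not self.period > 0:
            bad.append("period")
        if self.duration < 2 * self.period:
            bad.append("duration (need ≥ 2·period)")
        for name in ("community_amplitude_cv", "peak_amplitude_cv", "jitter_sd_frac", "noise_sd"):
            if getattr(self, name) < 0:
                bad.append(name)
        if not 0.0 <= self.skip_probability <= 1.0:
            bad.append("skip_probability")
        if not self.dt > 0:
            bad.append("dt")
        if self.kernel_rise_frac <= 0 or self.kernel_decay_frac <= self.kernel_rise_frac:
            bad.append("kernel fractions (need 0 < rise < decay)")
        if bad:
            raise ConfigError(f"invalid generator config fields: {', '.join(bad)}")

    def replace(self, **changes) -> "GeneratorConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


def _preset_configs() -> dict[str, GeneratorConfig]:
    base = GeneratorConfig()
    return {
        # tight entrainment: small jitter, rare skips
        "closed_loop": base.replace(preset="closed_loop", jitter_sd_frac=0.05, skip_probability=0.02),
        # loose coupling: broad phase jitter, frequent skips, doubled amplitude spread
        "open_loop": base.replace(
            preset="open_loop", jitter_sd_frac=0.25, skip_probability=0.30,
            community_amplitude_cv=0.6, peak_amplitude_cv=0.3,
        ),
        # no circuit: drift + noise only, no organized features
        "control": base.replace(preset="control", pulses=False),
    }


PRESETS = _preset_configs()


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean lognormal draw with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def _pulse_kernel(tau: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials burst, normalized to unit maximum."""
    k = np.where(tau >= 0, np.exp(-np.maximum(tau, 0.0) / decay) - np.exp(-np.maximum(tau, 0.0) / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return k / peak


def generate_traces(config: GeneratorConfig) -> CommunityTraces:
    """Draw one synthetic multi-community recording.

    Each community trace is baseline + drift·t + Σ_cycles amplitude ×
    kernel(t − cycle time − jitter) × Bernoulli(1 − skip) + Gaussian noise.
    Per-community random substreams are derived from (seed, community index),
    so a community's trace does not depend on how many others are generated.
    """
    cfg = config
    n_t = int(round(cfg.duration / cfg.dt)) + 1
    time_h = np.arange(n_t) * cfg.dt
    rise = cfg.kernel_rise_frac * cfg.period
    decay = cfg.kernel_decay_frac * cfg.period
    cycle_times = np.arange(0.0, cfg.duration, cfg.period)

    values = np.empty((cfg.n_communities, n_t))
    for i in range(cfg.n_communities):
        rng = np.random.default_rng([cfg.seed, i])
        amp_c = cfg.amplitude * _lognormal_factor(rng, cfg.community_amplitude_cv)
        trace = cfg.baseline + cfg.drift_per_hour * time_h
        if cfg.pulses:
            for t_k in cycle_times:
                fired = rng.random() >= cfg.skip_probability
                jitter = rng.normal(0.0, cfg.jitter_sd_frac * cfg.period)
                amp = amp_c * _lognormal_factor(rng, cfg.peak_amplitude_cv)
                if fired:
                    trace = trace + amp * _pulse_kernel(time_h - t_k - jitter, rise, decay)
        if cfg.noise_sd > 0:
            trace = trace + rng.normal(0.0, cfg.noise_sd, size=n_t)
        values[i] = trace

    return CommunityTraces(
        values=values, time_h=time_h, channel="dEGFP",
        meta={"generator": "kernel", "config": cfg.to_dict(), "seed": cfg.seed},
    )


def generate_from_model(
    params: CircuitParams,
    stimulus: StimulusProgram,
    n_communities: int,
    heterogeneity: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    output_dt: float = 1.0 / 6.0,
) -> CommunityTraces:
    """Simulate one circuit per community with lognormally jittered rates.

    Community i runs the ODE model with every kinetic rate scaled by an
    independent unit-mean lognormal factor (CV = ``heterogeneity``); IacR(t)
    serves as the reporter proxy, plus additive Gaussian noise.
    """
    if heterogeneity < 0 or noise_sd < 0:
        raise ConfigError("heterogeneity and noise_sd must be nonnegative")
    if n_communities < 1:
        raise ConfigError("n_communities must be ≥ 1")

    jittered_fields = ("a1", "a2", "b1", "b2", "K_A", "K_B", "gamma", "d1", "d2")
    ref = rest_state(params)
    values = None
    time_h = None
    for i in range(n_communities):
        rng = np.random.default_rng([seed, i])
        factors = _lognormal_factor(rng, heterogeneity, size=len(jittered_fields))
        p_i = params.replace(**{f: getattr(params, f) * float(fac) for f, fac in zip(jittered_fields, factors)})
        try:
            init = ref if heterogeneity == 0 else rest_state(p_i)
            traj = simulate(p_i, stimulus, init=init, output_dt=output_dt)
        except Exception as exc:  # annotate which community failed
            raise RuntimeError(f"simulation failed for community {i + 1}: {exc}") from exc
        if values is None:
            time_h = traj.time_h
            values = np.empty((n_communities, len(time_h)))
        trace = traj.iacr
        if noise_sd > 0:
            trace = trace + rng.normal(0.0, noise_sd, size=len(trace))
        values[i] = trace

    return CommunityTraces(
        values=values, time_h=time_h, channel="dEGFP",
        meta={"generator": "model", "heterogeneity": heterogeneity,
              "noise_sd": noise_sd, "seed": seed, "params": params.to_dict()},
    )
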