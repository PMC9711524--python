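"""Time-dependent phytohormone stimulus programs.

The circuit is driven by two external inputs: auxin (IAA), which accelerates
turnover of the activator IacR, and salicylate (SA), which accelerates turnover
of the repressor MarR.  A :class:`StimulusProgram` describes both waveforms on
a common clock.  Square waves are right-continuous: at an edge time the new
level already applies, and every edge is reported by :meth:`breakpoints` so the
integrator can restart there instead of smearing the discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["StimulusProgram", "StimulusError"]

_KINDS = ("off", "square", "sine", "pulse_list")


class StimulusError(ValueError):
    """Raised for an inconsistent stimulus description."""


@dataclass(frozen=True)
class StimulusProgram:
    """IAA(t) and SA(t) waveforms over a finite protocol duration.

    Parameters
    ----------
    duration:
        Total protocol length in hours.
    kind:
        ``"off"`` (both channels zero), ``"square"``, ``"sine"``, or
        ``"pulse_list"`` (explicit intervals).
    period:
        Waveform period in hours (square / sine kinds).
    iaa_amplitude, sa_amplitude:
        Dimensionless stimulus levels while a channel is high (default 1).
    duty:
        Fraction of the period a square wave is high, in (0, 1).
    iaa_offset, sa_offset:
        Start time (hours) of each channel's high phase (square) or phase
        shift (sine).
    pulses:
        For ``pulse_list``: ``(start, end, channel)`` with channel ``"IAA"``
        or ``"SA"``; intervals must not overlap within one channel.
    """

    duration: float
    kind: str = "off"
    period: float | None = None
    iaa_amplitude: float = 1.0
    sa_amplitude: float = 1.0
    duty: float = 0.5
    iaa_offset: float = 0.0
    sa_offset: float = 0.0
    iaa_duty: float | None = None
    sa_duty: float | None = None
    pulses: tuple[tuple[float, float, str], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise StimulusError(f"unknown stimulus kind {self.kind!r}")
        if not self.duration > 0:
            raise StimulusError("duration must be positive")
        if self.iaa_amplitude < 0 or self.sa_amplitude < 0:
            raise StimulusError("amplitudes must be nonnegative")
        if self.kind in ("square", "sine"):
            if self.period is None or not self.period > 0:
                raise StimulusError(f"{self.kind} waveform needs a positive period")
        if self.kind == "square":
            for d in (self.duty, self._duty("IAA"), self._duty("SA")):
                if not (0.0 < d < 1.0):
                    raise StimulusError("square-wave duty cycle must lie in (0, 1)")
        if self.kind == "pulse_list":
            by_channel: dict[str, list[tuple[float, float]]] = {"IAA": [], "SA": []}
            for start, end, channel in self.pulses:
                if channel not in by_channel:
                    raise StimulusError(f"pulse channel must be IAA or SA, got {channel!r}")
                if not end > start:
                    raise StimulusError(f"empty pulse interval ({start}, {end})")
                by_channel[channel].append((float(start), float(end)))
            for channel, ivs in by_channel.items():
                ivs.sort()
                for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
                    if s1 < e0:
                        raise StimulusError(f"overlapping {channel} pulses at t={s1}")

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def off(cls, duration: float) -> "StimulusProgram":
        """No hormones: the unforced circuit."""
        return cls(duration=duration, kind="off")

    @classmethod
    def antithetic(
        cls,
        period: float,
        duration: float,
        amplitude: float = 1.0,
        duty: float = 0.5,
    ) -> "StimulusProgram":
        """Alternating SA/IAA square waves; exactly one hormone high at a time.

        SA occupies the first ``duty`` fraction of each cycle and IAA the
        remainder, so the two high phases tile the period without overlap —
        the stimulus pattern drawn as alternating black (SA) and green (IAA)
        boxes in the experiments this model accompanies.
        """
        return cls(
            duration=duration,
            kind="square",
            period=period,
            iaa_amplitude=amplitude,
            sa_amplitude=amplitude,
            duty=duty,
            sa_offset=0.0,
            sa_duty=duty,
            iaa_offset=duty * period,
            iaa_duty=1.0 - duty,  # antithetic guarantee: IAA fills the rest of the cycle
        )

    @classmethod
    def square(
        cls,
        period: float,
        duration: float,
        iaa_amplitude: float = 1.0,
        sa_amplitude: float = 1.0,
        duty: float = 0.5,
        iaa_offset: float = 0.0,
        sa_offset: float = 0.0,
    ) -> "StimulusProgram":
        return cls(
            duration=duration,
            kind="square",
            period=period,
            iaa_amplitude=iaa_amplitude,
            sa_amplitude=sa_amplitude,
            duty=duty,
            iaa_offset=iaa_offset,
            sa_offset=sa_offset,
        )

    @classmethod
    def sine(
        cls,
        period: float,
        duration: float,
        iaa_amplitude: float = 1.0,
        sa_amplitude: float = 1.0,
        iaa_offset: float = 0.0,
        sa_offset: float = 0.0,
    ) -> "StimulusProgram":
        """Raised-sine waves: amplitude/2 * (1 - cos(2π (t - offset)/T)) ≥ 0."""
        return cls(
            duration=duration,
            kind="sine",
            period=period,
            iaa_amplitude=iaa_amplitude,
            sa_amplitude=sa_amplitude,
            iaa_offset=iaa_offset,
            sa_offset=sa_offset,
        )

    @classmethod
    def pulse_list(
        cls,
        pulses: Sequence[tuple[float, float, str]],
        duration: float,
        iaa_amplitude: float = 1.0,
        sa_amplitude: float = 1.0,
    ) -> "StimulusProgram":
        return cls(
            duration=duration,
            kind="pulse_list",
            iaa_amplitude=iaa_amplitude,
            sa_amplitude=sa_amplitude,
            pulses=tuple((float(s), float(e), str(c)) for s, e, c in pulses),
        )

    # ------------------------------------------------------------------ #
    # evaluation

    def _duty(self, name: str) -> float:
        override = self.iaa_duty if name == "IAA" else self.sa_duty
        return self.duty if override is None else override

    def _channel(self, t, amplitude: float, offset: float, name: str):
        t = np.asarray(t, dtype=float)
        if self.kind == "off" or amplitude == 0.0:
            return np.zeros_like(t)
        if self.kind == "square":
            phase = np.mod(t - offset, self.period)
            # snap float dirt at the edges: a phase within 1e-9 periods of an
            # edge takes the right-continuous level of that edge
            eps = 1e-9 * self.period
            high = (phase < self._duty(name) * self.period - eps) | (phase >= self.period - eps)
            return np.where(high, amplitude, 0.0)
        if self.kind == "sine":
            return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * (t - offset) / self.period))
        # pulse_list
        out = np.zeros_like(t)
        for start, end, channel in self.pulses:
            if channel == name:
                out = np.where((t >= start) & (t < end), amplitude, out)
        return out

    def iaa(self, t):
        """IAA level at time(s) ``t`` (hours); right-continuous."""
        return self._channel(t, self.iaa_amplitude, self.iaa_offset, "IAA")

    def sa(self, t):
        """SA level at time(s) ``t`` (hours); right-continuous."""
        return self._channel(t, self.sa_amplitude, self.sa_offset, "SA")

    def breakpoints(self, t0: float = 0.0, t1: float | None = None) -> np.ndarray:
        """Discontinuity times in the open interval (t0, t1), sorted."""
        if t1 is None:
            t1 = self.duration
        edges: set[float] = set()
        if self.kind == "square":
            for offset, duty in (
                (self.sa_offset, self._duty("SA")),
                (self.iaa_offset, self._duty("IAA")),
            ):
                k0 = int(np.floor((t0 - offset) / self.period)) - 1
                k1 = int(np.ceil((t1 - offset) / self.period)) + 1
                for k in range(k0, k1 + 1):
                    edges.add(offset + k * self.period)
                    edges.add(offset + (k + duty) * self.period)
        elif self.kind == "pulse_list":
            for start, end, _ in self.pulses:
                edges.add(start)
                edges.add(end)
        pts = np.array(sorted(e for e in edges if t0 < e < t1))
        return pts

    def with_duration(self, duration: float) -> "StimulusProgram":
        return replace(self, duration=duration)
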