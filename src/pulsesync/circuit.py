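"""Deterministic model of the IacR–MarR dual-feedback excitable circuit.

Two proteins form the circuit: the transcriptional activator IacR (auto-
activating through a cooperative Hill term) and the repressor MarR, itself
produced in an IacR-dependent way and acting by competitively raising the
activation threshold.  External phytohormones enter as multiplicative boosts
of the turnover terms: auxin (IAA) destabilises IacR and salicylate (SA)
destabilises MarR.

    dIacR/dt = a1 + b1·IacR² / (K_A² + IacR² + (γ·MarR)²) − d1·(1 + εI·IAA(t))·IacR
    dMarR/dt = a2 + b2·IacR² / (K_B² + IacR²)             − d2·(1 + εM·SA(t))·MarR

With hormones off the system sits in one of three qualitative regimes —
steady, excitable (single rest state, large pulse on super-threshold
perturbation, then a refractory period while MarR decays), or oscillatory —
and the turnover ratio d1/d2 moves it between them.  This module provides the
vector field, an adaptive stiff integrator with square-wave edges handled as
restart breakpoints, nullclines/fixed points, regime classification, a d1/d2
bifurcation scan, and the two-pulse refractory-period protocol.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root
from scipy.signal import find_peaks as _scipy_find_peaks

from .stimulus import StimulusProgram

__all__ = [
    "CircuitParams",
    "Trajectory",
    "NullclineSet",
    "RegimeLabel",
    "EXCITABLE_PARAMS",
    "ParameterError",
    "SolverError",
    "dynamics",
    "simulate",
    "rest_state",
    "nullclines",
    "classify_regime",
    "bifurcation_scan",
    "refractory_protocol",
]


class ParameterError(ValueError):
    """Invalid kinetic parameter set."""


class SolverError(RuntimeError):
    """ODE integration failed; carries the failure time."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class CircuitParams:
    """Kinetic constants of the dual-feedback circuit.

    Units: concentrations are arbitrary but consistent; rates are per hour.

    a1, a2      basal production of IacR / MarR (conc/h)
    b1, b2      IacR-dependent production (conc/h)
    K_A, K_B    half-max Hill coefficients (conc), strictly positive
    gamma       weight of MarR inside the activation Hill denominator
    d1, d2      turnover rates (1/h), strictly positive
    eps_I, eps_M  hormone effect on turnover (per stimulus unit)
    """

    a1: float
    a2: float
    b1: float
    b2: float
    K_A: float
    K_B: float
    gamma: float
    d1: float
    d2: float
    eps_I: float = 0.0
    eps_M: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "b1", "b2", "gamma", "eps_I", "eps_M"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        for name in ("K_A", "K_B", "d1", "d2"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")

    @property
    def turnover_ratio(self) -> float:
        """The bifurcation parameter d1/d2."""
        return self.d1 / self.d2

    def replace(self, **changes) -> "CircuitParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown parameter fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "CircuitParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


#: Calibrated excitable default.  Found by the documented procedure: fix the
#: production and Hill constants, then place the turnover pair (d1, d2) so
#: that the unforced system has a stable rest state firing one large pulse
#: under a super-threshold IacR kick, the d1/d2 axis traverses steady,
#: oscillatory and excitable bands, and antithetic forcing entrains 1:1 at
#: periods from 30 min to 3 h.  Procedure and sensitivities: docs/methods.md.
EXCITABLE_PARAMS = CircuitParams(
    a1=0.042,
    a2=0.03,
    b1=18.0,
    b2=2.46,
    K_A=0.05,
    K_B=0.15,
    gamma=1.0,
    d1=1.65,
    d2=0.2421878,
    eps_I=5.0,
    eps_M=70.0,
)


@dataclass
class Trajectory:
    """One deterministic simulation on a uniform time grid (hours)."""

    time_h: np.ndarray
    iacr: np.ndarray
    marr: np.ndarray
    iaa: np.ndarray
    sa: np.ndarray
    params: CircuitParams

    def __post_init__(self) -> None:
        n = len(self.time_h)
        for arr in (self.iacr, self.marr, self.iaa, self.sa):
            if len(arr) != n:
                raise ValueError("trajectory arrays must share one time grid")
        steps = np.diff(self.time_h)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12)):
            raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.time_h[1] - self.time_h[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.time_h, "IacR": self.iacr, "MarR": self.marr,
             "IAA": self.iaa, "SA": self.sa}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class NullclineSet:
    """Nullclines MarR*(IacR), MarR**(IacR) and the fixed points.

    ``marr_star`` is NaN wherever the IacR-nullcline has no nonnegative MarR
    solution (the inverted Hill term's radicand is negative or d1·IacR ≤ a1).
    """

    iacr_grid: np.ndarray
    marr_star: np.ndarray
    marr_star2: np.ndarray
    fixed_points: list[tuple[float, float]]
    params: CircuitParams


@dataclass
class RegimeLabel:
    """Qualitative regime with the diagnostics that justified it."""

    label: str  # steady | excitable | oscillatory
    n_peaks: int = 0
    interval_cv: float = float("nan")
    excursion_ratio: float = float("nan")
    returned_to_rest: bool = True
    rest: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.label not in ("steady", "excitable", "oscillatory"):
            raise ValueError(f"unknown regime label {self.label!r}")


# --------------------------------------------------------------------------- #
# vector field and integration


def dynamics(
    state: Sequence[float],
    t: float,
    params: CircuitParams,
    stimulus: StimulusProgram | None = None,
) -> tuple[float, float]:
    """Right-hand side (dIacR/dt, dMarR/dt) at ``state`` and time ``t``."""
    iacr, marr = state
    iaa = float(stimulus.iaa(t)) if stimulus is not None else 0.0
    sa = float(stimulus.sa(t)) if stimulus is not None else 0.0
    p = params
    act = p.b1 * iacr**2 / (p.K_A**2 + iacr**2 + (p.gamma * marr) ** 2)
    d_iacr = p.a1 + act - p.d1 * (1.0 + p.eps_I * iaa) * iacr
    d_marr = p.a2 + p.b2 * iacr**2 / (p.K_B**2 + iacr**2) - p.d2 * (1.0 + p.eps_M * sa) * marr
    return (d_iacr, d_marr)


def _grid(duration: float, output_dt: float) -> np.ndarray:
    n = int(round(duration / output_dt))
    if not np.isclose(n * output_dt, duration, rtol=1e-9, atol=1e-12):
        n = int(np.floor(duration / output_dt + 1e-12))
    return np.arange(n + 1) * output_dt


def simulate(
    params: CircuitParams,
    stimulus: StimulusProgram | None = None,
    init: Sequence[float] | None = None,
    duration: float | None = None,
    output_dt: float = 1.0 / 6.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the circuit ODEs and sample on a uniform grid.

    Square-wave/pulse edges are taken as integration breakpoints: the solver
    is restarted at every stimulus discontinuity so edges are not smeared by
    adaptive stepping across them.  Default cadence 1/6 h mirrors a 10-min
    imaging interval.
    """
    if duration is None:
        if stimulus is None:
            raise ValueError("either stimulus or duration must be given")
        duration = stimulus.duration
    if not duration > 0 or not output_dt > 0:
        raise ValueError("duration and output_dt must be positive")
    if init is None:
        init = rest_state(params)
    init = np.asarray(init, dtype=float)
    if np.any(init < 0):
        raise ValueError("initial conditions must be nonnegative")

    grid = _grid(duration, output_dt)
    breaks = stimulus.breakpoints(0.0, duration) if stimulus is not None else np.array([])
    seg_bounds = np.concatenate(([0.0], breaks, [duration]))

    def rhs(t, y):
        return dynamics(y, t, params, stimulus)

    out = np.empty((2, len(grid)))
    out[:, 0] = init
    y = init
    filled = 1
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        if b - a <= 1e-12:
            continue
        sol = solve_ivp(
            rhs, (a, b), y, method=method, dense_output=True, rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SolverError(f"integration failed in [{a:g}, {b:g}] h: {sol.message}", t_fail=float(sol.t[-1]) if len(sol.t) else a)
        y = sol.y[:, -1]
        inside = grid[(grid > a + 1e-12) & (grid <= b + 1e-12)]
        if len(inside):
            out[:, filled : filled + len(inside)] = sol.sol(np.clip(inside, a, b))
            filled += len(inside)
    if filled != len(grid):  # pragma: no cover - grid bookkeeping guard
        raise SolverError(f"output grid misaligned ({filled} of {len(grid)} samples)")

    iacr, marr = out
    low = min(iacr.min(initial=0.0), marr.min(initial=0.0))
    if low < -1e-6 * max(1.0, np.abs(out).max()):
        raise SolverError(f"trajectory went negative (min {low:g})")
    iacr = np.clip(iacr, 0.0, None)
    marr = np.clip(marr, 0.0, None)
    iaa = np.asarray(stimulus.iaa(grid)) if stimulus is not None else np.zeros_like(grid)
    sa = np.asarray(stimulus.sa(grid)) if stimulus is not None else np.zeros_like(grid)
    return Trajectory(time_h=grid, iacr=iacr, marr=marr, iaa=iaa, sa=sa, params=params)


def rest_state(
    params: CircuitParams,
    relax_hours: float | None = None,
    refine: bool = True,
) -> np.ndarray:
    """Unforced rest state: relax from (0, 0), then polish with a root solve.

    For oscillatory parameter sets there is no stable fixed point; the
    returned state is then simply where the relaxation ended (on or near the
    limit cycle), which is still a sensible integration start.
    """
    if relax_hours is None:
        relax_hours = 50.0 / min(params.d1, params.d2)
    relaxed = simulate(
        params.replace(eps_I=0.0, eps_M=0.0),
        stimulus=None,
        init=(0.0, 0.0),
        duration=relax_hours,
        output_dt=relax_hours / 400.0,
    )
    y_end = np.array([relaxed.iacr[-1], relaxed.marr[-1]])
    if refine:
        sol = root(lambda y: dynamics(y, 0.0, params), y_end, tol=1e-12)
        y_fp = sol.x
        if sol.success and np.all(y_fp >= -1e-9) and np.linalg.norm(y_fp - y_end) < 0.2 * (1.0 + np.linalg.norm(y_end)):
            return np.clip(y_fp, 0.0, None)
    return y_end


# --------------------------------------------------------------------------- #
# nullclines and fixed points


def nullclines(params: CircuitParams, iacr_grid: Iterable[float]) -> NullclineSet:
    """Hormone-free nullclines on a grid of IacR values.

    MarR** (the MarR-nullcline) is the closed form
    (a2 + b2·I²/(K_B² + I²)) / d2.  MarR* (the IacR-nullcline) solves
    dIacR/dt = 0 for MarR: (γ·MarR)² = b1·I²/(d1·I − a1) − K_A² − I², defined
    only where d1·I > a1 and the radicand is nonnegative; elsewhere NaN.
    Fixed points are sign changes of dIacR/dt along MarR**, refined by
    bracketed root finding.
    """
    grid = np.asarray(list(iacr_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("iacr_grid must be non-empty")
    p = params

    marr_star2 = (p.a2 + p.b2 * grid**2 / (p.K_B**2 + grid**2)) / p.d2

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = p.d1 * grid - p.a1
        radicand = np.where(denom > 0, p.b1 * grid**2 / denom - p.K_A**2 - grid**2, np.nan)
    if p.gamma > 0:
        marr_star = np.where(radicand >= 0, np.sqrt(np.maximum(radicand, 0.0)) / p.gamma, np.nan)
    else:
        # gamma = 0: MarR does not enter dIacR/dt; nullcline is vertical lines,
        # not a function of IacR — report NaN except where radicand hits zero.
        marr_star = np.where(np.abs(radicand) < 1e-12, 0.0, np.nan)

    def f(i):
        m = (p.a2 + p.b2 * i**2 / (p.K_B**2 + i**2)) / p.d2
        return dynamics((i, m), 0.0, params)[0]

    vals = np.array([f(i) for i in grid])
    fixed: list[tuple[float, float]] = []
    for i0, i1, v0, v1 in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if v0 == 0.0:
            fixed.append((float(i0), float((p.a2 + p.b2 * i0**2 / (p.K_B**2 + i0**2)) / p.d2)))
        elif v0 * v1 < 0:
            i_star = brentq(f, i0, i1, xtol=1e-14, rtol=1e-14)
            m_star = (p.a2 + p.b2 * i_star**2 / (p.K_B**2 + i_star**2)) / p.d2
            fixed.append((float(i_star), float(m_star)))
    if vals[-1] == 0.0:
        i0 = grid[-1]
        fixed.append((float(i0), float((p.a2 + p.b2 * i0**2 / (p.K_B**2 + i0**2)) / p.d2)))

    return NullclineSet(
        iacr_grid=grid, marr_star=marr_star, marr_star2=marr_star2,
        fixed_points=fixed, params=params,
    )


# --------------------------------------------------------------------------- #
# regime classification


def _trajectory_peaks(x: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Internal peak finder for regime diagnostics (prominence-based)."""
    span = float(np.ptp(x))
    if span <= 0:
        return np.array([], dtype=int), np.array([])
    idx, _ = _scipy_find_peaks(x, prominence=0.1 * span)
    return idx, idx * dt


def classify_regime(
    params: CircuitParams,
    perturbation: float = 2.0,
    window_hours: float = 48.0,
    excursion_threshold: float = 3.0,
    oscillation_cv: float = 0.1,
    output_dt: float = 0.02,
) -> RegimeLabel:
    """Label the unforced circuit steady, excitable, or oscillatory.

    Oscillatory: the unforced relaxation from (0, 0) keeps producing ≥3 peaks
    with inter-peak CV < ``oscillation_cv`` and non-vanishing relative
    amplitude in the second half of the window.  Excitable: the unperturbed
    system settles to rest, but kicking IacR up by ``perturbation``
    (relative) triggers a growing excursion whose peak exceeds
    ``excursion_threshold`` × rest IacR before returning to rest.  Steady:
    everything else.

    The default kick is 2.0 (three times the rest level): in this
    two-variable reduction the quasi-threshold lies a factor ~1.4–2 above
    rest wherever the rest state is robustly stable, so smaller kicks probe
    sub-threshold decay rather than excitability (see docs/methods.md).
    """
    if not perturbation > 0:
        raise ValueError("perturbation must be positive")
    free = simulate(params, stimulus=None, init=(0.0, 0.0),
                    duration=window_hours, output_dt=output_dt)
    half = len(free.time_h) // 2
    tail = free.iacr[half:]
    idx, t_pk = _trajectory_peaks(tail, output_dt)
    if len(idx) >= 3:
        intervals = np.diff(t_pk)
        cv = float(np.std(intervals) / np.mean(intervals)) if np.mean(intervals) > 0 else np.inf
        # a damped focus rings regularly too: demand sustained, non-trivial swing
        base = float(tail.min())
        amp_first = float(tail[idx[0]] - base)
        amp_last = float(tail[idx[-1]] - base)
        sustained = amp_last > 0.5 * amp_first
        rel_span = float(np.ptp(tail)) / max(float(np.median(tail)), 1e-12)
        if cv < oscillation_cv and sustained and rel_span > 0.5:
            return RegimeLabel("oscillatory", n_peaks=len(idx), interval_cv=cv, rest=None)

    rest = rest_state(params)
    rest_i = float(rest[0])
    kicked = simulate(
        params, stimulus=None, init=(rest_i * (1.0 + perturbation), rest[1]),
        duration=window_hours, output_dt=output_dt,
    )
    j_peak = int(np.argmax(kicked.iacr))
    peak = float(kicked.iacr[j_peak])
    ratio = peak / rest_i if rest_i > 0 else np.inf
    grows = j_peak > 0  # the excursion must grow beyond the kick itself
    back = (
        abs(kicked.iacr[-1] - rest_i) <= 0.05 * max(rest_i, 1e-12)
        and abs(kicked.marr[-1] - rest[1]) <= 0.05 * max(rest[1], 1e-12)
    )
    if ratio > excursion_threshold and grows and back:
        return RegimeLabel("excitable", excursion_ratio=ratio, returned_to_rest=back,
                           rest=(rest_i, float(rest[1])))
    return RegimeLabel("steady", excursion_ratio=ratio, returned_to_rest=back,
                       rest=(rest_i, float(rest[1])))


def bifurcation_scan(
    base: CircuitParams,
    ratio_grid: Iterable[float],
    mode: str = "vary-d1",
    **classify_kwargs,
) -> list[tuple[float, RegimeLabel]]:
    """Classify the regime along a grid of turnover ratios d1/d2.

    ``vary-d1`` sets d1 = ratio·d2 (d2 from ``base``); ``vary-d2`` sets
    d2 = d1/ratio (d1 from ``base``).
    """
    ratios = np.asarray(list(ratio_grid), dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("turnover ratios must be positive")
    if np.any(np.diff(ratios) < 0):
        raise ValueError("ratio_grid must be sorted ascending")
    out: list[tuple[float, RegimeLabel]] = []
    for r in ratios:
        if mode == "vary-d1":
            p = base.replace(d1=r * base.d2)
        elif mode == "vary-d2":
            p = base.replace(d2=base.d1 / r)
        else:
            raise ValueError("mode must be 'vary-d1' or 'vary-d2'")
        out.append((float(r), classify_regime(p, **classify_kwargs)))
    return out


# --------------------------------------------------------------------------- #
# refractory protocol


def refractory_protocol(
    params: CircuitParams = EXCITABLE_PARAMS,
    pulse_hours: float = 12.0,
    gap_hours: float = 2.0,
    amplitude: float = 1.0,
    lead_hours: float = 2.0,
    tail_hours: float = 8.0,
    output_dt: float = 1.0 / 60.0,
):
    """Two long IAA-only pulses probing the refractory period.

    The excitable circuit responds with one pulse at the *release* of a long
    auxin step (MarR has decayed during the step, so IacR rebounds into a
    derepressed field).  The response to the second release is suppressed
    while MarR raised by the first excursion is still above threshold.

    Returns ``(trajectory, table)`` where ``table`` is a DataFrame with one
    row per pulse: window, peak time, and response amplitude above rest.
    """
    import pandas as pd

    if not pulse_hours > 0 or gap_hours < 0:
        raise ValueError("pulse_hours must be positive and gap_hours nonnegative")
    starts = [lead_hours, lead_hours + pulse_hours + gap_hours]
    pulses = [(s, s + pulse_hours, "IAA") for s in starts]
    duration = starts[-1] + pulse_hours + tail_hours
    stim = StimulusProgram.pulse_list(pulses, duration=duration, iaa_amplitude=amplitude)
    rest = rest_state(params)
    traj = simulate(params, stim, init=rest, duration=duration, output_dt=output_dt)

    windows = [(starts[0], starts[1]), (starts[1], duration)]
    rows = []
    for k, (w0, w1) in enumerate(windows):
        sel = (traj.time_h >= w0) & (traj.time_h <= w1)
        seg = traj.iacr[sel]
        tseg = traj.time_h[sel]
        j = int(np.argmax(seg))
        rows.append(
            {
                "pulse": k + 1,
                "window_start_h": w0,
                "window_end_h": w1,
                "peak_time_h": float(tseg[j]),
                "amplitude": max(float(seg[j] - rest[0]), 0.0),
            }
        )
    return traj, pd.DataFrame(rows)
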