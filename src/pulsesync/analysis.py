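"""Community fluorescence trace analysis.

The processing chain mirrors how pulsatile reporter recordings are reduced in
practice: dual-channel normalisation ``green/(green+red)``, linear
detrending, Savitzky–Golay smoothing (filter length 15), 0–1 rescaling for
heat maps, run-length peak calling (a point is a peak only if preceded by at
least ``nups`` non-decreasing and followed by at least ``ndowns``
non-increasing steps), inter-peak period statistics, cross-community phase
drift, the synchrony index 1 − R (R = mean |phase deviation| over cycles in
units of the expected period), cumulative autocorrelation, and FFT power
spectral density.  :func:`analyze` composes the stages and keeps every
intermediate retrievable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal
from statsmodels.tsa.stattools import acf as _sm_acf

from .traces import CommunityTraces

__all__ = [
    "PeakSet",
    "DriftTable",
    "SynchronyResult",
    "SynchronyReport",
    "PipelineConfig",
    "AnalysisError",
    "normalize_reporter",
    "detrend",
    "smooth",
    "rescale01",
    "find_peaks",
    "periods",
    "phase_drift",
    "synchrony_index",
    "cumulative_autocorrelation",
    "power_spectrum",
    "analyze",
]


class AnalysisError(ValueError):
    """Pipeline-stage failure; the message names the stage."""


# --------------------------------------------------------------------------- #
# elementwise / per-trace stages


def normalize_reporter(green: CommunityTraces, red: CommunityTraces) -> CommunityTraces:
    """Growth-normalised reporter: green/(green+red), elementwise.

    Points where green+red == 0 map to 0; their count is stored under
    ``meta['zero_denominator_count']`` and reported as a warning.
    """
    if green.values.shape != red.values.shape or not np.allclose(green.time_h, red.time_h):
        raise AnalysisError("normalize_reporter: green and red grids/communities do not match")
    if green.communities != red.communities:
        raise AnalysisError("normalize_reporter: community identifiers differ between channels")
    if np.any(red.values < 0):
        raise AnalysisError("normalize_reporter: red channel has negative values")
    denom = green.values + red.values
    zero = denom == 0
    n_zero = int(zero.sum())
    if n_zero:
        warnings.warn(f"normalize_reporter: {n_zero} points with zero green+red set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(zero, 0.0, green.values / np.where(zero, 1.0, denom))
    return green.with_values(out, stage="normalized", zero_denominator_count=n_zero)


def detrend(traces: CommunityTraces) -> CommunityTraces:
    """Remove each community's least-squares straight line."""
    if traces.n_time < 3:
        raise AnalysisError("detrend: need at least 3 time points")
    out = _signal.detrend(traces.values, axis=1, type="linear")
    return traces.with_values(out, stage="detrended")


def smooth(traces: CommunityTraces, window: int = 15, polyorder: int = 4) -> CommunityTraces:
    """Savitzky–Golay smoothing along time (default filter length 15, order 4).

    Edges use the boundary polynomial fits themselves (``mode='interp'``).
    """
    if window % 2 == 0 or window <= polyorder:
        raise AnalysisError("smooth: window must be odd and greater than polyorder")
    if traces.n_time < window:
        raise AnalysisError(f"smooth: series length {traces.n_time} shorter than window {window}")
    out = _signal.savgol_filter(traces.values, window_length=window, polyorder=polyorder,
                                axis=1, mode="interp")
    return traces.with_values(out, stage="smoothed")


def rescale01(traces: CommunityTraces) -> CommunityTraces:
    """Per-community min–max rescaling to [0, 1]; flat traces map to 0."""
    lo = traces.values.min(axis=1, keepdims=True)
    hi = traces.values.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span[:, 0] == 0
    if flat.any():
        warnings.warn(f"rescale01: {int(flat.sum())} flat trace(s) mapped to 0")
    out = np.where(span > 0, (traces.values - lo) / np.where(span == 0, 1.0, span), 0.0)
    return traces.with_values(out, stage="rescaled")


# --------------------------------------------------------------------------- #
# run-length peak detection


@dataclass
class PeakSet:
    """Per-community peak tables from run-length detection."""

    communities: list[str]
    times: list[np.ndarray]          # hours, strictly increasing per community
    heights: list[np.ndarray]        # processed-signal units
    widths: list[np.ndarray]         # hours, full width at half prominence
    prominences: list[np.ndarray]
    nups: int = 6
    ndowns: int = 6

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, t, h, w, p in zip(self.communities, self.times, self.heights,
                                    self.widths, self.prominences):
            for tt, hh, ww, pp in zip(t, h, w, p):
                rows.append({"community": name, "peak_time_h": tt, "height": hh,
                             "width_h": ww, "prominence": pp})
        return pd.DataFrame(rows, columns=["community", "peak_time_h", "height", "width_h", "prominence"])

    @property
    def n_peaks(self) -> int:
        return sum(len(t) for t in self.times)


def _run_lengths(cond: np.ndarray) -> np.ndarray:
    """Length of the maximal True-run ending at each index of ``cond``."""
    idx = np.arange(len(cond))
    last_false = np.maximum.accumulate(np.where(~cond, idx, -1))
    return np.where(cond, idx - last_false, 0)


def peak_indices(x: np.ndarray, nups: int = 6, ndowns: int = 6,
                 min_height: float | None = None) -> np.ndarray:
    """Run-length peak candidates in one series.

    Index i qualifies when the ``nups`` steps into it are all non-decreasing
    and the ``ndowns`` steps out of it are all non-increasing.  Qualifying
    indices connected by a flat stretch (a plateau) collapse to the
    plateau's first sample.
    """
    if nups < 1 or ndowns < 1:
        raise AnalysisError("find_peaks: nups and ndowns must be ≥ 1")
    n = len(x)
    if n < nups + ndowns + 1:
        return np.array([], dtype=int)
    d = np.diff(x)
    up_end = _run_lengths(d >= 0)          # run ending at step j
    down_start = _run_lengths((d <= 0)[::-1])[::-1]  # run starting at step j
    cand = []
    for i in range(nups, n - ndowns):
        if up_end[i - 1] >= nups and down_start[i] >= ndowns:
            if min_height is None or x[i] >= min_height:
                cand.append(i)
    if not cand:
        return np.array([], dtype=int)
    # collapse plateaus: successive candidates joined by zero steps are one peak
    out = [cand[0]]
    for i in cand[1:]:
        if np.all(d[out[-1]:i] == 0):
            continue
        out.append(i)
    return np.array(out, dtype=int)


def find_peaks(
    traces: CommunityTraces,
    nups: int = 6,
    ndowns: int = 6,
    min_height: float | None = None,
) -> PeakSet:
    """Run-length peak detection on every community trace.

    Width is the full width at half prominence, in hours, measured on the
    same processed signal the peaks were called on.
    """
    times, heights, widths, proms = [], [], [], []
    for row in traces.values:
        idx = peak_indices(row, nups=nups, ndowns=ndowns, min_height=min_height)
        if len(idx) == 0:
            times.append(np.array([]))
            heights.append(np.array([]))
            widths.append(np.array([]))
            proms.append(np.array([]))
            continue
        prom = _signal.peak_prominences(row, idx)
        ok = prom[0] > 0
        w = np.full(len(idx), np.nan)
        if ok.any():
            sub = tuple(arr[ok] for arr in prom)
            w_ok = _signal.peak_widths(row, idx[ok], rel_height=0.5, prominence_data=sub)[0]
            w[ok] = w_ok * traces.dt
        times.append(traces.time_h[idx])
        heights.append(row[idx])
        widths.append(w)
        proms.append(prom[0])
    return PeakSet(
        communities=list(traces.communities), times=times, heights=heights,
        widths=widths, prominences=proms, nups=nups, ndowns=ndowns,
    )


# --------------------------------------------------------------------------- #
# period / phase / synchrony statistics


def periods(peaks: PeakSet) -> list[np.ndarray]:
    """Successive inter-peak intervals (hours) per community.

    Communities with fewer than two peaks contribute an empty list.
    """
    return [np.diff(t) if len(t) >= 2 else np.array([]) for t in peaks.times]


@dataclass
class DriftTable:
    """Signed peak-time deviations from the per-cycle reference."""

    communities: list[str]
    cycle_ref_times: np.ndarray       # hours, one per matched cycle
    drift: np.ndarray                 # (n_comm, n_cycles), NaN = unmatched
    expected_period: float
    reference: str = "population"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.drift, index=self.communities,
                          columns=[f"cycle_{k}" for k in range(self.drift.shape[1])])
        df.index.name = "community"
        return df


def _circular_phase(times: np.ndarray, period: float) -> float:
    """Mean phase of peak times on the stimulus circle, in [0, period)."""
    ang = 2.0 * np.pi * times / period
    mean = np.exp(1j * ang).mean()
    return float(np.mod(np.angle(mean) / (2.0 * np.pi) * period, period))


def phase_drift(
    peaks: PeakSet,
    expected_period: float,
    reference: str = "population",
    clock_offset: float | None = None,
) -> DriftTable:
    """Match peaks to stimulus cycles and tabulate signed deviations.

    Cycle references are either the cross-community median peak time per
    cycle (``reference='population'``, default) or a fixed stimulus clock
    ``clock_offset + k·T`` (``reference='clock'``).  A community's peak is
    matched to the nearest cycle reference within half a period; cycles with
    no peak stay NaN.
    """
    T = expected_period
    if not T > 0:
        raise AnalysisError("phase_drift: expected_period must be positive")
    if reference not in ("population", "clock"):
        raise AnalysisError(f"phase_drift: unknown reference {reference!r}")
    all_times = np.concatenate([t for t in peaks.times]) if peaks.times else np.array([])
    n_with = sum(1 for t in peaks.times if len(t))
    if len(all_times) == 0 or n_with < 2:
        warnings.warn("phase_drift: fewer than two communities with peaks; empty table")
        return DriftTable(list(peaks.communities), np.array([]),
                          np.empty((len(peaks.communities), 0)), T, reference)

    phi = clock_offset if clock_offset is not None else _circular_phase(all_times, T)
    k_all = np.round((all_times - phi) / T).astype(int)
    k_min, k_max = int(k_all.min()), int(k_all.max())
    n_cycles = k_max - k_min + 1

    # first pass: provisional per-cycle references
    if reference == "clock":
        refs = phi + (np.arange(k_min, k_max + 1)) * T
    else:
        assigned: list[list[float]] = [[] for _ in range(n_cycles)]
        for t in peaks.times:
            if len(t) == 0:
                continue
            k = np.round((t - phi) / T).astype(int)
            for kk in np.unique(k):
                pick = t[k == kk]
                best = pick[np.argmin(np.abs(pick - (phi + kk * T)))]
                assigned[kk - k_min].append(best)
        refs = np.array([np.median(v) if v else phi + (k_min + j) * T
                         for j, v in enumerate(assigned)])

    # second pass: nearest peak within ±T/2 of each reference
    drift = np.full((len(peaks.communities), n_cycles), np.nan)
    for c, t in enumerate(peaks.times):
        if len(t) == 0:
            continue
        for j, ref in enumerate(refs):
            dev = t - ref
            near = np.argmin(np.abs(dev))
            if np.abs(dev[near]) <= T / 2.0:
                drift[c, j] = dev[near]
    return DriftTable(list(peaks.communities), refs, drift, T, reference)


@dataclass
class SynchronyResult:
    """Per-community synchrony indices 1 − R and population summary."""

    communities: list[str]
    index: np.ndarray                 # in [0, 1]
    r: np.ndarray                     # mean |drift| / T, NaN if unmatched
    flagged: list[str]                # communities with no matched peaks
    median: float
    iqr: float
    drift_table: DriftTable


def synchrony_index(
    peaks: PeakSet,
    expected_period: float,
    reference: str = "population",
    clock_offset: float | None = None,
) -> SynchronyResult:
    """Synchrony index 1 − R per community.

    R is the mean over matched cycles of |peak-time deviation| divided by the
    expected period; the index is clipped at 0.  Communities that never match
    a cycle get index 0 and are flagged.
    """
    table = phase_drift(peaks, expected_period, reference=reference, clock_offset=clock_offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        r = np.nanmean(np.abs(table.drift), axis=1) / expected_period if table.drift.shape[1] else np.full(len(peaks.communities), np.nan)
    flagged = [name for name, rv in zip(peaks.communities, r) if not np.isfinite(rv)]
    index = np.where(np.isfinite(r), np.clip(1.0 - r, 0.0, 1.0), 0.0)
    q25, q75 = np.percentile(index, [25, 75]) if len(index) else (np.nan, np.nan)
    return SynchronyResult(
        communities=list(peaks.communities), index=index, r=r, flagged=flagged,
        median=float(np.median(index)) if len(index) else float("nan"),
        iqr=float(q75 - q25), drift_table=table,
    )


# --------------------------------------------------------------------------- #
# autocorrelation and spectra


@dataclass
class ACFResult:
    lags_h: np.ndarray
    acf: np.ndarray                   # cumulative (cross-community mean) ACF
    per_community: np.ndarray         # (n_included, n_lags+1)
    excluded: list[str]

    @property
    def dominant_period_h(self) -> float:
        """Lag of the highest local maximum at positive lag (NaN if none)."""
        peaks_idx, _ = _signal.find_peaks(self.acf)
        if len(peaks_idx) == 0:
            return float("nan")
        best = peaks_idx[np.argmax(self.acf[peaks_idx])]
        return float(self.lags_h[best])

    @property
    def dominant_peak_value(self) -> float:
        peaks_idx, _ = _signal.find_peaks(self.acf)
        return float(self.acf[peaks_idx].max()) if len(peaks_idx) else float("nan")


def cumulative_autocorrelation(traces: CommunityTraces, max_lag: float) -> ACFResult:
    """Cross-community mean of per-trace normalized autocorrelations.

    Each community's mean-centred trace is autocorrelated with the biased
    (divide-by-n) estimator and normalized to 1 at lag zero; the cumulative
    curve is the average over communities.  Constant traces are excluded.
    """
    if not max_lag < traces.duration / 2:
        raise AnalysisError("cumulative_autocorrelation: max_lag must be < duration/2")
    nlags = int(round(max_lag / traces.dt))
    rows, excluded = [], []
    for name, row in zip(traces.communities, traces.values):
        if np.ptp(row) == 0:
            excluded.append(name)
            continue
        rows.append(_sm_acf(row - row.mean(), nlags=nlags, fft=True, adjusted=False))
    if not rows:
        raise AnalysisError("cumulative_autocorrelation: all traces constant")
    if excluded:
        warnings.warn(f"cumulative_autocorrelation: excluded constant trace(s) {excluded}")
    per = np.asarray(rows)
    return ACFResult(
        lags_h=np.arange(nlags + 1) * traces.dt, acf=per.mean(axis=0),
        per_community=per, excluded=excluded,
    )


@dataclass
class PSDResult:
    freq_per_h: np.ndarray
    power: np.ndarray                 # cross-community mean PSD
    per_community: np.ndarray

    @property
    def dominant_period_h(self) -> float:
        """1 / argmax frequency of the mean PSD, zero frequency excluded."""
        if len(self.freq_per_h) < 2:
            return float("nan")
        j = 1 + int(np.argmax(self.power[1:]))
        f = self.freq_per_h[j]
        return float(1.0 / f) if f > 0 else float("nan")


def power_spectrum(traces: CommunityTraces) -> PSDResult:
    """Mean periodogram (PSD) of the mean-centred community traces."""
    if traces.n_time < 8:
        raise AnalysisError("power_spectrum: need at least 8 time points")
    centred = traces.values - traces.values.mean(axis=1, keepdims=True)
    freq, pxx = _signal.periodogram(centred, fs=1.0 / traces.dt, axis=1,
                                    detrend=False, scaling="density")
    return PSDResult(freq_per_h=freq, power=pxx.mean(axis=0), per_community=pxx)


# --------------------------------------------------------------------------- #
# full pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults of the composed analysis chain."""

    window: int = 15
    polyorder: int = 4
    nups: int = 6
    ndowns: int = 6
    min_height: float = 0.2           # on the 0–1 rescaled signal
    reference: str = "population"     # synchrony reference: population | clock
    clock_offset: float | None = None
    max_lag_periods: float = 3.0      # ACF lag range, in units of the expected period
    organized_threshold: float = 0.2  # dominant ACF peak below this ⇒ unstructured


@dataclass
class SynchronyReport:
    """Everything the pipeline measures on one recording."""

    expected_period: float
    config: PipelineConfig
    peak_set: PeakSet
    periods_by_community: list[np.ndarray]
    period_median: float
    period_iqr: float
    amplitudes: list[np.ndarray]      # smoothed-signal heights at the called peaks
    synchrony: SynchronyResult
    acf: ACFResult
    psd: PSDResult
    organized: bool
    flags: list[str]
    stages: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        """JSON-ready summary (scalars + plain lists)."""
        return {
            "expected_period_h": self.expected_period,
            "n_communities": len(self.peak_set.communities),
            "n_peaks": self.peak_set.n_peaks,
            "period_median_h": self.period_median,
            "period_iqr_h": self.period_iqr,
            "synchrony_index": [float(v) for v in self.synchrony.index],
            "synchrony_median": self.synchrony.median,
            "synchrony_iqr": self.synchrony.iqr,
            "acf_dominant_period_h": self.acf.dominant_period_h,
            "acf_dominant_peak": self.acf.dominant_peak_value,
            "psd_dominant_period_h": self.psd.dominant_period_h,
            "organized": bool(self.organized),
            "flags": list(self.flags),
            "acf": {"lags_h": self.acf.lags_h.tolist(), "values": self.acf.acf.tolist()},
            "psd": {"freq_per_h": self.psd.freq_per_h.tolist(), "power": self.psd.power.tolist()},
            "peaks": self.peak_set.to_frame().to_dict(orient="list"),
        }


def analyze(
    traces: CommunityTraces,
    expected_period: float,
    config: PipelineConfig = PipelineConfig(),
    red: CommunityTraces | None = None,
) -> SynchronyReport:
    """Run the full chain: (normalise) → detrend → smooth → rescale → peaks → stats.

    Amplitude statistics are read off the smoothed (pre-rescale) signal at the
    called peak positions, since min–max rescaling destroys amplitude
    information; detection itself runs on the rescaled signal so the height
    threshold is scale-free.
    """
    stages: dict = {"raw": traces}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except AnalysisError:
            raise
        except Exception as exc:
            raise AnalysisError(f"{name}: {exc}") from exc

    work = traces
    if red is not None:
        work = _stage("normalize_reporter", normalize_reporter, work, red)
        stages["normalized"] = work
    detrended = _stage("detrend", detrend, work)
    stages["detrended"] = detrended
    smoothed = _stage("smooth", smooth, detrended, window=config.window, polyorder=config.polyorder)
    stages["smoothed"] = smoothed
    rescaled = _stage("rescale01", rescale01, smoothed)
    stages["rescaled"] = rescaled

    peaks = _stage("find_peaks", find_peaks, rescaled, nups=config.nups,
                   ndowns=config.ndowns, min_height=config.min_height)
    stages["peaks"] = peaks

    pers = periods(peaks)
    pooled = np.concatenate(pers) if any(len(p) for p in pers) else np.array([])
    flags = []
    n_short = sum(1 for t in peaks.times if len(t) < 2)
    if n_short:
        flags.append(f"{n_short} communities with fewer than 2 peaks")

    # amplitudes on the smoothed signal at the detected peak times
    amplitudes = []
    for row, t in zip(smoothed.values, peaks.times):
        idx = np.searchsorted(smoothed.time_h, t)
        amplitudes.append(row[np.clip(idx, 0, smoothed.n_time - 1)])

    sync = _stage("synchrony_index", synchrony_index, peaks, expected_period,
                  reference=config.reference, clock_offset=config.clock_offset)
    max_lag = min(config.max_lag_periods * expected_period,
                  traces.duration / 2 - traces.dt)
    acf_res = _stage("cumulative_autocorrelation", cumulative_autocorrelation, smoothed, max_lag)
    psd_res = _stage("power_spectrum", power_spectrum, smoothed)

    organized = (
        np.isfinite(acf_res.dominant_peak_value)
        and acf_res.dominant_peak_value >= config.organized_threshold
    )
    if not organized:
        flags.append("unstructured")

    q = np.percentile(pooled, [25, 75]) if len(pooled) else (np.nan, np.nan)
    return SynchronyReport(
        expected_period=expected_period,
        config=config,
        peak_set=peaks,
        periods_by_community=pers,
        period_median=float(np.median(pooled)) if len(pooled) else float("nan"),
        period_iqr=float(q[1] - q[0]) if len(pooled) else float("nan"),
        amplitudes=amplitudes,
        synchrony=sync,
        acf=acf_res,
        psd=psd_res,
        organized=bool(organized),
        flags=flags,
        stages=stages,
    )
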