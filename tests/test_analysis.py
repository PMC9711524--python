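import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulsesync import (
    PRESETS,
    analyze,
    cumulative_autocorrelation,
    detrend,
    find_peaks,
    generate_traces,
    normalize_reporter,
    periods,
    phase_drift,
    power_spectrum,
    rescale01,
    smooth,
    synchrony_index,
)
from pulsesync.analysis import AnalysisError, PeakSet, peak_indices
from conftest import make_traces


def brute_force_peaks(x, nups, ndowns, min_height=None):
    """Exhaustive run-length scanner (oracle for peak_indices)."""
    d = np.diff(x)
    cand = []
    for i in range(1, len(x) - 1):
        up = 0
        j = i - 1
        while j >= 0 and d[j] >= 0:
            up += 1
            j -= 1
        down = 0
        j = i
        while j < len(d) and d[j] <= 0:
            down += 1
            j += 1
        if up >= nups and down >= ndowns and (min_height is None or x[i] >= min_height):
            cand.append(i)
    out = []
    for i in cand:
        if out and np.all(d[out[-1]:i] == 0):
            continue
        out.append(i)
    return np.array(out, dtype=int)


class TestNormalizeReporter:
    def test_equal_channels_give_half(self, random_traces):
        green = make_traces(np.abs(random_traces.values) + 1.0)
        out = normalize_reporter(green, green)
        assert np.allclose(out.values, 0.5)

    def test_zero_green_gives_zero(self, random_traces):
        red = make_traces(np.abs(random_traces.values) + 1.0)
        green = red.with_values(np.zeros_like(red.values))
        assert np.allclose(normalize_reporter(green, red).values, 0.0)

    def test_matches_elementwise_oracle_and_stays_in_unit_interval(self, rng):
        g = make_traces(rng.uniform(0.1, 5.0, size=(4, 60)))
        r = make_traces(rng.uniform(0.1, 5.0, size=(4, 60)))
        out = normalize_reporter(g, r)
        assert np.allclose(out.values, g.values / (g.values + r.values))
        assert out.values.min() >= 0 and out.values.max() <= 1

    def test_zero_denominator_counted(self, rng):
        g = make_traces(np.zeros((1, 30)))
        r = make_traces(np.zeros((1, 30)))
        with pytest.warns(UserWarning, match="zero"):
            out = normalize_reporter(g, r)
        assert out.meta["zero_denominator_count"] == 30

    def test_grid_mismatch_rejected(self, rng):
        g = make_traces(rng.uniform(1, 2, (2, 50)))
        r = make_traces(rng.uniform(1, 2, (2, 40)))
        with pytest.raises(AnalysisError):
            normalize_reporter(g, r)


class TestDetrend:
    def test_exact_line_maps_to_zero(self):
        t = np.arange(100) / 6.0
        traces = make_traces(np.vstack([3.0 + 0.5 * t, -1.0 + 2.0 * t]))
        out = detrend(traces)
        assert np.abs(out.values).max() < 1e-10 * 100

    def test_residuals_orthogonal_to_line_basis(self, random_traces):
        out = detrend(random_traces)
        t = random_traces.time_h
        scale = np.abs(random_traces.values).max()
        for row in out.values:
            assert abs(row.sum()) < 1e-8 * scale * len(t)
            assert abs(row @ t) < 1e-8 * scale * len(t) * t.max()

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=(1, 80))
        traces = make_traces(x)
        t = traces.time_h
        A = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.lstsq(A, x[0], rcond=None)[0]
        assert np.allclose(detrend(traces).values[0], x[0] - A @ beta, atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(AnalysisError):
            detrend(make_traces([[1.0, 2.0]]))


class TestSmooth:
    def test_polynomial_reproduced_exactly(self):
        t = np.arange(60) / 6.0
        poly = 1.0 - 2 * t + 0.3 * t**2 - 0.01 * t**3 + 0.001 * t**4
        out = smooth(make_traces(poly[None, :]), window=15, polyorder=4)
        assert np.allclose(out.values[0], poly, atol=1e-8 * np.abs(poly).max())

    def test_constant_unchanged(self):
        out = smooth(make_traces(np.full((2, 40), 7.0)))
        assert np.allclose(out.values, 7.0)

    def test_interior_point_matches_windowed_fit_oracle(self, rng):
        x = rng.normal(size=100)
        out = smooth(make_traces(x[None, :]), window=15, polyorder=4)
        for i in (20, 50, 77):
            idx = np.arange(i - 7, i + 8)
            coef = np.polynomial.polynomial.polyfit(idx - i, x[idx], 4)
            assert out.values[0, i] == pytest.approx(coef[0], abs=1e-8)

    @pytest.mark.parametrize("window,polyorder", [(14, 4), (15, 15), (5, 6)])
    def test_bad_filter_parameters_rejected(self, window, polyorder):
        with pytest.raises(AnalysisError):
            smooth(make_traces(np.zeros((1, 40))), window=window, polyorder=polyorder)


class TestRescale01:
    def test_simple_example(self):
        out = rescale01(make_traces([[2.0, 4.0, 6.0]]))
        assert np.allclose(out.values[0], [0.0, 0.5, 1.0])

    def test_idempotent(self, random_traces):
        once = rescale01(random_traces)
        twice = rescale01(once)
        assert np.allclose(once.values, twice.values)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50, unique=True))
    def test_range_and_order_preserved(self, vals):
        traces = make_traces(np.array(vals)[None, :])
        out = rescale01(traces).values[0]
        assert out.min() == 0.0 and out.max() == pytest.approx(1.0)
        # order-preserving up to float-precision ties
        order = np.argsort(vals, kind="stable")
        assert np.all(np.diff(out[order]) >= 0)

    def test_flat_trace_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            out = rescale01(make_traces(np.full((1, 10), 3.0)))
        assert np.allclose(out.values, 0.0)


class TestFindPeaks:
    def test_monotone_trace_has_no_peaks(self):
        assert len(peak_indices(np.arange(50.0), 6, 6)) == 0

    def test_six_up_six_down_bump_is_detected_five_is_not(self):
        # descending guards on both sides so the run counts are exact
        guard = np.arange(8.0, 0.0, -1.0)               # strictly falling
        rise6 = np.arange(1.0, 8.0)                     # 6 rising steps
        rise5 = np.arange(3.0, 8.0)                     # 5 rising steps
        fall6 = np.arange(6.0, -1.0, -1.0)              # 6 falling steps
        bump6 = np.concatenate([guard, rise6, fall6, guard[::-1]])
        apex = len(guard) + len(rise6) - 1
        assert list(peak_indices(bump6, 6, 6)) == [apex]
        bump5 = np.concatenate([guard, rise5, fall6, guard[::-1]])
        assert len(peak_indices(bump5, 6, 6)) == 0

    def test_matches_brute_force_oracle_on_random_traces(self, rng):
        for _ in range(60):
            n = int(rng.integers(30, 200))
            x = np.round(np.cumsum(rng.normal(size=n)), 1)  # ties occur
            for nups, ndowns in ((6, 6), (3, 2), (1, 1)):
                got = peak_indices(x, nups, ndowns)
                want = brute_force_peaks(x, nups, ndowns)
                assert np.array_equal(got, want), (nups, ndowns)

    def test_min_height_filters(self, rng):
        x = np.sin(np.arange(300) * 0.1)
        lo = peak_indices(x, 6, 6, min_height=None)
        hi = peak_indices(x, 6, 6, min_height=2.0)
        assert len(lo) > 0 and len(hi) == 0

    def test_peakset_fields_consistent(self, cosine_traces):
        ps = find_peaks(cosine_traces, nups=3, ndowns=3)
        assert ps.n_peaks > 0
        for t, h, w in zip(ps.times, ps.heights, ps.widths):
            assert np.all(np.diff(t) > 0)
            assert np.all(w[np.isfinite(w)] > 0)
        df = ps.to_frame()
        assert list(df.columns) == ["community", "peak_time_h", "height", "width_h", "prominence"]


class TestPeriodStatistics:
    def _peakset(self, times_lists):
        return PeakSet(
            communities=[f"c{i}" for i in range(len(times_lists))],
            times=[np.asarray(t, dtype=float) for t in times_lists],
            heights=[np.ones(len(t)) for t in times_lists],
            widths=[np.ones(len(t)) for t in times_lists],
            prominences=[np.ones(len(t)) for t in times_lists],
        )

    def test_periods_are_first_differences(self):
        ps = self._peakset([[0.0, 2.0, 4.0], [1.0]])
        out = periods(ps)
        assert np.allclose(out[0], [2.0, 2.0])
        assert len(out[1]) == 0

    def test_identical_trains_have_zero_drift_and_unit_synchrony(self):
        train = [0.5, 2.5, 4.5, 6.5]
        ps = self._peakset([train, train, train])
        table = phase_drift(ps, expected_period=2.0)
        assert np.allclose(table.drift[~np.isnan(table.drift)], 0.0)
        sync = synchrony_index(ps, expected_period=2.0)
        assert np.allclose(sync.index, 1.0)
        assert sync.median == 1.0

    def test_half_period_offset_gives_half_index(self):
        # one community always deviates T/2 from the fixed stimulus clock
        ps = self._peakset([[0.0, 2.0, 4.0, 6.0], [1.0, 3.0, 5.0, 7.0]])
        sync = synchrony_index(ps, expected_period=2.0, reference="clock", clock_offset=0.0)
        assert sync.index[0] == pytest.approx(1.0)
        assert sync.index[1] == pytest.approx(0.5)

    def test_symmetric_offset_splits_about_median_reference(self):
        delta = 0.3
        ps = self._peakset([[2.0 - delta / 2, 4.0 - delta / 2],
                            [2.0 + delta / 2, 4.0 + delta / 2]])
        table = phase_drift(ps, expected_period=2.0)
        assert np.allclose(np.abs(table.drift), delta / 2)

    def test_drift_matches_brute_force_matcher(self, rng):
        T = 2.0
        trains = [np.sort(k * T + rng.normal(0, 0.15, size=6)) for k in range(5)]
        trains = [t - t.min() + rng.uniform(0, 0.3) + 1.0 for t in trains]
        ps = self._peakset(trains)
        table = phase_drift(ps, expected_period=T)
        for c, t in enumerate(ps.times):
            for j, ref in enumerate(table.cycle_ref_times):
                dev = t - ref
                near = np.argmin(np.abs(dev))
                want = dev[near] if abs(dev[near]) <= T / 2 else np.nan
                got = table.drift[c, j]
                assert (np.isnan(got) and np.isnan(want)) or got == pytest.approx(want)

    def test_no_peaks_yields_flagged_empty_result(self):
        ps = self._peakset([[], []])
        with pytest.warns(UserWarning):
            sync = synchrony_index(ps, expected_period=2.0)
        assert np.allclose(sync.index, 0.0)
        assert set(sync.flagged) == {"c0", "c1"}


class TestAutocorrelation:
    def test_cosine_acf_peaks_at_its_period(self, cosine_traces):
        res = cumulative_autocorrelation(cosine_traces, max_lag=6.0)
        assert res.acf[0] == pytest.approx(1.0)
        assert res.dominant_period_h == pytest.approx(2.0, abs=cosine_traces.dt)
        lag_idx = int(round(2.0 / cosine_traces.dt))
        assert res.acf[lag_idx] > 0.9

    def test_matches_direct_lag_sum_oracle(self, rng):
        x = rng.normal(size=(3, 120))
        traces = make_traces(x)
        res = cumulative_autocorrelation(traces, max_lag=3.0)
        nlags = int(round(3.0 / traces.dt))
        for c in range(3):
            xc = x[c] - x[c].mean()
            denom = (xc**2).sum()
            for k in range(nlags + 1):
                direct = (xc[: len(xc) - k] * xc[k:]).sum() / denom
                assert res.per_community[c, k] == pytest.approx(direct, abs=1e-10)

    def test_white_noise_acf_within_sampling_bound(self, rng):
        n = 400
        traces = make_traces(rng.normal(size=(12, n)))
        res = cumulative_autocorrelation(traces, max_lag=traces.dt * 40)
        assert np.abs(res.acf[1:]).max() < 3.0 / np.sqrt(n)

    def test_constant_trace_excluded_with_warning(self, rng):
        vals = np.vstack([np.full(100, 2.0), rng.normal(size=100)])
        with pytest.warns(UserWarning, match="constant"):
            res = cumulative_autocorrelation(make_traces(vals), max_lag=2.0)
        assert res.excluded == ["c01"]

    def test_excessive_lag_rejected(self, random_traces):
        with pytest.raises(AnalysisError):
            cumulative_autocorrelation(random_traces, max_lag=random_traces.duration)


class TestPowerSpectrum:
    def test_sine_dominant_period(self):
        t = np.arange(0, 24, 1 / 6)
        traces = make_traces(np.sin(2 * np.pi * t / 2.0)[None, :])
        res = power_spectrum(traces)
        assert res.dominant_period_h == pytest.approx(2.0, rel=0.05)

    def test_parseval_identity(self, rng):
        x = rng.normal(size=(2, 128))
        traces = make_traces(x)
        res = power_spectrum(traces)
        df = res.freq_per_h[1] - res.freq_per_h[0]
        for c in range(2):
            xc = x[c] - x[c].mean()
            total = res.per_community[c].sum() * df
            assert total == pytest.approx((xc**2).mean(), rel=1e-8)

    def test_constant_trace_has_no_power(self):
        res = power_spectrum(make_traces(np.full((1, 64), 5.0)))
        assert np.allclose(res.power[1:], 0.0)


class TestAnalyzePipeline:
    def test_report_matches_manual_stage_composition(self):
        cfg = PRESETS["closed_loop"].replace(seed=2, n_communities=6, duration=24.0)
        traces = generate_traces(cfg)
        report = analyze(traces, expected_period=2.0)
        manual = rescale01(smooth(detrend(traces), window=15, polyorder=4))
        ps = find_peaks(manual, nups=6, ndowns=6, min_height=0.2)
        assert all(np.array_equal(a, b) for a, b in zip(report.peak_set.times, ps.times))
        sync = synchrony_index(ps, 2.0)
        assert np.allclose(report.synchrony.index, sync.index)
        assert np.allclose(report.stages["rescaled"].values, manual.values)

    def test_stage_count_and_community_preservation(self):
        cfg = PRESETS["closed_loop"].replace(seed=2, n_communities=5, duration=12.0)
        traces = generate_traces(cfg)
        report = analyze(traces, expected_period=2.0)
        for stage in ("detrended", "smoothed", "rescaled"):
            assert report.stages[stage].values.shape == traces.values.shape
            assert report.stages[stage].communities == traces.communities

    def test_report_serialises_to_plain_json(self):
        import json

        cfg = PRESETS["closed_loop"].replace(seed=1, n_communities=4, duration=12.0)
        report = analyze(generate_traces(cfg), expected_period=2.0)
        blob = json.dumps(report.to_dict())
        assert "period_median_h" in blob
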