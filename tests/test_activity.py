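"""AE activity pipeline: filtering, windowed rates, smoothing, peak, Ψ."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavitrace import (
    AESeries,
    RateSeries,
    compute_rate_series,
    estimate_pmaxrate,
    filter_hits,
    find_max_rate_time,
    interpolate_psi,
    smooth_rates,
)

from conftest import make_psi, make_series


class TestFilterHits:
    def test_threshold_is_inclusive(self):
        s = make_series([1, 2, 3], amps=[44.9, 45.0, 60.0])
        assert len(filter_hits(s)) == 2

    def test_threshold_zero_is_identity(self):
        s = make_series([1, 2, 3], amps=[44.9, 45.0, 60.0])
        assert len(filter_hits(s, 0.0)) == 3

    def test_count_matches_linear_scan(self, rng):
        amps = rng.uniform(35, 99, 1000)
        s = make_series(np.arange(1000) / 10.0, amps=amps)
        expected = int(sum(1 for a in amps if a >= 50.0))
        assert len(filter_hits(s, 50.0)) == expected


class TestRateSeries:
    def test_uniform_stream_interior_rate_is_one(self):
        s = make_series(np.arange(60), t_end_min=60)
        r = compute_rate_series(s)
        interior = (r.grid_times_min >= 7.5) & (r.grid_times_min <= 52.5)
        assert np.allclose(r.raw_rate[interior], 1.0)

    def test_no_hits_gives_zero_rate(self):
        s = AESeries(hits=[], t_end_s=3600.0)
        r = compute_rate_series(s)
        assert np.all(r.raw_rate == 0.0)

    def test_duration_shorter_than_window_errors(self):
        s = make_series([1.0, 2.0], t_end_min=10)
        with pytest.raises(ValueError, match="shorter window"):
            compute_rate_series(s)

    def test_matches_interval_counting_oracle(self, rng):
        times = np.sort(rng.uniform(0, 120, 500))
        s = make_series(times, t_end_min=120)
        r = compute_rate_series(s)
        t_end = 120.0
        for g in rng.choice(np.arange(20, 101), 20, replace=False):
            lo, hi = max(g - 7.5, 0.0), min(g + 7.5, t_end)
            count = int(np.sum((times >= lo) & (times <= hi)))
            assert r.raw_rate[int(g)] == pytest.approx(count / (hi - lo))

    def test_window_count_conserves_total(self, rng):
        # each interior hit is counted in exactly window_min windows
        times = rng.uniform(20, 100, 300)  # away from boundaries, irrational offsets
        s = make_series(times, t_end_min=120)
        r = compute_rate_series(s)
        assert np.sum(r.raw_rate) == pytest.approx(15.0 * len(times) / 15.0 * 1.0)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        r = RateSeries(np.arange(30.0), np.full(30, 4.2))
        sm = smooth_rates(r)
        assert np.allclose(sm.smoothed_rate, 4.2)

    def test_degree5_polynomial_reproduced_exactly(self):
        t = np.arange(40.0)
        # positive degree-5 polynomial on the grid
        y = 1e-6 * (t - 5) ** 5 + 0.01 * t**2 + 5.0
        y = y - y.min() + 1.0
        sm = smooth_rates(RateSeries(t, y))
        assert np.allclose(sm.smoothed_rate, y, atol=1e-8)

    def test_delta_spike_matches_convolution_weight_oracle(self):
        from scipy.signal import savgol_coeffs

        y = np.zeros(41)
        y[20] = 10.0
        with pytest.warns(UserWarning, match="floored"):
            sm = smooth_rates(
                RateSeries(np.arange(41.0), y), sg_order=2, sg_window=7
            )
        kernel = savgol_coeffs(7, 2)
        expected = np.maximum(np.convolve(y, kernel, mode="same"), 0.0)
        assert np.allclose(sm.smoothed_rate[5:-5], expected[5:-5], atol=1e-12)
        # interior kernel weights sum to 1, so before flooring the spike's
        # total mass is preserved
        assert kernel.sum() == pytest.approx(1.0)

    def test_invalid_window_errors(self):
        r = RateSeries(np.arange(30.0), np.ones(30))
        with pytest.raises(ValueError, match="odd"):
            smooth_rates(r, sg_order=5, sg_window=6)
        short = RateSeries(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError, match="raw-rate"):
            smooth_rates(short)


class TestPeak:
    def test_triangle_peak(self):
        t = np.arange(81.0)
        y = np.maximum(0.0, 40.0 - np.abs(t - 40))
        r = smooth_rates(RateSeries(t, y))
        assert find_max_rate_time(r) == pytest.approx(40.0, abs=1.0)

    def test_equal_maxima_earliest_wins(self):
        t = np.arange(121.0)
        y = np.zeros(121)
        r = RateSeries(t, y)
        sm = np.zeros(121)
        sm[30] = sm[90] = 5.0
        r.smoothed_rate = sm
        assert find_max_rate_time(r) == 30.0

    def test_all_zero_errors(self):
        r = RateSeries(np.arange(30.0), np.zeros(30))
        r.smoothed_rate = np.zeros(30)
        with pytest.raises(ValueError, match="no acoustic activity"):
            find_max_rate_time(r)

    def test_bimodal_matches_argmax_oracle(self, rng):
        t = np.arange(200.0)
        y = 10 * np.exp(-((t - 60) ** 2) / 200) + 6 * np.exp(
            -((t - 160) ** 2) / 50
        )
        y += rng.normal(0, 0.2, t.size).clip(-0.5, 0.5)
        y = np.maximum(y, 0)
        sm = smooth_rates(RateSeries(t, y))
        assert find_max_rate_time(sm) == t[int(np.argmax(sm.smoothed_rate))]
        assert abs(find_max_rate_time(sm) - 60.0) < 10


class TestInterpolatePsi:
    def test_midpoint_and_qc(self):
        psi = make_psi([(0, -1.0), (100, -3.0)])
        value, qc, bracketing = interpolate_psi(psi, 50.0)
        assert value == pytest.approx(-2.0)
        assert qc is False  # 1.0 MPa from the nearest reading
        assert bracketing == ((0.0, -1.0), (6000.0, -3.0))

    def test_time_on_reading_returns_it_exactly(self):
        psi = make_psi([(0, -1.0), (50, -2.2), (100, -3.0)])
        value, qc, _ = interpolate_psi(psi, 50.0)
        assert value == -2.2
        assert qc is True

    def test_outside_span_errors(self):
        psi = make_psi([(10, -1.0), (100, -3.0)])
        with pytest.raises(ValueError, match="extrapolate"):
            interpolate_psi(psi, 5.0)
        with pytest.raises(ValueError, match="extrapolate"):
            interpolate_psi(psi, 101.0)

    def test_dense_readings_match_oracle(self, rng):
        times = np.arange(0, 301, 10.0)
        values = -0.5 - 0.01 * times - 1e-5 * times**2
        psi = make_psi(list(zip(times, values)))
        for t in rng.uniform(0, 300, 25):
            expected = float(np.interp(t, times, values))
            got, qc, _ = interpolate_psi(psi, t)
            assert got == pytest.approx(expected, abs=1e-12)
            assert qc is True  # readings every 10 min on a smooth curve


@st.composite
def psi_query(draw):
    n = draw(st.integers(min_value=2, max_value=8))
    times = sorted(
        draw(
            st.lists(
                st.floats(0, 500, allow_nan=False),
                min_size=n,
                max_size=n,
                unique=True,
            )
        )
    )
    values = sorted(
        draw(
            st.lists(
                st.floats(-9, 0, allow_nan=False), min_size=n, max_size=n
            )
        ),
        reverse=True,
    )
    t = draw(st.floats(min_value=times[0], max_value=times[-1]))
    return list(zip(times, values)), t


@given(psi_query())
@settings(max_examples=60, deadline=None)
def test_interpolated_psi_lies_between_bracketing_readings(case):
    readings, t = case
    psi = make_psi(readings)
    value, _, (lo, hi) = interpolate_psi(psi, t)
    assert min(lo[1], hi[1]) - 1e-9 <= value <= max(lo[1], hi[1]) + 1e-9


class TestEstimatePmaxrate:
    def _stream(self, rng, center_min=60.0, spread_min=8.0, n=4000):
        times = rng.normal(center_min, spread_min, n)
        times = times[(times > 0) & (times < 120)]
        return make_series(times, amps=rng.uniform(46, 90, len(times)), t_end_min=120)

    def test_recovers_event_concentration(self, rng):
        # events concentrated where Ψ crosses -3.0 under linear drying
        s = self._stream(rng)
        psi = make_psi([(t, -0.05 * t) for t in range(0, 121, 10)])
        res = estimate_pmaxrate(s, psi)
        assert res.pmaxrate_mpa == pytest.approx(-3.0, abs=0.3)
        assert res.peak_rate > 0
        lo, hi = res.bracketing_readings
        assert min(lo[1], hi[1]) <= res.pmaxrate_mpa <= max(lo[1], hi[1])

    def test_equivariant_under_psi_shift(self, rng):
        s = self._stream(rng)
        psi0 = make_psi([(t, -0.05 * t) for t in range(0, 121, 10)])
        psi1 = make_psi([(t, -0.05 * t - 1.0) for t in range(0, 121, 10)])
        r0 = estimate_pmaxrate(s, psi0)
        r1 = estimate_pmaxrate(s, psi1)
        assert r1.pmaxrate_mpa == pytest.approx(r0.pmaxrate_mpa - 1.0, abs=1e-9)
        assert r1.t_max_min == r0.t_max_min

    def test_invariant_under_joint_time_rescaling(self, rng):
        times = rng.normal(60.0, 8.0, 4000)
        times = times[(times > 0) & (times < 120)]
        amps = rng.uniform(46, 90, len(times))
        s0 = make_series(times, amps=amps, t_end_min=120)
        s1 = make_series(2 * times, amps=amps, t_end_min=240)
        psi0 = make_psi([(t, -0.05 * t) for t in range(0, 121, 10)])
        psi1 = make_psi([(2 * t, -0.05 * t) for t in range(0, 121, 10)])
        r0 = estimate_pmaxrate(s0, psi0)
        r1 = estimate_pmaxrate(s1, psi1)
        # slower drying: same Ψ at the peak within the grid resolution
        assert r1.pmaxrate_mpa == pytest.approx(r0.pmaxrate_mpa, abs=0.15)

    def test_late_burst_below_peak_does_not_move_t_max(self, rng):
        s = self._stream(rng)
        psi = make_psi([(t, -0.05 * t) for t in range(0, 121, 10)])
        r0 = estimate_pmaxrate(s, psi)
        # append a late burst whose smoothed height stays below the main peak
        burst = rng.uniform(100.0, 115.0, int(r0.peak_rate * 15 * 0.4))
        times = np.concatenate([s.times_s / 60.0, burst])
        amps = np.concatenate(
            [s.amplitudes_db, rng.uniform(46, 90, len(burst))]
        )
        s1 = make_series(times, amps=amps, t_end_min=120)
        r1 = estimate_pmaxrate(s1, psi)
        assert r1.rates.smoothed_rate[105] < r0.peak_rate
        assert r1.t_max_min == r0.t_max_min

    def test_empty_after_filter_refuses(self):
        s = make_series([1, 2, 3], amps=[40, 41, 42], t_end_min=60)
        psi = make_psi([(0, -0.5), (60, -3.0)])
        with pytest.raises(ValueError, match="no hits at or above"):
            estimate_pmaxrate(s, psi)

    def test_stage_errors_are_labelled(self, rng):
        s = self._stream(rng)
        psi = make_psi([(118, -5.9), (120, -6.0)])  # span misses the peak
        with pytest.raises(ValueError, match="interpolation failed"):
            estimate_pmaxrate(s, psi)
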