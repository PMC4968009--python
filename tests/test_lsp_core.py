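import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from movelsp import (
    MovementModelSpec,
    PeriodicMean,
    SampleGrid,
    SpectralSummary,
    TrackSeries,
    average_periodograms,
    build_sample_grid,
    classify_harmonics,
    combine_individuals,
    dft_periodogram,
    fast_lsp,
    fit_loglog_slope,
    frequency_grid,
    local_maxima,
    lsq_lsp,
    prewhitened_lsp,
    schedule_periodogram,
    simulate_batch,
    simulate_track,
)
from oracle_utils import naive_dft_power

HOUR = 3600.0
DAY = 86400.0


def make_grid(values, w=None, dt=HOUR):
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] < values.shape[1]:
        values = values.T
    n = values.shape[0]
    w = np.ones(n) if w is None else np.asarray(w, float)
    return SampleGrid(t1=0.0, dt=dt, n=n, w=w, wx=w[:, None] * values)


class TestFrequencyGrid:
    def test_hourly_thousand_sample_grid(self):
        g = make_grid(np.zeros(1000))
        fg = frequency_grid(g)
        assert fg.nyquist == pytest.approx(0.5 / HOUR)
        assert fg.df == pytest.approx(1e-3 / HOUR)
        assert fg.freqs.size == 500
        assert fg.freqs[-1] == pytest.approx(fg.nyquist)

    def test_oversampling_doubles_points_same_nyquist(self):
        g = make_grid(np.zeros(1000))
        f1, f2 = frequency_grid(g, 1), frequency_grid(g, 2)
        assert f2.freqs.size == 2 * f1.freqs.size
        assert f2.freqs[-1] == f1.freqs[-1]

    def test_minimal_two_point_grid(self):
        g = make_grid(np.zeros(2), dt=1.0)
        fg = frequency_grid(g)
        assert np.allclose(fg.freqs, [0.5])

    def test_rejects_bad_oversampling(self):
        with pytest.raises(ValueError):
            frequency_grid(make_grid(np.zeros(10)), 0)


class TestFastLSP:
    def test_reduces_to_dft_periodogram_when_complete(self, rng):
        # generic (odd) length: every frequency, including the highest
        x = rng.standard_normal((255, 2))
        g = make_grid(x)
        lsp = fast_lsp(g)
        dft = dft_periodogram(g)
        assert np.allclose(lsp.power_by_dim, dft.power_by_dim, rtol=1e-10)

    def test_even_length_nyquist_bin_is_half_dft(self, rng):
        # at the exact Nyquist frequency of an even-length complete series
        # the sine quadrature vanishes: least-squares power = DFT bin / 2
        x = rng.standard_normal((256, 1))
        g = make_grid(x)
        with pytest.warns(UserWarning, match="near-singular"):
            lsp = fast_lsp(g)
        dft = dft_periodogram(g)
        assert np.allclose(lsp.power[:-1], dft.power[:-1], rtol=1e-10)
        assert lsp.power[-1] == pytest.approx(dft.power[-1] / 2, rel=1e-9)

    def test_recovers_tone_under_iid_missingness(self, rng):
        times = np.arange(1000) * HOUR
        x = np.sin(2 * np.pi * times / (24 * HOUR))
        keep = rng.random(1000) < 0.7
        keep[:2] = keep[-1] = True
        g = build_sample_grid(TrackSeries("t", times[keep], x[keep, None]))
        pg = fast_lsp(g)
        peak = 1 / pg.freqs.freqs[np.argmax(pg.power)]
        assert abs(peak - 24 * HOUR) <= 1.5 * pg.freqs.df * (24 * HOUR) ** 2

    def test_combined_power_is_mean_over_dimensions(self, rng):
        g = make_grid(rng.standard_normal((101, 3)))
        pg = fast_lsp(g)
        assert np.allclose(pg.power, pg.power_by_dim.mean(axis=1))

    def test_matches_least_squares_oracle_on_gappy_ou(self, rng):
        spec = MovementModelSpec("OU", 4.0, tau_pos=10 * HOUR)
        times = np.arange(256) * HOUR
        x = simulate_batch(spec, times, k=2, seed=5)[0]
        w = (rng.random(256) < 0.5).astype(float)
        w[:3] = 1
        g = SampleGrid(t1=0.0, dt=HOUR, n=256, w=w, wx=w[:, None] * x)
        fg = frequency_grid(g)
        fast = fast_lsp(g, fg)
        oracle = lsq_lsp(times[w > 0], x[w > 0], np.ones(int(w.sum())), fg.freqs)
        rel = np.abs(fast.power_by_dim - oracle.power_by_dim) / np.maximum(
            oracle.power_by_dim, 1e-12 * oracle.power_by_dim.max()
        )
        assert rel.max() < 1e-8

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(16, 192),
        seed=st.integers(0, 2**20),
        p_keep=st.floats(0.3, 1.0),
        res_freq=st.integers(1, 3),
    )
    def test_equivalence_property_random_schedules(self, n, seed, p_keep, res_freq):
        """fast_lsp and the exact least-squares oracle agree at every
        frequency for arbitrary schedules and signals on the grid."""
        rng = np.random.default_rng(seed)
        w = (rng.random(n) < p_keep).astype(float)
        w[rng.choice(n, 3, replace=False)] = 1.0
        x = rng.standard_normal((n, 2)).cumsum(axis=0)
        g = SampleGrid(t1=0.0, dt=HOUR, n=n, w=w, wx=w[:, None] * x)
        fg = frequency_grid(g, res_freq)
        fast = fast_lsp(g, fg)
        times = g.grid_times()[w > 0]
        oracle = lsq_lsp(times, x[w > 0], np.ones(int(w.sum())), fg.freqs)
        scale = oracle.power_by_dim.max()
        rel = np.abs(fast.power_by_dim - oracle.power_by_dim) / np.maximum(
            oracle.power_by_dim, 1e-9 * scale
        )
        assert rel.max() < 1e-8
        # non-negativity up to round-off
        assert fast.power.min() >= -1e-9 * scale

    def test_refuses_fewer_than_three_records(self):
        g = make_grid(np.ones(10), w=np.r_[1.0, 1.0, np.zeros(8)])
        with pytest.raises(ValueError):
            fast_lsp(g)


class TestDFTPeriodogram:
    def test_constant_series_has_zero_power(self):
        pg = dft_periodogram(make_grid(np.full(64, 7.0)))
        assert np.allclose(pg.power, 0.0, atol=1e-20)

    def test_on_grid_tone_occupies_single_bin(self):
        n = 64
        times = np.arange(n) * HOUR
        x = np.cos(2 * np.pi * 8 * times / (n * HOUR))
        pg = dft_periodogram(make_grid(x))
        hot = pg.power > 1e-9 * pg.power.max()
        assert hot.sum() == 1
        assert np.argmax(pg.power) == 7  # bin k=8 is the 8th positive freq

    def test_white_noise_matches_naive_summation(self, rng):
        x = rng.standard_normal((128, 2))
        g = make_grid(x)
        pg = dft_periodogram(g)
        naive = naive_dft_power(g.grid_times(), x, pg.freqs.freqs)
        assert np.allclose(pg.power_by_dim, naive, rtol=1e-8, atol=1e-12)
        # mean power ~ signal variance for white noise
        assert pg.power.mean() == pytest.approx(x.var(), rel=0.35)

    def test_refuses_gappy_series(self):
        w = np.ones(32)
        w[5] = 0
        with pytest.raises(ValueError, match="fast_lsp"):
            dft_periodogram(make_grid(np.zeros(32), w=w))


class TestSchedulePeriodogram:
    def test_complete_schedule_is_flat_zero(self):
        pg = schedule_periodogram(make_grid(np.zeros(100)))
        assert np.allclose(pg.power, 0.0, atol=1e-20)

    def test_duty_cycle_peaks_at_cycle_period(self):
        n = 480
        w = (np.arange(n) % 24) < 12  # 12 h on / 12 h off
        g = make_grid(np.zeros(n), w=w.astype(float))
        pg = schedule_periodogram(g)
        peak_period = 1 / pg.freqs.freqs[np.argmax(pg.power)]
        assert peak_period == pytest.approx(24 * HOUR, rel=1e-6)
        # cross-check the peak value against the direct least-squares fit
        oracle = lsq_lsp(g.grid_times(), g.w[:, None], np.ones(n),
                         np.array([1 / (24 * HOUR)]))
        assert pg.power[np.argmax(pg.power)] == pytest.approx(
            oracle.power[0], rel=1e-9)

    def test_iid_schedule_shows_no_systematic_peak(self, rng):
        n = 1024
        peak_counts = []
        for _ in range(5):
            w = (rng.random(n) < 0.5).astype(float)
            pg = schedule_periodogram(make_grid(np.zeros(n), w=w))
            q99 = np.quantile(pg.power, 0.99)
            peak_counts.append((pg.power > 3 * q99).sum())
        assert np.mean(peak_counts) < 2


class TestCombineIndividuals:
    def test_single_individual_identity_up_to_normalization(self, rng):
        pg = fast_lsp(make_grid(rng.standard_normal((101, 2))))
        out = combine_individuals([pg])
        assert np.allclose(out.power, pg.power / pg.power.mean())

    def test_two_identical_periodograms_average_to_same(self, rng):
        pg = fast_lsp(make_grid(rng.standard_normal((101, 2))))
        out = combine_individuals([pg, pg])
        assert np.allclose(out.power, pg.power / pg.power.mean())

    def test_shared_daily_pattern_reinforced_by_pooling(self):
        """Eight individuals with a common 24 h periodic mean over OUF
        noise: pooling boosts the daily peak above the median individual."""
        times = np.arange(720) * HOUR
        spec = MovementModelSpec(
            "OUF", 1.0, tau_pos=2 * DAY, tau_vel=2 * HOUR,
            mean=PeriodicMean(period=24 * HOUR, amplitude=0.25),
        )
        pgs = []
        for i in range(8):
            tr = simulate_track(spec, times, k=2, seed=100 + i)
            pgs.append(fast_lsp(build_sample_grid(tr)))
        combined = combine_individuals(pgs)

        def prominence(pg):
            f = pg.freqs.freqs
            p = pg.power / pg.power.mean()
            win = np.abs(f - 1 / (24 * HOUR)) <= pg.freqs.df
            band = (f > 1 / (40 * HOUR)) & (f < 1 / (15 * HOUR)) & ~win
            return p[win].max() / np.median(p[band])

        singles = [prominence(pg) for pg in pgs]
        assert prominence(combined) > np.median(singles)


class TestLocalMaxima:
    def test_monotone_periodogram_keeps_boundary_maximum(self):
        from movelsp.lsp_core import FrequencyGrid, Periodogram

        freqs = FrequencyGrid(np.linspace(0.1, 0.5, 50), 0.5, 0.4 / 49)
        pg = Periodogram(freqs, np.linspace(1, 5, 50)[:, None], 50)
        summary = local_maxima(pg, study_duration=1000.0)
        assert summary.peak_periods.size == 1
        assert summary.fundamental == pytest.approx(1 / 0.5)

    def test_two_well_separated_tones_both_reported(self):
        n = 1001
        times = np.arange(n) * HOUR
        x = (np.cos(2 * np.pi * times / (24 * HOUR))
             + 0.8 * np.cos(2 * np.pi * times / (12 * HOUR) + 0.3))
        pg = fast_lsp(make_grid(x))
        summary = local_maxima(pg, (n - 1) * HOUR)
        periods_h = summary.peak_periods[:2] / HOUR
        assert {round(p) for p in periods_h} == {24, 12}

    def test_retained_maxima_respect_one_over_duration_gap(self):
        times = np.arange(90 * 24) * HOUR  # 90 days
        spec = MovementModelSpec("OUF", 1.0, tau_pos=5 * DAY, tau_vel=2 * HOUR)
        tr = simulate_track(spec, times, k=1, seed=3)
        pg = fast_lsp(build_sample_grid(tr))
        d = (times.size - 1) * HOUR
        summary = local_maxima(pg, d)
        f = np.sort(1 / summary.peak_periods)
        assert np.all(np.diff(f) >= 1 / d - 1e-15)

    def test_peaks_sorted_by_descending_power(self, ou_track):
        pg = fast_lsp(build_sample_grid(ou_track))
        s = local_maxima(pg, 511 * HOUR)
        assert np.all(np.diff(s.peak_powers) <= 0)
        assert s.fundamental == s.peak_periods[0]


class TestClassifyHarmonics:
    def test_integer_submultiples_are_harmonics(self):
        s = SpectralSummary(
            peak_periods=np.array([24.0, 12.0, 8.0]) * HOUR,
            peak_powers=np.array([10.0, 5.0, 2.0]),
            fundamental=24.0 * HOUR,
        )
        labels, overall = classify_harmonics(s)
        assert labels == ["fundamental", "harmonic", "harmonic"]
        assert overall == "mono-periodic"

    def test_non_integer_ratio_is_multi_periodic(self):
        s = SpectralSummary(
            peak_periods=np.array([29.5 * DAY, 24 * HOUR]),
            peak_powers=np.array([8.0, 5.0]),
            fundamental=29.5 * DAY,
        )
        labels, overall = classify_harmonics(s)
        assert labels[1] == "independent-period"
        assert overall == "multi-periodic"

    def test_short_period_peak_dominating_long_one_is_multi_periodic(self):
        s = SpectralSummary(
            peak_periods=np.array([1.0 * HOUR, 24.0 * HOUR]),
            peak_powers=np.array([9.0, 4.0]),
            fundamental=1.0 * HOUR,
        )
        labels, overall = classify_harmonics(s)
        assert labels == ["fundamental", "independent-period"]
        assert overall == "multi-periodic"


class TestPeakWidthLaw:
    def test_peak_width_grows_as_period_squared(self):
        """Half-maximum width on the period scale ~ T^2/(N dt)."""
        n = 4097
        times = np.arange(n) * HOUR

        def width_at(period):
            x = np.cos(2 * np.pi * times / period)
            g = make_grid(x)
            pg = fast_lsp(g, frequency_grid(g, 4))
            p = pg.power
            i = np.argmax(p)
            half = p[i] / 2
            lo = i
            while lo > 0 and p[lo] > half:
                lo -= 1
            hi = i
            while hi < p.size - 1 and p[hi] > half:
                hi += 1
            periods = pg.freqs.periods
            return abs(periods[lo] - periods[hi])

        w24 = width_at(24 * HOUR)
        w96 = width_at(96 * HOUR)
        ratio = w96 / w24
        assert ratio == pytest.approx((96 / 24) ** 2, rel=0.35)


class TestSlopeHelpers:
    def test_prewhitened_white_noise_is_flat(self, rng):
        x = rng.standard_normal(4096)
        g = make_grid(x)
        pg = prewhitened_lsp(g)
        slope = fit_loglog_slope(pg, 4 * HOUR, 150 * HOUR, n_bins=10)
        assert abs(slope) < 0.25

    def test_averaging_requires_common_grid(self, rng):
        a = fast_lsp(make_grid(rng.standard_normal(100)))
        b = fast_lsp(make_grid(rng.standard_normal(120)))
        with pytest.raises(ValueError):
            average_periodograms([a, b])
        avg = average_periodograms([a, a])
        assert np.allclose(avg.power, a.power)
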