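"""Window FFT, scanning, region calling and HMR overlap accounting."""

import numpy as np
import pytest

from srnascape.io_coverage import Feature
from srnascape.periodicity import (
    PeriodWindow,
    call_periodic_regions,
    hmr_overlap,
    scan,
    spectrum_magnitudes,
    window_fft,
)


def brute_force_dft_magnitudes(x):
    """O(n^2) discrete Fourier transform magnitudes, bins 0..n//2."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    ks = np.arange(n // 2 + 1)
    j = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(ks, j) / n)
    return np.abs(basis @ x)


class TestWindowFft:
    @pytest.mark.parametrize("n", [64, 512, 1000, 1024])
    def test_magnitudes_match_brute_force(self, n):
        rng = np.random.default_rng(n)
        x = rng.poisson(3.0, size=n).astype(float)
        fast = spectrum_magnitudes(x)
        slow = brute_force_dft_magnitudes(x)
        assert np.allclose(fast, slow, rtol=1e-6, atol=1e-9)

    def test_impulse_train_period_100(self):
        v = np.zeros(1000)
        v[::100] = 1.0
        period, coeff, _ = window_fft(v, detrend="none")
        assert period == pytest.approx(100.0)

    def test_pure_cosine_period_200_coefficient_near_one(self):
        t = np.arange(1000)
        v = 1.0 + np.cos(2 * np.pi * t / 200)
        period, coeff, _ = window_fft(v, detrend="none")
        assert period == pytest.approx(200.0)
        assert coeff > 0.99

    def test_constant_coverage_no_period(self):
        assert window_fft(np.full(1000, 7.0)) == (None, 0.0, False)
        assert window_fft(np.zeros(1000)) == (None, 0.0, False)

    def test_shift_invariance_of_magnitudes(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(2.0, 1000).astype(float)
        base = spectrum_magnitudes(x)
        for shift in (1, 137, 500):
            rolled = spectrum_magnitudes(np.roll(x, shift))
            assert np.allclose(base, rolled, rtol=1e-9, atol=1e-9)

    def test_shifted_pile_train_same_period(self):
        v = np.zeros(1000)
        for k in range(5):
            v[k * 200 : k * 200 + 25] = 60.0
        p0, _, _ = window_fft(v)
        p1, _, _ = window_fft(np.roll(v, 61))
        assert p0 == pytest.approx(p1, abs=1.0)

    def test_180nt_pulse_train_reports_fundamental_not_harmonic(self):
        """A 180-nt pile train in a 1000-nt window sits between DFT bins;
        the harmonic rule must still report ~180, not ~90."""
        v = np.zeros(1000)
        for k in range(6):
            v[k * 180 : k * 180 + 25] = 60.0
        period, _, harmonic = window_fft(v)
        assert abs(period - 180) < 34  # within one bin at k~5.5
        assert harmonic

    def test_period_band_restricts_search(self):
        t = np.arange(1000)
        v = 1.0 + np.cos(2 * np.pi * t / 25)  # outside [50, 500]
        period, coeff, _ = window_fft(v, period_band=(50, 500))
        # the 25-nt tone is invisible inside the band
        assert period is None or abs(period - 25) > 10


class TestScan:
    def test_empty_track_no_windows(self):
        assert scan(np.zeros(500), window=1000) == []

    def test_single_periodic_region_wins_significance(self):
        rng = np.random.default_rng(11)
        v = rng.poisson(0.05, 20_000).astype(float)
        for k in range(30):
            s = 7000 + k * 180
            v[s : s + 25] += 60.0
        windows = scan({"chr1": v})
        sig = [w for w in windows if w.significant]
        assert sig, "periodic region must yield significant windows"
        inside = [w for w in sig if 6000 <= w.start <= 12500]
        assert len(inside) / len(sig) > 0.9

    def test_uniform_random_coverage_periods_not_concentrated(self):
        """Monte-Carlo null: significant windows on noise show no dominant
        period (no band value covers more than half of them)."""
        rng = np.random.default_rng(23)
        v = rng.poisson(2.0, 30_000).astype(float)
        windows = scan({"chr1": v})
        sig = [w for w in windows if w.significant and w.main_period]
        if len(sig) >= 10:
            periods = np.array([w.main_period for w in sig])
            # coarse 50-nt bins over the band
            hist, _ = np.histogram(periods, bins=np.arange(50, 551, 50))
            assert hist.max() / hist.sum() < 0.5

    def test_per_chromosome_maximum_flag(self):
        rng = np.random.default_rng(7)
        flat = rng.poisson(0.5, 3000).astype(float)
        strong = np.zeros(3000)
        for k in range(12):
            strong[k * 200 : k * 200 + 30] = 50.0
        global_windows = scan({"a": flat, "b": strong}, global_max=True)
        per_chrom = scan({"a": flat, "b": strong}, global_max=False)
        sig_global_a = [w for w in global_windows if w.chrom == "a" and w.significant]
        sig_local_a = [w for w in per_chrom if w.chrom == "a" and w.significant]
        assert len(sig_local_a) >= len(sig_global_a)


class TestRegionCalling:
    def _win(self, start, period=180.0, sig=True, chrom="chr1"):
        return PeriodWindow(
            chrom=chrom, start=start, length=1000, main_period=period,
            coefficient=0.5, significant=sig,
        )

    def test_three_close_significant_windows_one_region(self):
        windows = [self._win(0), self._win(100), self._win(300)]
        regions = call_periodic_regions(windows)
        assert len(regions) == 1
        assert regions[0].n_significant_windows == 3

    def test_two_significant_windows_no_region(self):
        regions = call_periodic_regions([self._win(0), self._win(100)])
        assert regions == []

    def test_windows_farther_than_span_not_merged(self):
        windows = [self._win(0), self._win(100), self._win(20_000)]
        assert call_periodic_regions(windows) == []

    def test_mean_period_and_band_flag(self):
        windows = [
            self._win(0, 180.0), self._win(100, 180.0), self._win(200, 90.0)
        ]
        (region,) = call_periodic_regions(windows)
        assert region.mean_period == pytest.approx(150.0)
        assert not region.in_175_225_band
        windows = [self._win(0, 180.0), self._win(100, 200.0), self._win(200, 220.0)]
        (region,) = call_periodic_regions(windows)
        assert region.in_175_225_band

    def test_non_significant_windows_ignored(self):
        windows = [self._win(0), self._win(100), self._win(300, sig=False)]
        assert call_periodic_regions(windows) == []


class TestHmrOverlap:
    def _region(self, start, end):
        from srnascape.periodicity import PeriodicRegion

        return PeriodicRegion(
            chrom="chr1", start=start, end=end, n_significant_windows=3,
            mean_period=180.0, in_175_225_band=True,
        )

    def test_region_inside_hmr_counts(self):
        hmrs = [Feature("chr1", 0, 10_000, ".", "hmr1")]
        report = hmr_overlap([self._region(2000, 4000)], hmrs)
        assert report["fraction_regions_overlapping_hmr"] == 1.0

    def test_disjoint_sets_zero(self):
        hmrs = [Feature("chr1", 50_000, 60_000, ".", "hmr1")]
        report = hmr_overlap([self._region(2000, 4000)], hmrs)
        assert report["fraction_regions_overlapping_hmr"] == 0.0

    def test_hmr_covered_80_percent_counts_in_deep_class(self):
        class Locus:
            chrom = "chr1"
            start = 1000
            end = 1800

        hmrs = [Feature("chr1", 1000, 2000, ".", "hmr1")]
        report = hmr_overlap([], hmrs, loci=[Locus()])
        assert report["fraction_hmrs_with_locus"] == 1.0
        assert report["fraction_hmrs_covered_gt75"] == 1.0

    def test_hmr_covered_half_not_in_deep_class(self):
        class Locus:
            chrom = "chr1"
            start = 1000
            end = 1500

        hmrs = [Feature("chr1", 1000, 2000, ".", "hmr1")]
        report = hmr_overlap([], hmrs, loci=[Locus()])
        assert report["fraction_hmrs_with_locus"] == 1.0
        assert report["fraction_hmrs_covered_gt75"] == 0.0
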