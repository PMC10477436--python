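"""Sliding-window PSD contracts: row arithmetic, Parseval, band additivity."""

import numpy as np
import pytest
from scipy import signal as ssig

from snapipe.errors import AlignmentError, ArgumentError
from snapipe.simulate import Recording, default_config, generate_recording
from snapipe.spectral import (
    BandDefinition,
    SpectralWindowing,
    Spectrogram,
    band_power,
    mean_psd,
    peak_frequency,
    sliding_psd,
)

FS = 1000.0


class TestWindowArithmetic:
    @pytest.mark.parametrize(
        "n,frac,overlap",
        [(600_000, 0.005, 0.2), (100_000, 0.005, 0.2), (50_000, 0.01, 0.5), (20_000, 0.02, 0.0)],
    )
    def test_row_count_formula(self, n, frac, overlap, labels):
        w = SpectralWindowing(window_fraction=frac, overlap_fraction=overlap)
        win = w.window_samples(n)
        step = w.step_samples(n)
        x = np.random.default_rng(0).normal(size=n)
        sg = sliding_psd(Recording(x, FS, labels), w)
        assert sg.power.shape[0] == (n - win) // step + 1

    def test_default_windowing_of_ten_minutes_gives_249_rows(self, labels):
        x = np.random.default_rng(1).normal(size=600_000)
        w = SpectralWindowing()
        assert w.window_samples(600_000) == 3000
        assert w.step_samples(600_000) == 2400
        sg = sliding_psd(Recording(x, FS, labels), w)
        assert sg.power.shape[0] == 249

    def test_too_short_signal_reports_required_minimum(self, labels):
        with pytest.raises(ArgumentError, match="at least"):
            sliding_psd(Recording(np.zeros(1000), FS, labels))


class TestPeriodogramCorrectness:
    def test_rows_match_scipy_periodogram(self, labels):
        x = np.random.default_rng(2).normal(size=20_000)
        w = SpectralWindowing(window_fraction=0.02, overlap_fraction=0.2)
        sg = sliding_psd(Recording(x, FS, labels), w)
        win = w.window_samples(20_000)
        step = w.step_samples(20_000)
        for row in (0, 3, sg.power.shape[0] - 1):
            seg = x[row * step : row * step + win]
            f_ref, p_ref = ssig.periodogram(
                seg, FS, window="hann", nfft=512, detrend="constant"
            )
            np.testing.assert_allclose(sg.power[row], p_ref, rtol=1e-10, atol=1e-15)
            np.testing.assert_allclose(sg.freqs, f_ref)

    def test_pure_tone_argmax_in_every_row(self, make_tone):
        rec = make_tone(7.0, duration=100.0)
        sg = sliding_psd(rec, SpectralWindowing(window_fraction=0.02))
        peak_bins = sg.freqs[np.argmax(sg.power, axis=1)]
        assert np.all(np.abs(peak_bins - 7.0) <= sg.df)

    def test_parseval_within_5_percent_per_row(self, labels):
        # the PSD integral must match the windowed-segment variance
        x = np.random.default_rng(3).normal(size=200_000)
        sg = sliding_psd(Recording(x, FS, labels))
        win = SpectralWindowing().window_samples(200_000)
        step = SpectralWindowing().step_samples(200_000)
        taper = ssig.windows.hann(win, sym=False)
        for row in range(sg.power.shape[0]):
            seg = x[row * step : row * step + win]
            seg = seg - seg.mean()
            windowed_var = np.sum((seg * taper) ** 2) / np.sum(taper**2)
            integral = np.trapezoid(sg.power[row], sg.freqs)
            assert integral == pytest.approx(windowed_var, rel=0.05)


class TestMeanPsd:
    def test_single_row_is_degenerate(self, labels):
        sg = Spectrogram(
            np.ones((1, 5)), np.arange(5.0), np.zeros(1), labels, "envelope"
        )
        out = mean_psd(sg)
        assert out.degenerate
        np.testing.assert_array_equal(out.ci_low, out.mean_power)

    def test_identical_rows_give_zero_width_ci(self, labels):
        sg = Spectrogram(
            np.ones((4, 5)), np.arange(5.0), np.zeros(4), labels, "envelope"
        )
        out = mean_psd(sg)
        np.testing.assert_allclose(out.ci_high - out.ci_low, 0.0, atol=1e-12)

    def test_ci_covers_true_mean_at_nominal_rate(self, labels):
        rng = np.random.default_rng(4)
        mu = 5.0
        rows = rng.normal(mu, 1.0, size=(100, 400))
        sg = Spectrogram(
            np.abs(rows), np.arange(400.0), np.zeros(100), labels, "envelope"
        )
        # use raw normal rows (shift positive) for the coverage check
        rows_pos = rows - rows.min() + 1.0
        sg = Spectrogram(rows_pos, np.arange(400.0), np.zeros(100), labels, "envelope")
        out = mean_psd(sg)
        target = mu - rows.min() + 1.0
        covered = np.mean((out.ci_low <= target) & (target <= out.ci_high))
        assert 0.92 <= covered <= 0.98

    def test_grid_mismatch_rejected(self, labels):
        a = Spectrogram(np.ones((2, 5)), np.arange(5.0), np.zeros(2), labels, "envelope")
        b = Spectrogram(np.ones((2, 6)), np.arange(6.0), np.zeros(2), labels, "envelope")
        with pytest.raises(AlignmentError):
            mean_psd([a, b])


class TestBandPower:
    def test_adjacent_bands_partition_their_parent(self, labels):
        x = np.random.default_rng(5).normal(size=100_000)
        sg = sliding_psd(Recording(x, FS, labels))
        p_lo = band_power(sg, BandDefinition("lo", 0.0, 4.0))
        p_hi = band_power(sg, BandDefinition("hi", 4.0, 10.0))
        p_all = band_power(sg, BandDefinition("all", 0.0, 10.0))
        np.testing.assert_allclose(p_lo + p_hi, p_all, rtol=1e-9)

    def test_zero_spectrum_gives_zero_power(self, labels):
        sg = Spectrogram(np.zeros((3, 10)), np.arange(10.0), np.zeros(3), labels, "envelope")
        assert not band_power(sg, BandDefinition("b", 1.0, 5.0)).any()

    def test_tone_power_concentrates_in_its_band(self, make_tone):
        rec = make_tone(7.0, duration=100.0)
        sg = sliding_psd(rec, SpectralWindowing(window_fraction=0.02))
        in_band = np.mean(band_power(sg, BandDefinition("b", 4.0, 10.0)))
        total = np.mean(band_power(sg, BandDefinition("all", 0.0, sg.freqs[-1])))
        assert in_band / total > 0.95

    def test_band_outside_grid_rejected(self, labels):
        sg = Spectrogram(np.ones((2, 10)), np.arange(10.0), np.zeros(2), labels, "envelope")
        with pytest.raises(ArgumentError):
            band_power(sg, BandDefinition("b", 5.0, 20.0))

    def test_monotone_under_pointwise_domination(self, labels):
        freqs = np.linspace(0, 100, 200)
        lo = np.abs(np.random.default_rng(6).normal(size=(1, 200)))
        hi = lo * 1.5
        band = BandDefinition("b", 10.0, 90.0)
        p_lo = band_power(Spectrogram(lo, freqs, np.zeros(1), labels, "envelope"), band)
        p_hi = band_power(Spectrogram(hi, freqs, np.zeros(1), labels, "envelope"), band)
        assert np.all(p_hi >= p_lo)


class TestPeakFrequency:
    def test_flat_spectrum_ties_break_to_lowest_frequency(self, labels):
        sg = Spectrogram(np.ones((2, 50)), np.arange(50.0), np.zeros(2), labels, "envelope")
        assert peak_frequency(sg, BandDefinition("b", 10.0, 20.0)) == 10.0

    def test_empty_band_rejected(self, labels):
        sg = Spectrogram(np.ones((2, 5)), np.arange(5.0) * 10, np.zeros(2), labels, "envelope")
        with pytest.raises(ArgumentError):
            peak_frequency(sg, BandDefinition("b", 1.0, 9.0))

    def test_default_disinhibited_envelope_peaks_at_half_hz(self):
        from snapipe.envelope import rms_envelope

        cfg = default_config("CTRL", "renal", "BIC", seed=21)
        rec = generate_recording(cfg)
        sg = sliding_psd(rms_envelope(rec, 50), channel="envelope")
        pk = peak_frequency(sg, BandDefinition("lo", 0.0, 4.0))
        assert abs(pk - 0.5) <= sg.df

    def test_default_baseline_carrier_peak_at_dominant_center(self):
        cfg = default_config("CTRL", "renal", "BAS", seed=22, duration=120.0)
        rec = generate_recording(cfg)
        sg = sliding_psd(rec, channel="burst")
        pk = peak_frequency(sg, BandDefinition("b", 60.0, 200.0))
        # dominant configured carrier is 150 Hz (190 is configured weaker)
        assert abs(pk - 150.0) <= 10.0
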