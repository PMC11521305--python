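"""Welch spectra, the export grid, band powers and derived endpoints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qeegvar import (
    DEFAULT_SCHEME,
    PowerSpectrum,
    aggregate_bins,
    band_powers,
    epoch_powers,
    percent_change,
    psd_of_segments,
    relative_band,
)
from qeegvar.errors import DegenerateSpectrumError, InsufficientDataError
from qeegvar.preprocess import ArtifactMask, detect_artifacts

from conftest import make_recording


def flat_spectrum(power=1.0):
    freqs = np.fft.rfftfreq(1024, d=0.01)
    return PowerSpectrum(freqs=freqs, power=np.full(len(freqs), power), segment_count=1)


class TestWelch:
    def test_export_grid_is_481_bins(self, noise_recording):
        spec = psd_of_segments([noise_recording.samples])
        f, p = spec.export_grid()
        assert len(f) == 481
        assert np.isclose(f[0], 1.07421875)
        assert np.isclose(f[-1], 47.94921875)
        assert spec.df == pytest.approx(100 / 1024)

    def test_sum_equals_mean_square(self, rng):
        x = rng.normal(0, 3.0, 100 * 120)
        spec = psd_of_segments([x])
        # mean square of the analysed (segmented) samples
        segs = np.array([x[i : i + 1024] for i in range(0, len(x) - 1023, 512)])
        assert spec.power.sum() == pytest.approx(np.mean(segs**2), rel=1e-9)

    def test_unit_sine_power_half(self, sine_recording):
        spec = psd_of_segments([sine_recording.samples])
        assert spec.power.sum() == pytest.approx(0.5, rel=0.01)
        f, p = spec.export_grid()
        near = np.abs(f - 5.0) <= 0.3
        assert p[near].sum() / p.sum() >= 0.99

    def test_zero_signal_zero_spectrum(self):
        spec = psd_of_segments([np.zeros(2048)])
        assert np.all(spec.power == 0.0)

    def test_agrees_with_scipy_welch_shape(self, rng):
        """Independent route: same spectral shape as scipy's Welch."""
        from scipy.signal import welch

        x = rng.standard_normal(100 * 300)
        spec = psd_of_segments([x])
        f_sp, p_sp = welch(
            x, fs=100, window="hamming", nperseg=1024, noverlap=512, detrend=False
        )
        # scipy scales the DC/Nyquist bins of its one-sided density
        # differently; the interior bins must agree up to one global factor
        ours = spec.power[1:-1] / spec.power[1:-1].sum()
        theirs = p_sp[1:-1] / p_sp[1:-1].sum()
        assert np.max(np.abs(ours - theirs)) < 1e-6
        assert np.corrcoef(ours, theirs)[0, 1] > 0.999999

    def test_segments_do_not_bridge_gaps(self, rng):
        """Two short spans give exactly their own full segments."""
        a = rng.standard_normal(1100)
        b = rng.standard_normal(1600)
        spec = psd_of_segments([a, b])
        assert spec.segment_count == 1 + 2  # 1100 -> 1 segment, 1600 -> 2

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            psd_of_segments([np.zeros(500)])


class TestBandPowers:
    def test_flat_spectrum_fractions_match_bandwidth(self):
        rec = band_powers(flat_spectrum())
        assert rec.relative["Delta"] == pytest.approx(3 / 47, abs=0.0022)
        assert rec.relative["Beta-2"] == pytest.approx(14 / 47, abs=0.0022)

    def test_single_bin_in_theta1(self):
        spec = flat_spectrum(0.0)
        k = np.argmin(np.abs(spec.freqs - 5.0))
        spec.power[k] = 2.0
        rec = band_powers(spec)
        assert rec.relative["Theta-1"] == 1.0
        assert all(v == 0.0 for b, v in rec.relative.items() if b != "Theta-1")

    def test_relative_sums_to_one(self, rng):
        spec = psd_of_segments([rng.standard_normal(100 * 60)])
        rec = band_powers(spec)
        assert sum(rec.relative.values()) == pytest.approx(1.0, abs=1e-9)

    def test_band_partition_matches_total(self, rng):
        spec = psd_of_segments([rng.standard_normal(100 * 60)])
        rec = band_powers(spec)
        assert sum(rec.raw.values()) == pytest.approx(rec.total, rel=1e-12)

    def test_degenerate_spectrum(self):
        with pytest.raises(DegenerateSpectrumError):
            band_powers(flat_spectrum(0.0))


class TestRelativeBand:
    def test_consistent_with_record(self, rng):
        spec = psd_of_segments([rng.standard_normal(100 * 60)])
        rec = band_powers(spec)
        assert relative_band(spec, "Gamma-1") == pytest.approx(
            rec.relative["Gamma-1"], rel=1e-12
        )

    def test_widening_total_range_never_increases(self, rng):
        spec = psd_of_segments([rng.standard_normal(100 * 60)])
        vals = [
            relative_band(spec, "Gamma-1", total_range=tr)
            for tr in [(30.0, 48.0), (10.0, 48.0), (1.0, 48.0), (0.5, 48.0)]
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestPercentChange:
    def _record(self, gamma, total=10.0):
        from qeegvar import BandPowerRecord

        raw = {"Gamma-1": gamma, "Delta": total - gamma}
        return BandPowerRecord(
            raw=raw, total=total, relative={k: v / total for k, v in raw.items()}
        )

    def test_no_change_is_zero(self):
        r = self._record(2.0)
        assert percent_change(r, r, "Gamma-1") == 0.0

    def test_fifty_percent(self):
        assert percent_change(self._record(3.0), self._record(2.0), "Gamma-1") == pytest.approx(50.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            percent_change(self._record(1.0), self._record(0.0), "Gamma-1")

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(gain=st.floats(min_value=0.01, max_value=100.0))
    def test_gain_invariance_of_relative_and_pct_change(self, gain):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(100 * 120)
        y = rng.standard_normal(100 * 120) * 1.3
        s1, s2 = psd_of_segments([x]), psd_of_segments([y])
        g1, g2 = psd_of_segments([x * gain]), psd_of_segments([y * gain])
        r, rg = band_powers(s1), band_powers(g1)
        for band in r.relative:
            assert rg.relative[band] == pytest.approx(r.relative[band], rel=1e-9)
        pc = percent_change(band_powers(s2), band_powers(s1), "Gamma-1")
        pcg = percent_change(band_powers(g2), band_powers(g1), "Gamma-1")
        assert pcg == pytest.approx(pc, rel=1e-9)


class TestEpochsAndBins:
    def test_epoch_count_and_mask_exclusion(self, rng):
        rec = make_recording(rng.standard_normal(100 * 300))
        empty = ArtifactMask(intervals=[])
        recs = epoch_powers(rec, empty, epoch_s=10)
        assert len(recs) == 30
        mask = ArtifactMask(intervals=[(95.0, 125.0)])
        kept = [r.meta["epoch"] for r in epoch_powers(rec, mask, epoch_s=10)]
        assert set(range(30)) - set(kept) == {9, 10, 11, 12}

    def test_epoch_mean_matches_whole_recording_power(self, rng):
        rec = make_recording(rng.standard_normal(100 * 600))
        recs = epoch_powers(rec, ArtifactMask(intervals=[]), epoch_s=10)
        mean_epoch_total = np.mean([r.total for r in recs])
        whole = band_powers(psd_of_segments([rec.samples])).total
        assert mean_epoch_total == pytest.approx(whole, rel=0.05)

    def test_binned_counts_and_sem(self, rng):
        rec = make_recording(rng.standard_normal(100 * 3600))
        recs = epoch_powers(rec, ArtifactMask(intervals=[]), epoch_s=10)
        df = aggregate_bins(recs, bin_width_s=1800, epoch_s=10)
        assert sorted(df["bin"].unique()) == [0, 1]
        assert (df["n"] == 180).all()
        sub = df[df["band"] == "Delta"]
        expected_sem = np.std(
            [r.raw["Delta"] for r in recs[:180]], ddof=1
        ) / np.sqrt(180)
        assert sub.iloc[0]["sem_raw"] == pytest.approx(expected_sem)

    def test_constant_epochs_zero_sem(self):
        t = np.arange(0, 120, 0.01)
        rec = make_recording(np.sin(2 * np.pi * 6 * t))
        recs = epoch_powers(rec, ArtifactMask(intervals=[]), epoch_s=10)
        df = aggregate_bins(recs, bin_width_s=120, epoch_s=10)
        assert df[df["band"] == "Theta-2"]["sem_raw"].iloc[0] == pytest.approx(0.0, abs=1e-12)
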