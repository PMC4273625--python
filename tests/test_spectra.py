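import numpy as np
import pytest
from scipy import signal as sig

import freqconn as fc
from freqconn.io import TimeSeriesPanel
from freqconn.spectra import Band, CoherenceSpectrum, SpectralSettings


def bandpass_noise(rng, n, band, fs):
    sos = sig.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sig.sosfiltfilt(sos, rng.standard_normal(n + 400))[200 : 200 + n]
    return x / x.std()


class TestCoherenceSpectrum:
    def test_identical_signals_have_unit_coherence(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=610)
        panel = TimeSeriesPanel(np.column_stack([x, x]), dt=2.0)
        spec = fc.coherence_spectrum(panel)
        np.testing.assert_allclose(spec.values[0, 1], 1.0, atol=1e-10)

    def test_sign_flip_preserves_unit_coherence(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=610)
        panel = TimeSeriesPanel(np.column_stack([x, -x]), dt=2.0)
        spec = fc.coherence_spectrum(panel)
        np.testing.assert_allclose(spec.values[0, 1], 1.0, atol=1e-10)

    def test_diagonal_is_one_and_symmetric(self):
        rng = np.random.default_rng(2)
        panel = TimeSeriesPanel(rng.normal(size=(610, 5)), dt=2.0)
        spec = fc.coherence_spectrum(panel)
        for f in range(spec.values.shape[2]):
            np.testing.assert_allclose(np.diag(spec.values[:, :, f]), 1.0, atol=1e-10)
        np.testing.assert_allclose(spec.values, np.transpose(spec.values, (1, 0, 2)), atol=1e-12)

    def test_matches_scipy_welch_coherence(self):
        rng = np.random.default_rng(3)
        panel = TimeSeriesPanel(rng.normal(size=(610, 3)), dt=2.0)
        spec = fc.coherence_spectrum(panel)
        f_ref, c_ref = sig.coherence(
            panel.values[:, 0],
            panel.values[:, 2],
            fs=0.5,
            window="hann",
            nperseg=128,
            noverlap=64,
            detrend="linear",
        )
        np.testing.assert_allclose(spec.freqs, f_ref, atol=1e-12)
        np.testing.assert_allclose(spec.values[0, 2], c_ref, atol=1e-10)

    def test_white_noise_coherence_matches_monte_carlo_bias(self):
        """Independent signals: estimator bias measured by an independent
        Monte-Carlo oracle over replicate pairs."""
        rng = np.random.default_rng(4)
        reps = 400
        means = np.empty(reps)
        for r in range(reps):
            panel = TimeSeriesPanel(rng.normal(size=(610, 2)), dt=2.0)
            means[r] = fc.coherence_spectrum(panel).values[0, 1].mean()
        bias, se = means.mean(), means.std(ddof=1) / np.sqrt(reps)
        test_panel = TimeSeriesPanel(np.random.default_rng(999).normal(size=(610, 2)), dt=2.0)
        observed = fc.coherence_spectrum(test_panel).values[0, 1].mean()
        # one draw from the same null: within 3 population SDs of the bias
        assert abs(observed - bias) < 3 * means.std(ddof=1)
        assert bias < 0.2  # Welch MSC bias ~1/n_segments for 8 segments
        assert se < 0.01

    def test_constant_roi_is_rejected_by_name(self):
        vals = np.random.default_rng(5).normal(size=(610, 3))
        vals[:, 1] = 4.2
        with pytest.raises(ValueError, match="ROI 2"):
            fc.coherence_spectrum(TimeSeriesPanel(vals, dt=2.0))

    def test_too_few_segments_rejected(self):
        panel = TimeSeriesPanel(np.random.default_rng(6).normal(size=(100, 2)), dt=2.0)
        with pytest.raises(ValueError, match="segments"):
            fc.coherence_spectrum(panel)

    def test_roi_permutation_permutes_spectrum(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(610, 4))
        perm = np.array([2, 0, 3, 1])
        spec = fc.coherence_spectrum(TimeSeriesPanel(vals, dt=2.0))
        spec_p = fc.coherence_spectrum(TimeSeriesPanel(vals[:, perm], dt=2.0))
        np.testing.assert_allclose(spec_p.values, spec.values[np.ix_(perm, perm)], atol=1e-12)

    def test_bounded_on_random_panels(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(300, 700))
            k = int(rng.integers(2, 6))
            scale = 10 ** rng.uniform(-3, 3)
            panel = TimeSeriesPanel(scale * rng.normal(size=(n, k)), dt=2.0)
            v = fc.coherence_spectrum(panel).values
            assert v.min() >= 0.0 and v.max() <= 1.0 + 1e-12

    def test_in_band_coupling_exceeds_out_of_band(self):
        """Planted 0.07-0.09 Hz coupling: band-averaged coherence inside the
        coupled band beats the complementary range in >=95% of replicates."""
        rng = np.random.default_rng(9)
        band = Band(0.07, 0.09)
        out_band = Band(0.15, 0.25)
        wins = 0
        reps = 60
        for _ in range(reps):
            latent = bandpass_noise(rng, 610, (0.07, 0.09), 0.5)
            x = 0.6 * latent + rng.normal(size=610)
            y = 0.6 * latent + rng.normal(size=610)
            spec = fc.coherence_spectrum(TimeSeriesPanel(np.column_stack([x, y]), dt=2.0))
            inside = fc.band_average(spec, band).values[0, 1]
            outside = fc.band_average(spec, out_band).values[0, 1]
            wins += inside > outside
        assert wins >= int(np.ceil(0.95 * reps))


class TestMakeBands:
    def test_published_grid_has_23_bands(self):
        bands = fc.make_bands(0.01, 0.25, 0.02, 0.5)
        assert len(bands) == 23
        np.testing.assert_allclose([b.center for b in bands], np.arange(0.02, 0.245, 0.01), atol=1e-12)

    def test_single_band_when_range_equals_width(self):
        bands = fc.make_bands(0.01, 0.03, 0.02, 0.5)
        assert len(bands) == 1
        assert (bands[0].lo, bands[0].hi) == (0.01, 0.03)

    def test_zero_overlap_gives_disjoint_bands(self):
        bands = fc.make_bands(0.01, 0.05, 0.02, 0.0)
        assert [(b.lo, b.hi) for b in bands] == [(0.01, 0.03), (0.03, 0.05)]

    @pytest.mark.parametrize(
        "args", [(0.05, 0.01, 0.02, 0.5), (0.01, 0.25, 0.02, 1.0), (0.01, 0.25, 0.3, 0.5), (0.01, 0.25, -0.02, 0.5)]
    )
    def test_invalid_grids_rejected(self, args):
        with pytest.raises(ValueError):
            fc.make_bands(*args)


class TestBandAverage:
    @staticmethod
    def _spectrum(values, freqs):
        return CoherenceSpectrum(values=np.asarray(values, float), freqs=np.asarray(freqs, float))

    def test_constant_spectrum_averages_to_constant(self):
        freqs = np.linspace(0, 0.25, 33)
        spec = self._spectrum(np.full((3, 3, 33), 0.7), freqs)
        out = fc.band_average(spec, Band(0.05, 0.1))
        np.testing.assert_allclose(out.values, 0.7)

    def test_full_grid_band_equals_direct_mean(self):
        rng = np.random.default_rng(10)
        freqs = np.linspace(0.001, 0.25, 40)
        vals = rng.random((2, 2, 40))
        spec = self._spectrum(vals, freqs)
        out = fc.band_average(spec, Band(0.0005, 0.26), include_hi=True)
        np.testing.assert_allclose(out.values, vals.mean(axis=2), atol=1e-14)

    def test_two_point_band_is_arithmetic_mean(self):
        freqs = np.array([0.01, 0.02, 0.03, 0.05])
        vals = np.zeros((2, 2, 4))
        vals[0, 1] = vals[1, 0] = [0.9, 0.2, 0.4, 0.8]  # points at 0.02, 0.03 in [0.015, 0.035)
        spec = self._spectrum(vals, freqs)
        out = fc.band_average(spec, Band(0.015, 0.035))
        assert out.values[0, 1] == pytest.approx(0.3)

    def test_empty_band_is_fatal_and_names_band(self):
        spec = self._spectrum(np.full((2, 2, 3), 0.5), np.array([0.1, 0.2, 0.3]))
        with pytest.raises(ValueError, match="0.01"):
            fc.band_average(spec, Band(0.01, 0.02))


class TestSystemCurves:
    def test_three_roi_hand_enumeration(self):
        import pandas as pd

        table = pd.DataFrame({"system": ["a", "a", "b"]})
        vals = np.array([[1.0, 0.4, 0.6], [0.4, 1.0, 0.2], [0.6, 0.2, 1.0]])
        curves = fc.system_curves([fc.CoherenceMatrix(vals, Band(0.01, 0.03))], table)
        # pairs: (1,2) intra=0.4; (1,3),(2,3) inter mean=(0.6+0.2)/2
        assert curves["intra"][0] == pytest.approx(0.4)
        assert curves["inter"][0] == pytest.approx(0.4)

    def test_single_system_reports_missing_inter(self):
        import pandas as pd

        table = pd.DataFrame({"system": ["a", "a", "a"]})
        vals = np.eye(3) * 0.0 + 0.5
        curves = fc.system_curves([fc.CoherenceMatrix(vals, Band(0.01, 0.03))], table)
        assert curves["inter"][0] is None
        assert curves["intra"][0] == pytest.approx(0.5)

    def test_planted_cohort_curves_peak_in_coupled_bands(self, small_cohort_spectra):
        """Cohort-mean intra and inter curves attain their two largest values
        in the bands containing 0.02 and 0.08 Hz."""
        import pandas as pd

        cfg, panels, spectra = small_cohort_spectra
        bands = fc.make_bands(0.01, 0.25, 0.02, 0.5)
        table = pd.DataFrame({"system": [f"sys{c}" for c in cfg.planted_partition]})
        mean_mats = []
        for i, band in enumerate(bands):
            mats = [fc.band_average(sp, band, include_hi=(i == len(bands) - 1)) for sp in spectra]
            mean_mats.append(fc.CoherenceMatrix(np.mean([m.values for m in mats], axis=0), band))
        curves = fc.system_curves(mean_mats, table, bands)

        def overlaps(band, lo, hi):
            return band.lo < hi - 1e-12 and band.hi > lo + 1e-12

        for key in ("intra", "inter"):
            vals = np.array(curves[key])
            in_vlf = np.array([overlaps(b, *cfg.bands[0]) for b in bands])
            in_lf = np.array([overlaps(b, *cfg.bands[1]) for b in bands])
            outside = ~(in_vlf | in_lf)
            # each planted band's best grid band beats every uncoupled band
            assert vals[in_vlf].max() > vals[outside].max()
            assert vals[in_lf].max() > vals[outside].max()
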