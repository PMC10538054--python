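"""Spectrum preprocessing: baseline, smoothing, calibration, peaks, QC."""

import numpy as np
import pandas as pd
import pytest

import maldilip as m
from maldilip.preprocess import (
    CalibrationConfig,
    LockMassError,
    Peak,
    PeakList,
    ProfileSpectrum,
    _blockwise_mad_noise,
    build_feature_matrix,
    extract_feature_matrix,
    mean_spectrum,
    recalibrate_spectrum,
    replicate_cv,
    snip_baseline,
)


def _spec(mz, intensity, **kw):
    return ProfileSpectrum(np.asarray(mz, float), np.asarray(intensity, float), **kw)


class TestSnipBaseline:
    def test_constant_spectrum_is_its_own_baseline(self):
        mz = np.arange(100, 110, 0.01)
        s = _spec(mz, np.full(mz.size, 3.7))
        b = snip_baseline(s, 50)
        assert np.allclose(b, 3.7, atol=1e-9)

    def test_linear_ramp_recovered(self):
        # midpoint clipping leaves a peak-free ramp untouched in linear space;
        # the log-log compression is for spectra with peaks, not tested here
        mz = np.arange(0, 10, 0.01)
        ramp = np.linspace(1, 9, mz.size)
        b = snip_baseline(_spec(mz, ramp), 100, lls=False)
        resid = ramp - b
        assert resid.max() < 0.01 * (ramp.max() - ramp.min())

    def test_gaussian_peak_removed(self):
        mz = np.arange(0, 20, 0.01)
        peak = 100 * np.exp(-0.5 * ((mz - 10) / 0.03) ** 2)  # sigma = 3 bins
        b = snip_baseline(_spec(mz, peak), 30)
        assert b[np.argmin(np.abs(mz - 10))] < 0.05 * 100

    def test_baseline_below_envelope_and_residual_nonnegative(self, rng):
        mz = np.arange(100, 300, 0.01)
        v = 5 * np.exp(-(mz - 100) / 80) + np.abs(rng.normal(0, 0.1, mz.size))
        s = _spec(mz, v)
        b = snip_baseline(s, 100)
        assert np.all(b <= v + 1e-12)
        sub = m.subtract_baseline(s, 100)
        assert np.all(sub.intensity >= 0)

    def test_too_many_iterations_rejected(self):
        s = _spec(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            snip_baseline(s, 5)


class TestSavgolSmooth:
    def test_quadratic_reproduced_exactly(self):
        mz = np.arange(0, 10, 0.1)
        quad = 3 + 0.5 * mz + 0.2 * mz**2
        out = m.savgol_smooth(_spec(mz, quad), half_window=5, poly_order=2)
        assert np.allclose(out.intensity, quad, atol=1e-9)

    def test_constant_unchanged(self):
        s = _spec(np.arange(50.0), np.full(50, 2.0))
        assert np.allclose(m.savgol_smooth(s).intensity, 2.0)

    def test_white_noise_variance_reduced(self, rng):
        x = rng.normal(5.0, 1.0, 20000).clip(0)
        out = m.savgol_smooth(_spec(np.arange(20000.0), x), half_window=5, poly_order=2)
        # the filter's coefficient norm bounds the output variance well below 0.35
        assert out.intensity.var() < 0.35

    def test_order_must_fit_window(self):
        s = _spec(np.arange(50.0), np.ones(50))
        with pytest.raises(ValueError):
            m.savgol_smooth(s, half_window=1, poly_order=3)


class TestTicNormalize:
    def test_sum_is_one(self, rng):
        s = _spec(np.arange(100.0), rng.uniform(0, 5, 100))
        out, scale = m.tic_normalize(s)
        assert out.intensity.sum() == pytest.approx(1.0, abs=1e-12)
        assert scale == pytest.approx(s.intensity.sum())

    def test_scale_invariance_and_idempotence(self, rng):
        v = rng.uniform(0, 5, 100)
        s1, _ = m.tic_normalize(_spec(np.arange(100.0), v))
        s7, _ = m.tic_normalize(_spec(np.arange(100.0), 7 * v))
        assert np.allclose(s1.intensity, s7.intensity)
        twice, _ = m.tic_normalize(s1)
        assert np.allclose(twice.intensity, s1.intensity)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            m.tic_normalize(_spec(np.arange(10.0), np.zeros(10)))


class TestLockMassRecalibration:
    def test_peaklist_lands_on_lock(self):
        pl = PeakList([Peak(400.0, 1.0, 10.0), Peak(760.70, 8.0, 50.0)], +1)
        out, shift = m.lock_mass_recalibrate(pl, CalibrationConfig())
        factor = 760.5851 / 760.70
        assert out.peaks[-1].mz == pytest.approx(760.5851, abs=1e-9)
        assert out.peaks[0].mz == pytest.approx(400.0 * factor, abs=1e-9)
        assert shift == pytest.approx(factor - 1.0)

    def test_relative_distances_preserved(self):
        pl = PeakList([Peak(400.0, 1, 1), Peak(600.0, 1, 1), Peak(760.7, 5, 9)], +1)
        out, _ = m.lock_mass_recalibrate(pl)
        assert out.peaks[1].mz / out.peaks[0].mz == pytest.approx(600.0 / 400.0, rel=1e-12)

    def test_missing_lock_mass_raises(self):
        pl = PeakList([Peak(500.0, 1.0, 5.0)], +1)
        with pytest.raises(LockMassError):
            m.lock_mass_recalibrate(pl)
        with pytest.raises(LockMassError):
            m.lock_mass_recalibrate(PeakList([], +1))

    def test_profile_drift_corrected_below_bound(self, tissue_panel):
        # +300 ppm simulated drift must come back under the 0.05% accuracy bound
        design = m.SimulationDesign(groups=(("A", 2), ("B", 2)), replicates=1, seed=5)
        spec = m.simulate_profile_spectrum(tissue_panel, design, drift_ppm=300.0, seed=7)
        sub = m.subtract_baseline(spec, 100)
        cal, shift = recalibrate_spectrum(sub)
        prov = tissue_panel.provenance()
        mono = prov[(prov.isotope == 0) & (prov.rel_abundance >= 0.3)]
        pl = m.detect_peaks(cal, 3.0)
        errs = [
            np.abs(pl.mz - t).min() / t
            for t in mono.theo_mz
            if np.abs(pl.mz - t).min() < 0.3
        ]
        assert len(errs) > 20
        assert np.mean(np.asarray(errs) < 5e-4) >= 0.99
        assert shift == pytest.approx(-300e-6, rel=0.1)


class TestAlignment:
    @staticmethod
    def _peaky(mz, centers, heights, shift=0.0):
        v = np.zeros(mz.size)
        for c, h in zip(centers, heights):
            v += h * np.exp(-0.5 * ((mz - c - shift) / 0.05) ** 2)
        return v

    def test_identical_spectra_unchanged(self):
        mz = np.arange(100, 200, 0.01)
        v = self._peaky(mz, [120, 150, 180], [5, 9, 4])
        out = m.align_spectra([_spec(mz, v), _spec(mz, v)], n_anchor_peaks=3)
        for s in out:
            assert np.allclose(s.intensity, v, atol=1e-9)

    def test_rigid_shift_recovered(self):
        mz = np.arange(100, 200, 0.01)
        centers, heights = [120, 150, 180], [5, 9, 4]
        ref = self._peaky(mz, centers, heights)
        shifted = self._peaky(mz, centers, heights, shift=0.3)
        spectra = [_spec(mz, ref)] * 3 + [_spec(mz, shifted)]
        out = m.align_spectra(spectra, n_anchor_peaks=3, match_window=0.4)
        aligned = out[-1].intensity
        for c in centers:
            apex = mz[np.argmax(aligned * (np.abs(mz - c) < 0.2))]
            assert abs(apex - c) < 0.011

    def test_spectrum_without_anchors_warns_identity(self):
        mz = np.arange(100, 200, 0.01)
        ref = self._peaky(mz, [120, 150], [5, 9])
        flat = np.zeros(mz.size)
        with pytest.warns(UserWarning, match="anchors"):
            out = m.align_spectra(
                [_spec(mz, ref), _spec(mz, ref), _spec(mz, flat)], n_anchor_peaks=2
            )
        assert np.allclose(out[-1].intensity, flat)


class TestDetectPeaks:
    def test_three_gaussians_over_noise(self, rng):
        mz = np.arange(100, 400, 0.01)
        v = np.abs(rng.normal(0, 0.05, mz.size))
        for c in (150.0, 250.0, 350.0):
            v += 8 * np.exp(-0.5 * ((mz - c) / 0.03) ** 2)
        pl = m.detect_peaks(_spec(mz, v), snr_threshold=3.0)
        found = sorted(p.mz for p in pl.peaks if p.intensity > 1)
        assert len(found) == 3
        for got, want in zip(found, (150.0, 250.0, 350.0)):
            assert abs(got - want) <= 0.011

    def test_zero_spectrum_empty(self):
        pl = m.detect_peaks(_spec(np.arange(100.0), np.zeros(100)))
        assert len(pl) == 0

    def test_monotone_in_threshold(self, rng):
        mz = np.arange(100, 200, 0.01)
        v = np.abs(rng.normal(0, 0.05, mz.size)) + 5 * np.exp(
            -0.5 * ((mz - 150) / 0.03) ** 2
        )
        s = _spec(mz, v)
        n = [len(m.detect_peaks(s, t)) for t in (1.0, 3.0, 10.0, np.inf)]
        assert n == sorted(n, reverse=True)
        assert n[-1] == 0


class TestFeatureMatrix:
    def test_identical_peaklists_give_equal_rows(self):
        pls = [
            PeakList([Peak(700.0, 1.0, 5), Peak(800.0, 2.0, 5)], +1, sample_id=s)
            for s in ("a", "b")
        ]
        fm = build_feature_matrix(pls, 5e-4)
        assert fm.values.shape == (2, 2)
        assert np.allclose(fm.values[0], fm.values[1])
        assert np.allclose(fm.feature_mz, [700.0, 800.0])

    def test_near_peaks_merge_within_tolerance(self):
        pls = [
            PeakList([Peak(700.0, 1.0, 5)], +1),
            PeakList([Peak(700.001, 3.0, 5)], +1),
        ]
        fm = build_feature_matrix(pls, 5e-4)
        assert fm.feature_mz.size == 1
        # intensity-weighted consensus m/z
        assert fm.feature_mz[0] == pytest.approx((700.0 + 3 * 700.001) / 4)

    def test_disjoint_lists_are_block_diagonal(self):
        pls = [
            PeakList([Peak(700.0, 1.0, 5)], +1),
            PeakList([Peak(900.0, 2.0, 5)], +1),
        ]
        fm = build_feature_matrix(pls, 5e-4)
        assert fm.values[0, 1] == 0 and fm.values[1, 0] == 0
        assert fm.values[0, 0] > 0 and fm.values[1, 1] > 0

    def test_mixed_polarity_rejected(self):
        with pytest.raises(ValueError, match="polarit"):
            build_feature_matrix(
                [PeakList([Peak(1, 1, 1)], +1), PeakList([Peak(1, 1, 1)], -1)]
            )

    def test_extraction_cannot_drop_features(self):
        mz = np.arange(100, 200, 0.01)
        v = 5 * np.exp(-0.5 * ((mz - 150) / 0.03) ** 2) + 0.01
        spectra = [_spec(mz, v), _spec(mz, 0.5 * v)]
        consensus = PeakList([Peak(150.0, 5.0, 10.0)], +1)
        fm = extract_feature_matrix(spectra, consensus, 1e-4)
        assert fm.values.shape == (2, 1)
        assert fm.values[1, 0] == pytest.approx(0.5 * fm.values[0, 0], rel=0.01)


class TestReplicateCv:
    @staticmethod
    def _fm(values, bio):
        values = np.asarray(values, float)
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(values))], "bio_sample": bio}
        )
        return m.FeatureMatrix(np.array([500.0]), values.reshape(-1, 1), samples)

    def test_identical_replicates_cv_zero(self):
        qc = replicate_cv(self._fm([2.0, 2.0, 2.0], ["x"] * 3))
        assert qc.feature_cv[0] == 0.0 and qc.passed

    def test_hand_computed_cv(self):
        # sd(1, 1, 1.3)/mean(1, 1, 1.3) = 0.17321/1.1
        qc = replicate_cv(self._fm([1.0, 1.0, 1.3], ["x"] * 3))
        assert qc.mean_cv == pytest.approx(0.1575, abs=1e-3)

    def test_triplicates_at_20pct_noise_pass_gate(self, rng):
        n_feat, n_bio = 50, 6
        base = rng.uniform(0.5, 3.0, n_feat)
        rows, bio = [], []
        for b in range(n_bio):
            for _ in range(3):
                sigma = np.sqrt(np.log(1 + 0.2**2))
                rows.append(base * rng.lognormal(0, sigma, n_feat))
                bio.append(f"b{b}")
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(rows))], "bio_sample": bio}
        )
        fm = m.FeatureMatrix(np.arange(n_feat) + 100.0, np.vstack(rows), samples)
        qc = replicate_cv(fm)
        assert qc.mean_cv < 0.50 and qc.passed

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            replicate_cv(self._fm([1.0, 2.0], ["x", "y"]))


def test_mean_spectrum_requires_shared_axis():
    a = _spec(np.arange(10.0), np.ones(10))
    b = _spec(np.arange(11.0), np.ones(11))
    with pytest.raises(ValueError):
        mean_spectrum([a, b])
    avg = mean_spectrum([a, _spec(np.arange(10.0), 3 * np.ones(10))])
    assert np.allclose(avg.intensity, 2.0)


def test_noise_estimator_tracks_scale(rng):
    x = np.abs(rng.normal(0, 2.0, 5000))
    _, noise = _blockwise_mad_noise(x, 200)
    assert 0.5 < np.median(noise) / 2.0 < 1.5
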