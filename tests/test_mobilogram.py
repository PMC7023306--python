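import math

import numpy as np
import pytest

from timsccs.mobilogram import (
    FrameStack,
    Mobilogram,
    apex_ccs,
    extract_bpm,
    extract_eim,
    peak_purity,
    pick_peaks,
    smooth,
    tims_resolving_power,
)
from timsccs.physics import fit_calibration, inverse_k0_from_ccs

from conftest import gaussian_trace

AXIS = np.linspace(0.4, 1.8, 1000)


def frames_from_traces(traces):
    """Build a FrameStack from {mz: per-bin intensity array}."""
    spectra = []
    for i in range(AXIS.size):
        mzs, intens = [], []
        for mz, trace in traces.items():
            if trace[i] > 1e-9:
                mzs.append(mz)
                intens.append(trace[i])
        spectra.append((np.array(mzs), np.array(intens)))
    return FrameStack(raw_axis=AXIS, spectra=spectra)


class TestExtraction:
    def test_eim_of_single_species_is_exact(self):
        trace = gaussian_trace(AXIS, 1.1, 0.02, 1000.0)
        frames = frames_from_traces({609.146: trace})
        eim = extract_eim(frames, 609.146, tol=0.01)
        expected = np.where(trace > 1e-9, trace, 0.0)
        np.testing.assert_allclose(eim.intensity, expected)

    def test_absent_target_gives_zero_eim(self):
        frames = frames_from_traces({609.146: gaussian_trace(AXIS, 1.1, 0.02, 1000.0)})
        eim = extract_eim(frames, 500.0, tol=0.01)
        assert eim.intensity.sum() == 0.0

    def test_tolerance_separates_then_merges_close_species(self):
        a = gaussian_trace(AXIS, 1.0, 0.02, 1000.0)
        b = gaussian_trace(AXIS, 1.3, 0.02, 800.0)
        frames = frames_from_traces({609.10: a, 609.60: b})
        narrow = extract_eim(frames, 609.10, tol=0.01)
        np.testing.assert_allclose(narrow.intensity, np.where(a > 1e-9, a, 0.0))
        wide = extract_eim(frames, 609.10, tol=1.0)
        # brute-force oracle: the per-bin sum of both species
        expected = np.where(a > 1e-9, a, 0.0) + np.where(b > 1e-9, b, 0.0)
        np.testing.assert_allclose(wide.intensity, expected)

    def test_bpm_equals_eim_for_single_species(self):
        trace = gaussian_trace(AXIS, 1.1, 0.02, 1000.0)
        frames = frames_from_traces({609.146: trace})
        np.testing.assert_allclose(
            extract_bpm(frames).intensity,
            extract_eim(frames, 609.146, tol=0.01).intensity,
        )

    def test_bpm_is_per_bin_maximum(self):
        a = gaussian_trace(AXIS, 1.0, 0.02, 1000.0)
        b = gaussian_trace(AXIS, 1.4, 0.02, 700.0)
        frames = frames_from_traces({300.0: a, 700.0: b})
        bpm = extract_bpm(frames)
        brute = np.array(
            [max(i.max() if i.size else 0.0, 0.0) for _, i in frames.spectra]
        )
        np.testing.assert_allclose(bpm.intensity, brute)

    def test_empty_frames_give_empty_mobilogram(self):
        frames = FrameStack(raw_axis=np.array([]), spectra=[])
        assert extract_eim(frames, 609.0, tol=0.01).intensity.size == 0


class TestSmoothing:
    def test_constant_trace_unchanged(self):
        m = Mobilogram(AXIS, np.full(AXIS.size, 500.0))
        np.testing.assert_allclose(smooth(m).intensity, 500.0, atol=1e-9)

    def test_gaussian_apex_barely_moves(self):
        sigma = 4 * float(np.diff(AXIS).mean())
        m = Mobilogram(AXIS, gaussian_trace(AXIS, 1.1, sigma, 1000.0))
        before = pick_peaks(m)[0].apex_inv_k0
        after = pick_peaks(smooth(m))[0].apex_inv_k0
        assert abs(after - before) < 0.25 * m.bin_spacing

    def test_total_intensity_preserved_for_interior_peak(self):
        m = Mobilogram(AXIS, gaussian_trace(AXIS, 1.1, 0.02, 1000.0))
        sm = smooth(m)
        assert sm.intensity.sum() == pytest.approx(m.intensity.sum(), rel=0.01)

    def test_two_cycles_equals_applying_twice(self):
        m = Mobilogram(AXIS, gaussian_trace(AXIS, 1.1, 0.02, 1000.0))
        np.testing.assert_allclose(
            smooth(m, cycles=2).intensity, smooth(smooth(m)).intensity, atol=1e-9
        )

    def test_window_below_five_points_rejected(self):
        coarse = np.linspace(0.4, 1.8, 60)
        m = Mobilogram(coarse, np.ones(60))
        with pytest.raises(ValueError, match="window"):
            smooth(m, window_mobility=0.005)

    def test_no_new_local_maxima_created(self):
        y = (
            gaussian_trace(AXIS, 0.8, 0.02, 1000.0)
            + gaussian_trace(AXIS, 1.2, 0.02, 600.0)
            + gaussian_trace(AXIS, 1.5, 0.02, 300.0)
        )
        sm = smooth(Mobilogram(AXIS, y)).intensity
        interior = (sm[1:-1] > sm[:-2]) & (sm[1:-1] > sm[2:])
        significant = interior & (sm[1:-1] > 0.01 * sm.max())
        assert significant.sum() <= 3


class TestPeakPicking:
    def test_single_gaussian_one_peak_at_center(self):
        m = Mobilogram(AXIS, gaussian_trace(AXIS, 1.1, 0.02, 1000.0))
        peaks = pick_peaks(m)
        assert len(peaks) == 1
        assert abs(peaks[0].apex_inv_k0 - 1.1) < m.bin_spacing / 2
        # FWHM of a Gaussian is 2.3548 sigma
        assert peaks[0].fwhm_inv_k0 == pytest.approx(2.3548 * 0.02, rel=0.02)
        assert peaks[0].base_width_inv_k0 == pytest.approx(4 * 0.02, rel=0.02)

    def test_relative_intensity_threshold_suppresses_minor_peak(self):
        y = gaussian_trace(AXIS, 0.9, 0.02, 1000.0) + gaussian_trace(
            AXIS, 1.4, 0.02, 100.0
        )
        m = Mobilogram(AXIS, y)
        assert len(pick_peaks(m, rel_intensity_threshold=15)) == 1
        assert len(pick_peaks(m, rel_intensity_threshold=5)) == 2

    def test_min_valley_merges_shallow_doublet(self):
        # two overlapping Gaussians whose valley sits at ~95% of the lower apex
        y = gaussian_trace(AXIS, 1.100, 0.030, 1000.0) + gaussian_trace(
            AXIS, 1.172, 0.030, 900.0
        )
        from scipy.signal import find_peaks as _fp

        idx, _ = _fp(y)
        valley_frac = y[idx[0] : idx[1]].min() / min(y[idx[0]], y[idx[1]])
        assert 0.90 < valley_frac < 0.96  # fixture sanity
        m = Mobilogram(AXIS, y)
        assert len(pick_peaks(m, min_valley=10)) == 1
        assert len(pick_peaks(m, min_valley=4)) == 2

    def test_well_separated_gaussians_all_found(self):
        centers = [0.7, 1.0, 1.3, 1.6]
        y = sum(gaussian_trace(AXIS, c, 0.015, 1000.0) for c in centers)
        peaks = pick_peaks(Mobilogram(AXIS, y))
        assert len(peaks) == len(centers)
        for p, c in zip(peaks, centers):
            assert abs(p.apex_inv_k0 - c) < float(np.diff(AXIS).mean()) / 2

    def test_all_zero_mobilogram_empty(self):
        assert pick_peaks(Mobilogram(AXIS, np.zeros(AXIS.size))) == []

    def test_parameter_bounds(self):
        m = Mobilogram(AXIS, gaussian_trace(AXIS, 1.1, 0.02, 10.0))
        with pytest.raises(ValueError):
            pick_peaks(m, sensitivity=0)
        with pytest.raises(ValueError):
            pick_peaks(m, min_valley=150)


class TestPurity:
    def _frames_with_contaminant(self, target_frac):
        target = gaussian_trace(AXIS, 1.1, 0.02, 1000.0 * target_frac)
        other = gaussian_trace(AXIS, 1.1, 0.02, 1000.0 * (1 - target_frac))
        return frames_from_traces({609.146: target, 455.2: other})

    def test_pure_species_purity_one(self):
        frames = frames_from_traces({609.146: gaussian_trace(AXIS, 1.1, 0.02, 1000.0)})
        peak = pick_peaks(extract_eim(frames, 609.146, tol=0.01))[0]
        assert peak_purity(frames, peak, 609.146, tol=0.01) == pytest.approx(1.0)

    def test_absent_target_purity_zero(self):
        frames = frames_from_traces({455.2: gaussian_trace(AXIS, 1.1, 0.02, 1000.0)})
        peak = pick_peaks(extract_bpm(frames))[0]
        assert peak_purity(frames, peak, 609.146, tol=0.01) == 0.0

    def test_eighty_twenty_mixture(self):
        frames = self._frames_with_contaminant(0.8)
        peak = pick_peaks(extract_bpm(frames))[0]
        assert peak_purity(frames, peak, 609.146, tol=0.01) == pytest.approx(0.8)

    def test_matches_brute_force_double_sum(self):
        frames = self._frames_with_contaminant(0.65)
        peak = pick_peaks(extract_bpm(frames))[0]
        lo = peak.apex_inv_k0 - peak.base_width_inv_k0 / 2
        hi = peak.apex_inv_k0 + peak.base_width_inv_k0 / 2
        target = total = 0.0
        for pos, (mz, inten) in zip(frames.raw_axis, frames.spectra):
            if lo <= pos <= hi:
                for m, i in zip(mz, inten):
                    total += i
                    if abs(m - 609.146) <= 0.01:
                        target += i
        assert peak_purity(frames, peak, 609.146, tol=0.01) == pytest.approx(
            target / total, rel=1e-12
        )


class TestApexCCSAndResolvingPower:
    def test_identity_calibration_matches_direct_conversion(self, ctx):
        from timsccs.physics import ccs_from_inverse_k0

        inv = inverse_k0_from_ccs(231.05, 609.14610, ctx)
        frames = frames_from_traces(
            {609.14610: gaussian_trace(AXIS, inv, 0.012, 1000.0)}
        )
        peak = pick_peaks(extract_eim(frames, 609.14610, tol=0.01))[0]
        ccs = apex_ccs(peak, None, 609.14610, ctx)
        assert ccs == pytest.approx(
            ccs_from_inverse_k0(peak.apex_inv_k0, 609.14610, ctx), rel=1e-12
        )
        assert abs(ccs - 231.05) / 231.05 < 5e-4

    def test_distorted_axis_recovered_through_calibration(self, tune_mix_table, ctx):
        slope, intercept = 1.04, -0.015
        inv = inverse_k0_from_ccs(231.05, 609.14610, ctx)
        raw_center = (inv - intercept) / slope
        frames = frames_from_traces(
            {609.14610: gaussian_trace(AXIS, raw_center, 0.012, 1000.0)}
        )
        ref = tune_mix_table.reference_inverse_k0(ctx)
        model = fit_calibration((ref - intercept) / slope, tune_mix_table, ctx)
        peak = pick_peaks(extract_eim(frames, 609.14610, tol=0.01))[0]
        ccs = apex_ccs(peak, model, 609.14610, ctx)
        assert abs(ccs - 231.05) / 231.05 < 5e-4
        assert peak.fwhm_ccs is not None and peak.fwhm_ccs > 0

    @pytest.mark.parametrize(
        "apex, fwhm, expected", [(160.0, 4.0, 40.0), (160.0, 4.0 / 3.0, 120.0)]
    )
    def test_resolving_power_regimes(self, apex, fwhm, expected):
        from timsccs.mobilogram import MobilityPeak

        peak = MobilityPeak(
            apex_inv_k0=1.0,
            height=100.0,
            fwhm_inv_k0=0.01,
            base_width_inv_k0=0.017,
            area=1.0,
            apex_ccs=apex,
            fwhm_ccs=fwhm,
            base_width_ccs=fwhm * 4 / 2.3548,
        )
        assert tims_resolving_power(peak) == pytest.approx(expected, rel=1e-6)

    def test_resolving_power_scale_invariant(self):
        m1 = Mobilogram(AXIS, gaussian_trace(AXIS, 1.1, 0.015, 1000.0))
        m2 = Mobilogram(AXIS, gaussian_trace(AXIS, 1.1, 0.015, 50000.0))
        r1 = tims_resolving_power(pick_peaks(m1)[0])
        r2 = tims_resolving_power(pick_peaks(m2)[0])
        assert r1 == pytest.approx(r2, rel=1e-9)
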