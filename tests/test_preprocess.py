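import numpy as np
import pytest

from toxprint.io import RawSpectrum
from toxprint.peaks import Peak, PeakList
from toxprint.preprocess import (
    calibrate,
    estimate_baseline,
    select_calibration_peaks,
    smooth,
    subtract_baseline,
)


def _flat(n=2000, value=100.0):
    return RawSpectrum(mz=2000.0 + np.arange(n) * 1.0, intensity=np.full(n, value))


class TestSmooth:
    def test_constant_spectrum_unchanged(self):
        out = smooth(_flat(), width_channels=50)
        np.testing.assert_allclose(out.intensity, 100.0)

    def test_width_one_is_identity(self):
        rng = np.random.default_rng(0)
        spec = RawSpectrum(mz=np.arange(100.0) + 2000, intensity=rng.uniform(0, 10, 100))
        np.testing.assert_array_equal(smooth(spec, 1).intensity, spec.intensity)

    def test_impulse_matches_explicit_convolution(self):
        """Oracle: direct convolution loop over a 51-sample boxcar."""
        n, w = 501, 51
        intensity = np.zeros(n)
        intensity[250] = 1.0
        spec = RawSpectrum(mz=np.arange(n) + 2000.0, intensity=intensity)
        out = smooth(spec, width_channels=51).intensity
        expected = np.zeros(n)
        half = w // 2
        for i in range(half, n - half):  # interior only: full windows
            expected[i] = intensity[i - half : i + half + 1].sum() / w
        np.testing.assert_allclose(out[half : n - half], expected[half : n - half])
        assert out[250] == pytest.approx(1.0 / 51)

    def test_even_width_rounded_up_to_odd(self):
        n = 201
        intensity = np.zeros(n)
        intensity[100] = 1.0
        spec = RawSpectrum(mz=np.arange(n) + 2000.0, intensity=intensity)
        np.testing.assert_array_equal(
            smooth(spec, 50).intensity, smooth(spec, 51).intensity
        )

    def test_total_ion_current_preserved_for_interior_signal(self):
        rng = np.random.default_rng(1)
        intensity = np.zeros(5000)
        intensity[1000:4000] = rng.uniform(0, 100, 3000)
        spec = RawSpectrum(mz=np.arange(5000.0) + 2000, intensity=intensity)
        out = smooth(spec, 51)
        assert out.intensity.sum() == pytest.approx(intensity.sum(), rel=0.005)

    def test_window_longer_than_spectrum_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            smooth(_flat(20), width_channels=51)


class TestBaseline:
    def test_flat_spectrum_recovered_exactly_in_interior(self):
        out = estimate_baseline(_flat(value=100.0), width_channels=100).values
        np.testing.assert_allclose(out, 100.0)

    def test_decaying_exponential_recovered_within_two_percent(self):
        # decay scale (5000 Da) far above the window span (101 Da)
        mz = 2000.0 + np.arange(18001)
        amplitude = 800.0
        truth = amplitude * np.exp(-(mz - 2000.0) / 5000.0)
        spec = RawSpectrum(mz=mz, intensity=truth)
        estimate = estimate_baseline(spec, width_channels=100).values
        assert np.max(np.abs(estimate - truth)) < 0.02 * amplitude

    def test_narrow_peak_not_absorbed(self):
        mz = 2000.0 + np.arange(2001)
        intensity = 500.0 * np.exp(-0.5 * ((mz - 3000.0) / 3.0) ** 2)
        spec = RawSpectrum(mz=mz, intensity=intensity)
        baseline = estimate_baseline(spec, width_channels=100).values
        apex = int(np.argmin(np.abs(mz - 3000.0)))
        assert baseline[apex] < 1.0

    def test_window_errors(self):
        with pytest.raises(ValueError):
            estimate_baseline(_flat(), width_channels=2)
        with pytest.raises(ValueError, match="exceeds"):
            estimate_baseline(_flat(50), width_channels=101)


class TestSubtractBaseline:
    def test_subtracting_self_gives_zero(self):
        from toxprint.preprocess import BaselineCurve

        spec = _flat(value=42.0)
        out, n_clipped = subtract_baseline(spec, BaselineCurve(spec.intensity.copy()))
        np.testing.assert_array_equal(out.intensity, 0.0)
        assert n_clipped == 0

    def test_zero_baseline_is_identity_and_clipping_counted(self):
        from toxprint.preprocess import BaselineCurve

        spec = _flat(value=10.0)
        out, n = subtract_baseline(spec, BaselineCurve(np.zeros(len(spec))))
        np.testing.assert_array_equal(out.intensity, spec.intensity)
        assert n == 0
        over = BaselineCurve(np.full(len(spec), 15.0))
        clipped, n = subtract_baseline(spec, over)
        assert np.all(clipped.intensity == 0.0)
        assert n == len(spec)

    def test_length_mismatch_rejected(self):
        from toxprint.preprocess import BaselineCurve

        with pytest.raises(ValueError, match="length"):
            subtract_baseline(_flat(100), BaselineCurve(np.zeros(99)))


def _peaklist(masses, sample="s", abundance=500.0):
    return PeakList(
        sample_id=sample,
        condition=None,
        peaks=[Peak(mass=m, abundance=abundance, snr=10.0) for m in masses],
    )


class TestSelectCalibrationPeaks:
    def test_ten_of_twenty_shared_masses(self):
        shared = np.linspace(3000, 19000, 20)
        lists = [_peaklist(shared, f"s{i}") for i in range(12)]
        refs = select_calibration_peaks(lists, n_refs=10)
        assert len(refs) == 10
        assert all(any(abs(r - m) < 1e-6 for m in shared) for r in refs)
        # evenly spread: extremes always kept
        assert refs[0] == pytest.approx(shared[0])
        assert refs[-1] == pytest.approx(shared[-1])

    def test_minority_peak_never_selected(self):
        shared = np.linspace(3000, 19000, 12)
        lists = [_peaklist(shared, f"s{i}") for i in range(12)]
        lists[0] = _peaklist(np.append(shared, 10_101.0), "s0")
        refs = select_calibration_peaks(lists, n_refs=12)
        assert not any(abs(r - 10_101.0) < 0.5 for r in refs)

    def test_fewer_qualifying_than_requested_warns(self):
        shared = np.linspace(4000, 16000, 5)
        lists = [_peaklist(shared, f"s{i}") for i in range(6)]
        with pytest.warns(UserWarning, match="5 qualifying"):
            refs = select_calibration_peaks(lists, n_refs=10)
        assert len(refs) == 5

    def test_too_few_lists_rejected(self):
        with pytest.raises(ValueError, match="3 peak lists"):
            select_calibration_peaks([_peaklist([5000.0])] * 2)


class TestCalibrate:
    def test_identity_drift_recovers_identity_map(self):
        refs = np.linspace(3000, 19000, 10)
        observed = _peaklist(refs)
        calibrated, model = calibrate(observed, refs)
        assert model.slope == pytest.approx(1.0, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(calibrated.masses, refs, atol=1e-9)

    def test_synthetic_sqrt_domain_drift_recovered(self):
        """Oracle: the generator's own drift coefficients (a=0, b=1.0005)."""
        refs = np.linspace(3000, 19000, 10)
        b_true = 1.0005
        drifted = (b_true * np.sqrt(refs)) ** 2
        observed = _peaklist(drifted)
        calibrated, model = calibrate(observed, refs, tolerance_da=25.0)
        # fitted map inverts the drift: slope should be 1/b
        assert model.slope == pytest.approx(1.0 / b_true, abs=1e-5)
        drifted_17k = (b_true * np.sqrt(17000.0)) ** 2
        corrected = model.apply(np.array([drifted_17k]))[0]
        assert abs(corrected - 17000.0) < 0.5

    def test_rms_residual_never_increases(self):
        rng = np.random.default_rng(4)
        refs = np.linspace(3000, 19000, 10)
        noisy = refs + rng.normal(0, 0.5, refs.size)
        observed = _peaklist(noisy)
        _, model = calibrate(observed, refs, tolerance_da=5.0)
        pre_rms = np.sqrt(np.mean((noisy - refs) ** 2))
        assert model.rms_residual_da <= pre_rms + 1e-12

    def test_calibration_idempotent(self):
        refs = np.linspace(3000, 19000, 10)
        drifted = (0.01 + 1.0003 * np.sqrt(refs)) ** 2
        once, _ = calibrate(_peaklist(drifted), refs, tolerance_da=25.0)
        twice, model2 = calibrate(once, refs, tolerance_da=25.0)
        np.testing.assert_allclose(twice.masses, once.masses, rtol=1e-9)
        assert model2.slope == pytest.approx(1.0, abs=1e-9)

    def test_single_match_rejected(self):
        refs = np.array([5000.0, 12000.0])
        observed = _peaklist([5000.5, 20000.0])  # only the first is matchable
        with pytest.raises(ValueError, match="at least 2"):
            calibrate(observed, refs, tolerance_da=2.0)
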