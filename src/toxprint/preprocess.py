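"""Spectrum preprocessing: smoothing, baseline removal, internal recalibration.

Widths are expressed in channels (grid samples) and rounded up to odd so the
filters stay centred. The processing order used by the pipeline is
smooth -> estimate/subtract baseline -> detect peaks -> recalibrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import RawSpectrum

__all__ = [
    "smooth",
    "estimate_baseline",
    "subtract_baseline",
    "select_calibration_peaks",
    "calibrate",
    "BaselineCurve",
    "CalibrationModel",
]


def _odd(width: int) -> int:
    width = int(width)
    return width if width % 2 == 1 else width + 1


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge windows shrink to the available samples."""
    half = window // 2
    padded = np.concatenate([np.zeros(1), np.cumsum(x)])
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (padded[hi] - padded[lo]) / (hi - lo)


def smooth(spectrum: RawSpectrum, width_channels: int = 50) -> RawSpectrum:
    """Average smoothing with the given filter width (in channels).

    The window is rounded up to odd for centring; edges use shrinking
    windows, so a constant spectrum passes through unchanged and total ion
    current is preserved for interior-supported signals.
    """
    if width_channels < 1:
        raise ValueError("width_channels must be >= 1")
    window = _odd(width_channels)
    if window > len(spectrum):
        raise ValueError(
            f"smoothing window {window} exceeds spectrum length {len(spectrum)}"
        )
    if window == 1:
        return spectrum.with_intensity(spectrum.intensity.copy())
    return spectrum.with_intensity(_running_mean(spectrum.intensity, window))


@dataclass
class BaselineCurve:
    """Estimated chemical-noise baseline on the spectrum grid (mV)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("baseline contains non-finite values")


def estimate_baseline(spectrum: RawSpectrum, width_channels: int = 100) -> BaselineCurve:
    """Morphological baseline: rolling minimum followed by rolling mean.

    The minimum filter slides under peaks narrower than the window; the mean
    of the same width smooths the staircase the minimum leaves behind.
    """
    if width_channels < 3:
        raise ValueError("width_channels must be >= 3")
    window = _odd(width_channels)
    if window > len(spectrum):
        raise ValueError(
            f"baseline window {window} exceeds spectrum length {len(spectrum)}"
        )
    eroded = ndimage.minimum_filter1d(spectrum.intensity, size=window, mode="nearest")
    return BaselineCurve(values=_running_mean(eroded, window))


def subtract_baseline(
    spectrum: RawSpectrum, baseline: BaselineCurve
) -> tuple[RawSpectrum, int]:
    """Subtract a baseline, clipping at zero; returns (spectrum, n_clipped)."""
    if baseline.values.size != len(spectrum):
        raise ValueError(
            f"baseline length {baseline.values.size} != spectrum length {len(spectrum)}"
        )
    diff = spectrum.intensity - baseline.values
    n_clipped = int(np.sum(diff < 0))
    return spectrum.with_intensity(np.maximum(diff, 0.0)), n_clipped


# ---------------------------------------------------------------------------
# Internal calibration
# ---------------------------------------------------------------------------

def _match_tolerance(mass: np.ndarray, tol_da: float, tol_ppm: float) -> np.ndarray:
    return np.maximum(tol_da, tol_ppm * 1e-6 * np.asarray(mass, dtype=float))


def select_calibration_peaks(
    peaklists,
    n_refs: int = 10,
    majority_frac: float = 0.5,
    tol_da: float = 2.0,
    tol_ppm: float = 500.0,
) -> np.ndarray:
    """Pick reference masses present in the majority of spectra, evenly spread.

    Peak masses are pooled and single-linkage clustered with the matching
    tolerance; clusters seen in more than ``majority_frac`` of the input
    lists qualify, and ``n_refs`` of them are chosen by greedy
    farthest-point selection over mass so the references span the range.
    """
    if len(peaklists) < 3:
        raise ValueError("need at least 3 peak lists to select calibration references")
    from .align import _cluster_masses

    pooled_masses = []
    pooled_samples = []
    for i, pl in enumerate(peaklists):
        for peak in pl.peaks:
            pooled_masses.append(peak.mass)
            pooled_samples.append(i)
    pooled_masses = np.asarray(pooled_masses, dtype=float)
    pooled_samples = np.asarray(pooled_samples)
    labels, medians = _cluster_masses(pooled_masses, tol_da, tol_ppm)

    qualifying = []
    for cid, median in enumerate(medians):
        n_present = np.unique(pooled_samples[labels == cid]).size
        if n_present > majority_frac * len(peaklists):
            qualifying.append(median)
    if len(qualifying) < 2:
        raise ValueError(
            f"only {len(qualifying)} consensus peaks present in the majority of "
            f"spectra; need at least 2 for calibration"
        )
    qualifying = np.sort(np.asarray(qualifying))
    if len(qualifying) <= n_refs:
        if len(qualifying) < n_refs:
            warnings.warn(
                f"only {len(qualifying)} qualifying reference peaks available "
                f"(requested {n_refs})",
                stacklevel=2,
            )
        return qualifying

    # greedy farthest-point: start from the extremes, add the mass farthest
    # from the current selection until n_refs are chosen
    chosen = [qualifying[0], qualifying[-1]]
    remaining = list(qualifying[1:-1])
    while len(chosen) < n_refs and remaining:
        dists = [min(abs(m - c) for c in chosen) for m in remaining]
        best = int(np.argmax(dists))
        chosen.append(remaining.pop(best))
    return np.sort(np.asarray(chosen))


@dataclass
class CalibrationModel:
    """Affine recalibration in the sqrt(m/z) domain: s_corrected = a + b*s."""

    intercept: float
    slope: float
    residuals_da: np.ndarray   # per matched reference, after correction
    n_refs_used: int

    def __post_init__(self) -> None:
        if self.n_refs_used < 2:
            raise ValueError("calibration needs at least 2 matched references")
        if self.slope <= 0:
            raise ValueError("calibration map must be strictly increasing")

    def apply(self, mass: np.ndarray) -> np.ndarray:
        s = np.sqrt(np.asarray(mass, dtype=float))
        return (self.intercept + self.slope * s) ** 2

    @property
    def rms_residual_da(self) -> float:
        return float(np.sqrt(np.mean(self.residuals_da**2)))


def calibrate(obj, reference_masses, tolerance_da: float = 2.0, tolerance_ppm: float = 500.0):
    """Internally recalibrate a peak list or spectrum against reference masses.

    Matches observed peaks to the nearest reference within
    ``max(tolerance_da, tolerance_ppm * mass)``, fits observed -> reference
    as an affine map in sqrt(m/z) by least squares, and applies the map to
    the full mass axis. Returns (calibrated object, CalibrationModel).
    """
    from .peaks import PeakList

    reference_masses = np.sort(np.asarray(reference_masses, dtype=float))
    if isinstance(obj, PeakList):
        observed_axis = np.array([p.mass for p in obj.peaks])
    elif isinstance(obj, RawSpectrum):
        observed_axis = obj.mz
    else:
        raise TypeError(f"cannot calibrate object of type {type(obj).__name__}")

    # pair each reference with its nearest observed peak/channel
    matched_obs, matched_ref = [], []
    candidates = observed_axis
    for ref in reference_masses:
        idx = int(np.argmin(np.abs(candidates - ref)))
        tol = max(tolerance_da, tolerance_ppm * 1e-6 * ref)
        if abs(candidates[idx] - ref) <= tol:
            matched_obs.append(candidates[idx])
            matched_ref.append(ref)
    if len(matched_obs) < 2:
        raise ValueError(
            f"only {len(matched_obs)} references matched within tolerance; "
            f"need at least 2"
        )
    s_obs = np.sqrt(np.asarray(matched_obs))
    s_ref = np.sqrt(np.asarray(matched_ref))
    design = np.column_stack([np.ones_like(s_obs), s_obs])
    (intercept, slope), *_ = np.linalg.lstsq(design, s_ref, rcond=None)

    corrected_axis = (intercept + slope * np.sqrt(observed_axis)) ** 2
    if np.any(np.diff(corrected_axis) <= 0):
        raise ValueError("calibration produced a non-monotone mass axis")
    residuals = (intercept + slope * s_obs) ** 2 - np.asarray(matched_ref)
    model = CalibrationModel(
        intercept=float(intercept),
        slope=float(slope),
        residuals_da=residuals,
        n_refs_used=len(matched_obs),
    )

    if isinstance(obj, PeakList):
        calibrated = obj.with_masses(model.apply(np.array([p.mass for p in obj.peaks])))
    else:
        calibrated = obj.with_mz(corrected_axis)
    return calibrated, model
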