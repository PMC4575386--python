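"""Noise estimation and peak detection with the dual S/N + absolute threshold.

A candidate apex must clear both a signal-to-noise ratio of 3 and an
absolute ion abundance of 200 mV (the defaults used throughout). Noise is a
rolling median-absolute-deviation of the baseline-subtracted signal, which
stays robust in the presence of sparse large peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .io import Condition, RawSpectrum

__all__ = ["Peak", "PeakList", "estimate_noise", "detect_peaks"]


@dataclass(frozen=True)
class Peak:
    """One detected centroid: mass (Da), apex abundance (mV), S/N."""

    mass: float
    abundance: float
    snr: float

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


@dataclass
class PeakList:
    """Detected peaks of one sample, sorted by mass."""

    sample_id: str
    condition: Condition | None
    peaks: list[Peak] = field(default_factory=list)
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mass)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def masses(self) -> np.ndarray:
        return np.array([p.mass for p in self.peaks])

    @property
    def abundances(self) -> np.ndarray:
        return np.array([p.abundance for p in self.peaks])

    def with_masses(self, new_masses: np.ndarray) -> "PeakList":
        peaks = [
            replace(p, mass=float(m)) for p, m in zip(self.peaks, new_masses)
        ]
        return PeakList(
            sample_id=self.sample_id,
            condition=self.condition,
            peaks=peaks,
            replicate_index=self.replicate_index,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "mass": [p.mass for p in self.peaks],
                "abundance_mV": [p.abundance for p in self.peaks],
                "snr": [p.snr for p in self.peaks],
            }
        )


def estimate_noise(spectrum: RawSpectrum, window_channels: int = 501) -> np.ndarray:
    """Per-channel noise level (mV): rolling MAD scaled to Gaussian sigma.

    The MAD of the signal around its rolling median, scaled by 1.4826, is a
    consistent estimate of the noise standard deviation that ignores sparse
    peaks. Values are floored at machine epsilon so S/N stays defined.
    """
    if window_channels < 11 or window_channels % 2 == 0:
        raise ValueError("window_channels must be odd and >= 11")
    if window_channels > len(spectrum):
        raise ValueError(
            f"noise window {window_channels} exceeds spectrum length {len(spectrum)}"
        )
    x = spectrum.intensity
    med = ndimage.median_filter(x, size=window_channels, mode="nearest")
    mad = ndimage.median_filter(np.abs(x - med), size=window_channels, mode="nearest")
    return np.maximum(1.4826 * mad, np.finfo(float).eps)


def _half_max_width(intensity: np.ndarray, apex: int) -> int:
    """FWHM in channels around an apex, by walking out to the half-maximum."""
    half = intensity[apex] / 2.0
    left = apex
    while left > 0 and intensity[left - 1] > half:
        left -= 1
    right = apex
    n = intensity.size
    while right < n - 1 and intensity[right + 1] > half:
        right += 1
    return max(right - left, 1)


def detect_peaks(
    spectrum: RawSpectrum,
    snr_min: float = 3.0,
    abs_min_mv: float = 200.0,
    noise_window: int = 501,
    centroid_halfwidth: int = 3,
) -> PeakList:
    """Detect peaks on a preprocessed (smoothed, baseline-subtracted) spectrum.

    Local maxima must clear both thresholds; maxima closer than the local
    FWHM are merged into the taller one. The reported mass is the
    intensity-weighted centroid over apex +- ``centroid_halfwidth`` channels
    and plateau ties resolve to the lowest-mass channel.
    """
    y = spectrum.intensity
    noise = estimate_noise(spectrum, noise_window)
    _, props = signal.find_peaks(y, height=max(abs_min_mv, 0.0), plateau_size=1)
    # plateau ties resolve to the left edge, i.e. the lowest-mass channel
    candidates = props["left_edges"]
    apexes = np.asarray(
        [a for a in candidates if y[a] / noise[a] >= snr_min and y[a] >= abs_min_mv],
        dtype=int,
    )

    # merge maxima closer than the local FWHM, keeping the taller
    kept: list[int] = []
    for apex in sorted(apexes, key=lambda a: -y[a]):
        fwhm = _half_max_width(y, apex)
        if all(abs(apex - other) >= fwhm for other in kept):
            kept.append(apex)
    kept.sort()

    peaks = []
    n = y.size
    for apex in kept:
        lo = max(apex - centroid_halfwidth, 0)
        hi = min(apex + centroid_halfwidth + 1, n)
        weights = y[lo:hi]
        centroid = float(np.average(spectrum.mz[lo:hi], weights=weights))
        peaks.append(
            Peak(mass=centroid, abundance=float(y[apex]), snr=float(y[apex] / noise[apex]))
        )
    return PeakList(
        sample_id=spectrum.sample_id,
        condition=spectrum.condition,
        peaks=peaks,
        replicate_index=spectrum.replicate_index,
    )
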