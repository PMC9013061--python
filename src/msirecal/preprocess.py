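"""Optional TOF-style preprocessing: noise thresholding, smoothing, centroiding.

Public repository datasets ship as centroided peaks and skip this module
entirely; it exists for profile-like peak lists exported from TOF
instruments.  The noise threshold is a kneedle-type knee of the sorted
intensity curve, smoothing is Savitzky-Golay, and centroids are apex
intensities with intensity-weighted m/z over the contiguous above-threshold
support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io import PeakSpectrum


@dataclass
class PreprocessConfig:
    sg_window: int = 7
    sg_order: int = 3
    min_peak_points: int = 3
    kneedle_sensitivity: float = 0.0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if self.min_peak_points < 3:
            raise ValueError("min_peak_points must be >= 3")


def kneedle_threshold(intensities) -> float:
    """Knee of the sorted intensity curve: baseline-noise threshold.

    Intensities are sorted ascending and the curve is normalized to the unit
    square; the knee is the point of maximum perpendicular distance to the
    chord joining the curve's endpoints.  If the curve has no pronounced knee
    (distance indistinguishable from zero) the minimum intensity is returned
    with a warning, i.e. nothing is discarded as noise.
    """
    v = np.sort(np.asarray(intensities, dtype=float))
    if v.size < 10:
        raise ValueError("kneedle_threshold requires at least 10 intensity values")
    if np.any(v < 0):
        raise ValueError("intensities must be non-negative")
    span = v[-1] - v[0]
    if span == 0:
        warnings.warn("all intensities equal; threshold set to that value")
        return float(v[0])
    x = np.linspace(0.0, 1.0, v.size)
    y = (v - v[0]) / span
    # perpendicular distance to the chord from (0,0) to (1,1): |y - x| / sqrt(2)
    dist = np.abs(y - x) / np.sqrt(2.0)
    if dist.max() <= 1e-12:
        warnings.warn("no pronounced knee in intensity curve; threshold set to minimum")
        return float(v[0])
    return float(v[int(np.argmax(dist))])


def smooth_spectrum(spectrum: PeakSpectrum, config: PreprocessConfig) -> PeakSpectrum:
    """Savitzky-Golay smoothing of the intensity trace along the m/z axis."""
    if len(spectrum) < config.sg_window:
        raise ValueError(
            f"sg_window={config.sg_window} longer than spectrum of {len(spectrum)} points"
        )
    smoothed = savgol_filter(
        spectrum.intensities.astype(np.float64), config.sg_window, config.sg_order
    )
    return PeakSpectrum(
        spectrum.pixel_index, spectrum.x, spectrum.y, spectrum.masses, np.clip(smoothed, 0, None)
    )


def detect_centroids(
    spectrum: PeakSpectrum, threshold: float, config: PreprocessConfig | None = None
) -> PeakSpectrum:
    """Reduce a profile-like trace to centroids.

    Each maximal contiguous run of points strictly above ``threshold`` with at
    least ``min_peak_points`` points yields one centroid: m/z is the
    intensity-weighted mean over the run, intensity is the apex intensity.
    """
    config = config or PreprocessConfig()
    mz = spectrum.masses
    inten = spectrum.intensities.astype(np.float64)
    above = inten > threshold
    out_mz, out_int = [], []
    i = 0
    n = len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= config.min_peak_points:
            seg_mz, seg_int = mz[i:j], inten[i:j]
            out_mz.append(float(np.average(seg_mz, weights=seg_int)))
            out_int.append(float(seg_int.max()))
        i = j
    return PeakSpectrum(
        spectrum.pixel_index,
        spectrum.x,
        spectrum.y,
        np.array(out_mz, dtype=np.float64),
        np.array(out_int, dtype=np.float32),
    )
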