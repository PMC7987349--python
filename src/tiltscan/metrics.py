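"""Image-quality metrics: CNR, contrast, FWHM, and RF intensity.

All contrast statistics are computed on linear (pre-log-compression)
envelope intensities; variance-based quantities are meaningless on dB
data, so log images are never accepted here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .reconstruct import Volume

__all__ = ["ROI", "CNRReport", "cnr_from_samples", "cnr", "fwhm", "rms_intensity"]


@dataclass(frozen=True)
class ROI:
    """Axis-aligned box in mm: center and half extents per axis."""

    center_mm: tuple[float, float, float]
    half_extents_mm: tuple[float, float, float]

    def slices(self, vol: Volume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        axes = (vol.x_axis_mm, vol.y_axis_mm, vol.z_axis_mm)
        masks = []
        for ax, c, h in zip(axes, self.center_mm, self.half_extents_mm):
            m = (ax >= c - h) & (ax <= c + h)
            if not m.any():
                raise ValueError("ROI does not cover any voxel centers")
            masks.append(m)
        return tuple(masks)


@dataclass(frozen=True)
class CNRReport:
    """Contrast statistics between a target and a background region."""

    mean_target: float
    mean_background: float
    var_target: float
    var_background: float
    contrast_db: float
    cnr: float


def cnr_from_samples(target: np.ndarray, background: np.ndarray) -> CNRReport:
    """CNR ``|St - Sb| / sqrt(var_t + var_b)`` on linear intensities.

    Contrast is also reported in dB as ``20 log10`` of the ratio of the
    larger to the smaller region mean.
    """
    t = np.asarray(target, float).ravel()
    b = np.asarray(background, float).ravel()
    if t.size == 0 or b.size == 0:
        raise ValueError("empty ROI")
    st, sb = float(t.mean()), float(b.mean())
    vt, vb = float(t.var()), float(b.var())
    denom = math.sqrt(vt + vb)
    cnr_val = abs(st - sb) / denom if denom > 0 else 0.0
    if min(st, sb) > 0:
        contrast_db = 20.0 * math.log10(max(st, sb) / min(st, sb))
    else:
        contrast_db = math.inf if max(st, sb) > 0 else 0.0
    return CNRReport(st, sb, vt, vb, contrast_db, cnr_val)


def cnr(vol: Volume, target_roi: ROI, background_roi: ROI) -> CNRReport:
    """CNR between two ROIs of a reconstructed volume.

    Both ROIs must lie entirely inside the valid (in-wedge) voxels;
    touching masked padding raises rather than biasing the statistics.
    """
    samples = []
    for roi in (target_roi, background_roi):
        mx, my, mz = roi.slices(vol)
        sub_valid = vol.valid[np.ix_(mx, my, mz)]
        if not sub_valid.all():
            raise ValueError("ROI touches invalid (out-of-wedge) voxels")
        samples.append(vol.intensity[np.ix_(mx, my, mz)])
    return cnr_from_samples(samples[0], samples[1])


def fwhm(positions_mm, intensities) -> float:
    """Full width at half maximum of a sampled profile.

    Crossings of the half-maximum level are located by linear interpolation
    on each side of the highest peak; a profile that never falls below half
    maximum on either side raises ("unresolved").
    """
    x = np.asarray(positions_mm, float)
    y = np.asarray(intensities, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("profile needs at least 3 samples")
    if np.any(np.diff(x) <= 0):
        raise ValueError("positions must be strictly increasing")
    i = int(np.argmax(y))
    half = y[i] / 2.0

    def cross(idx_range, left: bool) -> float:
        for j in idx_range:
            if y[j] <= half:
                # between j and its inward neighbour
                k = j + 1 if left else j - 1
                frac = (half - y[j]) / (y[k] - y[j])
                return x[j] + frac * (x[k] - x[j])
        raise ValueError("unresolved: profile does not fall to half maximum")

    x_left = cross(range(i - 1, -1, -1), left=True)
    x_right = cross(range(i + 1, len(y)), left=False)
    return float(x_right - x_left)


def rms_intensity(
    signal,
    sampling_freq_hz: float | None = None,
    lowpass_cutoff_hz: float | None = None,
    window: np.ndarray | None = None,
) -> float:
    """Root-mean-square of a signal, optionally low-pass filtered.

    With a window, the RMS is window-power normalized
    (``sqrt(sum(w^2 s^2)/sum(w^2))``) so a constant signal keeps RMS |c|.
    """
    s = np.asarray(signal, float).ravel()
    if s.size == 0:
        raise ValueError("empty signal")
    if lowpass_cutoff_hz is not None:
        if sampling_freq_hz is None:
            raise ValueError("low-pass filtering requires the sampling frequency")
        b, a = butter(4, lowpass_cutoff_hz / (sampling_freq_hz / 2.0), btype="low")
        s = filtfilt(b, a, s)
    if window is not None:
        w = np.asarray(window, float).ravel()
        if len(w) != len(s):
            raise ValueError("window length mismatch")
        return float(np.sqrt(np.sum(w**2 * s**2) / np.sum(w**2)))
    return float(np.sqrt(np.mean(s**2)))
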