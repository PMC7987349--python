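"""Mirror-kinematics calibration from synthetic sweep measurements.

Emulates the two calibration studies a mirror-swept probe needs before
reconstruction: tracking the reflected beam's elevational position over
time to recover the tilt sinusoid (amplitude, phase, offset, frequency),
and characterizing the drive — voltage-to-angle linearity and the
resonance peak of the tilting frequency response.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import linregress

from .scheduler import MirrorKinematics, tilt_angle_at

__all__ = [
    "SweepMeasurement",
    "CalibrationFit",
    "simulate_sweep_map",
    "track_beam_angle",
    "fit_sinusoid",
    "fit_voltage_angle",
    "resonance_peak",
    "kinematics_from_range",
]


@dataclass
class SweepMeasurement:
    """Time series of measured tilt angles from a beam-tracking sweep."""

    times_s: np.ndarray
    tilt_deg: np.ndarray  # NaN where tracking failed
    noise_sd_deg: float = 0.0
    drive_voltage_vpp: float | None = None
    drive_freq_hz: float | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, float)
        self.tilt_deg = np.asarray(self.tilt_deg, float)
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times_s) != len(self.tilt_deg):
            raise ValueError("times and angles length mismatch")

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.tilt_deg)


@dataclass
class CalibrationFit:
    """Recovered tilt-sinusoid parameters and fit quality."""

    half_range_deg: float
    phase_rad: float
    offset_deg: float
    tilt_freq_hz: float
    rms_residual_deg: float

    def as_kinematics(self) -> MirrorKinematics:
        return MirrorKinematics(
            self.half_range_deg, self.tilt_freq_hz, self.phase_rad, self.offset_deg
        )


def simulate_sweep_map(
    kin: MirrorKinematics,
    times_s: np.ndarray,
    y_positions_mm: np.ndarray,
    range_mm: float = 16.9,
    beam_sigma_mm: float = 1.0,
    angle_noise_sd_deg: float = 0.0,
    seed: int | None = None,
    dropout_columns=(),
) -> np.ndarray:
    """Synthetic elevational-intensity map (ny, nt) of a tilting sweep.

    The beam center follows ``y(t) = range * tan(2 theta(t))`` (scan angle
    is twice the tilt); per-column angle jitter emulates measurement noise.
    ``dropout_columns`` are zeroed to emulate lost acquisitions.
    """
    times_s = np.asarray(times_s, float)
    y = np.asarray(y_positions_mm, float)
    rng = np.random.default_rng(seed)
    theta = tilt_angle_at(kin, times_s)
    if angle_noise_sd_deg:
        theta = theta + rng.normal(0.0, angle_noise_sd_deg, len(times_s))
    y_center = range_mm * np.tan(np.radians(2.0 * theta))
    intensity = np.exp(-((y[:, None] - y_center[None, :]) ** 2) / (2 * beam_sigma_mm**2))
    for c in dropout_columns:
        intensity[:, c] = 0.0
    return intensity


def track_beam_angle(
    intensity_map: np.ndarray,
    y_positions_mm: np.ndarray,
    range_mm: float,
    times_s: np.ndarray,
    noise_sd_deg: float = 0.0,
) -> SweepMeasurement:
    """Per time column: beam-peak elevational position (with parabolic
    sub-sample refinement) converted to a tilt angle.

    A flat column (no peak) is marked missing (NaN), never interpolated.
    """
    m = np.asarray(intensity_map, float)
    y = np.asarray(y_positions_mm, float)
    if m.ndim != 2 or m.shape[0] != len(y):
        raise ValueError("intensity map must be (ny, nt) matching y positions")
    if m.shape[1] < 1:
        raise ValueError("map needs at least one time column")
    dy = y[1] - y[0] if len(y) > 1 else 1.0
    tilt = np.full(m.shape[1], np.nan)
    for j in range(m.shape[1]):
        col = m[:, j]
        if not np.isfinite(col).all() or col.max() - col.min() <= 0:
            continue  # flat or corrupt column: missing
        i = int(np.argmax(col))
        y_pk = y[i]
        if 0 < i < len(y) - 1:
            denom = col[i - 1] - 2 * col[i] + col[i + 1]
            if denom < 0:
                y_pk = y[i] + 0.5 * (col[i - 1] - col[i + 1]) / denom * dy
        alpha = math.degrees(math.atan2(y_pk, range_mm))
        tilt[j] = alpha / 2.0
    return SweepMeasurement(times_s, tilt, noise_sd_deg=noise_sd_deg)


def _linear_fit(t: np.ndarray, theta: np.ndarray, freq_hz: float):
    w = 2.0 * math.pi * freq_hz
    basis = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(basis, theta, rcond=None)
    resid = theta - basis @ coef
    return coef, float(np.sqrt(np.mean(resid**2)))


def fit_sinusoid(
    meas: SweepMeasurement,
    freq_known_hz: float | None = None,
    freq_band_hz: tuple[float, float] = (100.0, 350.0),
    coarse_step_hz: float = 1.0,
) -> CalibrationFit:
    """Least-squares recovery of the tilt sinusoid parameters.

    With the frequency known the model is linear in a sin/cos/constant
    basis.  Otherwise the residual is scanned on a coarse frequency grid
    over ``freq_band_hz`` and refined by bounded 1-D minimization, which
    avoids the divergence of a joint nonlinear fit.  The amplitude is
    reported non-negative with the phase adjusted accordingly.
    """
    good = ~meas.missing
    t = meas.times_s[good]
    theta = meas.tilt_deg[good]
    if len(t) < 4:
        raise ValueError("under-determined: need at least 4 valid samples")

    if freq_known_hz is not None:
        span_periods = (t[-1] - t[0]) * freq_known_hz
        if span_periods < 2.0:
            raise ValueError("under-determined: need >= 2 mirror periods of data")
        coef, rms = _linear_fit(t, theta, freq_known_hz)
        f_hat = freq_known_hz
    else:
        freqs = np.arange(freq_band_hz[0], freq_band_hz[1] + coarse_step_hz, coarse_step_hz)
        rms_grid = [_linear_fit(t, theta, f)[1] for f in freqs]
        f0 = freqs[int(np.argmin(rms_grid))]
        lo = max(freq_band_hz[0], f0 - coarse_step_hz)
        hi = min(freq_band_hz[1], f0 + coarse_step_hz)
        res = minimize_scalar(
            lambda f: _linear_fit(t, theta, f)[1],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        f_hat = float(res.x)
        if (t[-1] - t[0]) * f_hat < 2.0:
            raise ValueError("under-determined: need >= 2 mirror periods of data")
        coef, rms = _linear_fit(t, theta, f_hat)

    a, b, gamma = coef
    amp = math.hypot(a, b)
    phase = math.atan2(b, a) if amp > 0 else 0.0
    return CalibrationFit(
        half_range_deg=amp,
        phase_rad=phase % (2.0 * math.pi),
        offset_deg=float(gamma),
        tilt_freq_hz=f_hat,
        rms_residual_deg=rms,
    )


def fit_voltage_angle(voltages_vpp, total_ranges_deg):
    """Ordinary least-squares line through (drive voltage, total tilt range).

    Returns (slope deg/Vpp, intercept deg, r^2).
    """
    v = np.asarray(voltages_vpp, float)
    r = np.asarray(total_ranges_deg, float)
    if len(v) < 2 or len(v) != len(r):
        raise ValueError("need at least 2 (voltage, range) points")
    if np.ptp(v) == 0:
        raise ValueError("voltages are all identical; line is undefined")
    fit = linregress(v, r)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def resonance_peak(freqs_hz, amplitudes_deg) -> float:
    """Resonance frequency: argmax with 3-point parabolic refinement.

    Monotone responses return the boundary frequency with a warning (the
    peak lies at or beyond the measured band).
    """
    f = np.asarray(freqs_hz, float)
    a = np.asarray(amplitudes_deg, float)
    if len(f) < 3 or len(f) != len(a):
        raise ValueError("need at least 3 (frequency, amplitude) points")
    order = np.argsort(f)
    f, a = f[order], a[order]
    i = int(np.argmax(a))
    if i == 0 or i == len(f) - 1:
        warnings.warn(
            "amplitude response is monotone over the measured band; "
            "resonance lies at or beyond the boundary",
            stacklevel=2,
        )
        return float(f[i])
    # vertex of the parabola through the three points around the maximum
    p = np.polyfit(f[i - 1 : i + 2], a[i - 1 : i + 2], 2)
    if p[0] >= 0:
        return float(f[i])
    return float(-p[1] / (2.0 * p[0]))


def kinematics_from_range(
    upper_deg: float,
    lower_deg: float,
    tilt_freq_hz: float,
    phase_rad: float = 0.0,
) -> MirrorKinematics:
    """Map an asymmetric measured tilt range (+upper/-lower) onto the
    symmetric sinusoid: ``A = (upper+lower)/2``, ``gamma = (upper-lower)/2``.
    """
    return MirrorKinematics(
        half_range_deg=(upper_deg + lower_deg) / 2.0,
        tilt_freq_hz=tilt_freq_hz,
        phase_rad=phase_rad,
        offset_deg=(upper_deg - lower_deg) / 2.0,
    )
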