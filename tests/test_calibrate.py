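"""Calibration: beam tracking, sinusoid fitting, drive linearity, resonance."""

import math

import numpy as np
import pytest

from tiltscan import (
    MirrorKinematics,
    SweepMeasurement,
    fit_sinusoid,
    fit_voltage_angle,
    kinematics_from_range,
    resonance_peak,
    simulate_sweep_map,
    track_beam_angle,
)
from tiltscan.scheduler import tilt_angle_at

KIN = MirrorKinematics(11.95, 250.0, phase_rad=0.3, offset_deg=0.6)


def _times(n_periods=10.0, per_period=80, fm=250.0):
    fs = per_period * fm
    n = int(n_periods / fm * fs)
    return np.arange(1, n + 1) / fs


def test_track_recovers_noiseless_angles():
    times = _times(4)
    y = np.arange(-14.0, 14.0, 0.1)
    m = simulate_sweep_map(KIN, times, y, range_mm=16.9)
    meas = track_beam_angle(m, y, 16.9, times)
    truth = tilt_angle_at(KIN, times)
    assert np.nanmax(np.abs(meas.tilt_deg - truth)) < 0.05


def test_track_constant_beam_gives_constant_angle():
    y = np.arange(-5.0, 5.0, 0.05)
    col = np.exp(-((y - 1.2) ** 2) / 0.5)
    m = np.tile(col[:, None], (1, 10))
    meas = track_beam_angle(m, y, 10.0, np.arange(1, 11) * 1e-3)
    assert np.allclose(meas.tilt_deg, meas.tilt_deg[0])
    expected = math.degrees(math.atan2(1.2, 10.0)) / 2
    assert meas.tilt_deg[0] == pytest.approx(expected, abs=1e-3)


def test_track_dropout_column_marked_missing():
    times = _times(2)
    y = np.arange(-14.0, 14.0, 0.1)
    m = simulate_sweep_map(KIN, times, y, 16.9, dropout_columns=(5, 17))
    meas = track_beam_angle(m, y, 16.9, times)
    assert meas.missing[5] and meas.missing[17]
    assert np.isnan(meas.tilt_deg[5])
    assert not meas.missing[6]


def test_fit_sinusoid_exact_on_model_data():
    times = _times(5)
    theta = tilt_angle_at(KIN, times)
    meas = SweepMeasurement(times, theta)
    fit = fit_sinusoid(meas, freq_known_hz=250.0)
    assert fit.half_range_deg == pytest.approx(11.95, abs=1e-9)
    assert fit.phase_rad == pytest.approx(0.3, abs=1e-9)
    assert fit.offset_deg == pytest.approx(0.6, abs=1e-9)
    assert fit.rms_residual_deg < 1e-9


def test_fit_sinusoid_frequency_scan_recovers_fm():
    times = _times(10)
    theta = tilt_angle_at(KIN, times)
    fit = fit_sinusoid(SweepMeasurement(times, theta))
    assert fit.tilt_freq_hz == pytest.approx(250.0, abs=1e-3)
    assert fit.half_range_deg == pytest.approx(11.95, abs=1e-6)


def test_fit_sinusoid_offset_only_degenerate():
    times = _times(5)
    kin0 = MirrorKinematics(0.0, 250.0, 0.0, 0.6)
    meas = SweepMeasurement(times, tilt_angle_at(kin0, times))
    fit = fit_sinusoid(meas, freq_known_hz=250.0)
    assert fit.half_range_deg == pytest.approx(0.0, abs=1e-9)
    assert fit.offset_deg == pytest.approx(0.6, abs=1e-9)


def test_fit_sinusoid_underdetermined_raises():
    times = _times(1)  # only one mirror period
    meas = SweepMeasurement(times, tilt_angle_at(KIN, times))
    with pytest.raises(ValueError, match="under-determined"):
        fit_sinusoid(meas, freq_known_hz=250.0)


def test_amplitude_invariant_to_phase_wrap():
    times = _times(5)
    k1 = MirrorKinematics(8.0, 250.0, phase_rad=0.7)
    k2 = MirrorKinematics(8.0, 250.0, phase_rad=0.7 + 2 * math.pi)
    f1 = fit_sinusoid(SweepMeasurement(times, tilt_angle_at(k1, times)), 250.0)
    f2 = fit_sinusoid(SweepMeasurement(times, tilt_angle_at(k2, times)), 250.0)
    assert f1.half_range_deg == pytest.approx(f2.half_range_deg, abs=1e-12)
    assert f1.phase_rad == pytest.approx(f2.phase_rad, abs=1e-9)


def test_estimator_bias_shrinks_with_noise():
    times = _times(10)
    errs = []
    for sd in (0.5, 0.05, 0.005):
        rng = np.random.default_rng(0)
        trials = []
        for _ in range(20):
            theta = tilt_angle_at(KIN, times) + rng.normal(0, sd, len(times))
            fit = fit_sinusoid(SweepMeasurement(times, theta), 250.0)
            trials.append(fit.half_range_deg - 11.95)
        errs.append(abs(np.mean(trials)))
    assert errs[2] < errs[0]
    assert errs[2] < 1e-3


def test_voltage_angle_two_point_line():
    # measured total tilt ranges: 14.4 deg at 5 Vpp, 23.9 deg at 10 Vpp
    slope, intercept, r2 = fit_voltage_angle([5.0, 10.0], [14.4, 23.9])
    assert slope == pytest.approx(1.9)
    assert intercept == pytest.approx(4.9)
    assert r2 == pytest.approx(1.0)


def test_voltage_angle_proportional_and_duplicates():
    slope, intercept, r2 = fit_voltage_angle([1, 2, 3, 4], [2.0, 4.0, 6.0, 8.0])
    assert intercept == pytest.approx(0.0, abs=1e-12)
    assert r2 == pytest.approx(1.0)
    slope, intercept, r2 = fit_voltage_angle([1, 1, 3], [2.0, 4.0, 6.0])
    assert r2 < 1.0
    # best fit passes through the mean of the duplicated abscissa
    assert slope * 1 + intercept == pytest.approx(3.0)


def test_voltage_angle_single_point_rejected():
    with pytest.raises(ValueError):
        fit_voltage_angle([5.0], [14.4])


def test_resonance_lorentzian_peak():
    f = np.arange(100.0, 351.0, 10.0)
    amp = 1.0 / (1.0 + ((f - 240.0) / 30.0) ** 2)
    assert abs(resonance_peak(f, amp) - 240.0) <= 2.0


def test_resonance_symmetric_triangle_exact():
    f = np.arange(100.0, 301.0, 10.0)
    amp = -np.abs(f - 200.0)
    assert resonance_peak(f, amp) == pytest.approx(200.0)


def test_resonance_monotone_returns_boundary_with_warning():
    f = np.arange(100.0, 351.0, 10.0)
    amp = np.linspace(0.1, 1.0, len(f))
    with pytest.warns(UserWarning, match="monotone"):
        assert resonance_peak(f, amp) == 350.0


def test_kinematics_from_asymmetric_range():
    kin = kinematics_from_range(12.6, 11.3, 250.0)
    assert kin.half_range_deg == pytest.approx(11.95)
    assert kin.offset_deg == pytest.approx(0.65)


def test_sweep_measurement_requires_increasing_times():
    with pytest.raises(ValueError, match="strictly increasing"):
        SweepMeasurement(np.array([0.0, 0.0, 1.0]), np.zeros(3))
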