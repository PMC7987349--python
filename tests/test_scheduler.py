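"""Scheduler: PRF bounds, tilt kinematics, volume-rate regimes, volume
partitioning, and the compounding / line-by-line multiplex variants."""

import math

import numpy as np
import pytest

from tiltscan import (
    AcquisitionConfig,
    MirrorKinematics,
    ScheduleError,
    build_schedule,
    effective_prf,
    multiplex_schedule,
    partition_into_volumes,
    planes_per_volume,
    prf_from_depth,
    scan_angle_at,
    tilt_angle_at,
    volume_rate,
)
from tiltscan.scheduler import RateResult, samples_of_volume

from conftest import brute_force_rate


@pytest.mark.parametrize(
    "c, d, expected",
    [(1500, 30, 25000), (1500, 15, 50000), (1540, 77, 10000)],
)
def test_prf_from_depth_closed_form(c, d, expected):
    assert prf_from_depth(c, d) == pytest.approx(expected)


@pytest.mark.parametrize("c, d", [(0, 30), (1500, 0), (-1, 10)])
def test_prf_from_depth_rejects_nonpositive(c, d):
    with pytest.raises(ValueError):
        prf_from_depth(c, d)


@pytest.mark.parametrize(
    "prf, na, expected", [(25000, 1, 25000), (13500, 3, 4500), (20000, 4, 5000)]
)
def test_effective_prf(prf, na, expected):
    assert effective_prf(prf, na) == pytest.approx(expected)


def test_effective_prf_rejects_bad_na():
    with pytest.raises(ValueError):
        effective_prf(1000, 0)


@pytest.mark.parametrize(
    "a, phi, gamma, fm, t, expected",
    [
        (12, 0, 0, 250, 0.0, 0.0),
        (12, 0, 0, 250, 1e-3, 12.0),
        (10, math.pi, 2, 100, 0.0, 2.0),
    ],
)
def test_tilt_angle_sinusoid(a, phi, gamma, fm, t, expected):
    kin = MirrorKinematics(a, fm, phi, gamma)
    assert tilt_angle_at(kin, t) == pytest.approx(expected, abs=1e-9)


def test_scan_angle_is_twice_tilt():
    kin = MirrorKinematics(22.5, 250.0)  # tilt reaches 45 deg... scaled
    kin45 = MirrorKinematics(45.0, 250.0)
    t_quarter = 1 / (4 * 250.0)
    assert scan_angle_at(kin45, t_quarter) == pytest.approx(90.0)
    ts = np.linspace(0, 0.01, 101)
    assert np.allclose(scan_angle_at(kin, ts), 2 * tilt_angle_at(kin, ts))
    kin_neg = MirrorKinematics(11.3, 250.0)
    assert scan_angle_at(kin_neg, 3 / (4 * 250.0)) == pytest.approx(-22.6)


@pytest.mark.parametrize(
    "prfe, fv, regime, m, n_planes",
    [
        (20000, 500.0, "condition1", 1, 41),
        (1000, 500.0, "condition1", 1, 3),
        (1125, 125.0, "condition2", 2, 9),
        (1062.5, 62.5, "condition2", 4, 17),
    ],
)
def test_volume_rate_reference_configurations(prfe, fv, regime, m, n_planes):
    """The published operating points: 20-kHz full configuration and the
    1000/1125/1062.5-Hz PRF examples at a 250-Hz mirror."""
    kin = MirrorKinematics(11.95, 250.0)
    rate = volume_rate(prfe, kin)
    assert rate.volume_rate_hz == pytest.approx(fv)
    assert rate.regime == regime
    assert rate.multiplier_m == m
    assert planes_per_volume(prfe, rate) == n_planes


def test_planes_per_volume_formula_uses_given_peak_flag():
    # PRFe/Fv quotient plus one only for a sampled extremum in condition 1
    no_peak = RateResult(500.0, "condition1", 1, 50, False, 50.0)
    assert planes_per_volume(25000, no_peak) == 50
    with_peak = RateResult(500.0, "condition1", 1, 41, True, 80.0)
    assert planes_per_volume(20000, with_peak) == 41


def test_planes_per_volume_rejects_noninteger_quotient():
    rate = RateResult(500.0, "condition1", 1, 3, False, 2.2)
    with pytest.raises(ScheduleError):
        planes_per_volume(1100, rate)


def test_volume_rate_nonrepeating_ratio_raises():
    kin = MirrorKinematics(10, 250.0)
    with pytest.raises(ScheduleError, match="non-repeating"):
        volume_rate(250.0 * math.pi, kin)


def test_even_ratio_with_exotic_phase_demoted_with_warning():
    kin = MirrorKinematics(10, 250.0, phase_rad=math.pi / 7)
    with pytest.warns(UserWarning, match="condition-1 phase"):
        rate = volume_rate(1000.0, kin)
    assert rate.regime == "condition2"
    assert rate.volume_rate_hz == pytest.approx(250.0)


@pytest.mark.filterwarnings("ignore::UserWarning")
def test_volume_rate_matches_enumeration_oracle_sampled():
    """Spot sample of the brute-force equivalence (full 200-case sweep runs
    in the acceptance suite)."""
    rng = np.random.default_rng(7)
    fm = 250.0
    for _ in range(40):
        q = int(rng.integers(1, 13))
        p = int(rng.integers(2 * q + 1, 40 * q))
        r = p / q
        for phi in (0.0, math.pi / 4):
            prfe = r * fm
            rate = volume_rate(prfe, MirrorKinematics(10, fm, phi))
            n_p = planes_per_volume(prfe, rate)
            fv_o, np_o, regime_o = brute_force_rate(prfe, fm, phi)
            assert rate.volume_rate_hz == pytest.approx(fv_o)
            assert n_p == np_o
            assert rate.regime == regime_o


def test_schedule_quarter_period_sequence():
    acq = AcquisitionConfig(prf_hz=1000.0, duration_s=0.004)
    kin = MirrorKinematics(12, 250.0)
    sched = build_schedule(acq, kin, partition=False)
    assert [s.index for s in sched] == [1, 2, 3, 4]
    assert [pytest.approx(s.tilt_deg, abs=1e-9) for s in sched] == [12.0, 0.0, -12.0, 0.0]
    assert all(s.scan_deg == 2 * s.tilt_deg for s in sched)


def test_schedule_periodicity_condition2():
    # PRFe/Fm = 4.5: sampled tilt sequence repeats every 9 transmits
    acq = AcquisitionConfig(prf_hz=1125.0, duration_s=0.032)
    kin = MirrorKinematics(12, 250.0)
    sched = build_schedule(acq, kin, partition=False)
    tilts = np.array([s.tilt_deg for s in sched])
    assert np.allclose(tilts[:9], tilts[9:18], atol=1e-9)
    assert not np.allclose(tilts[:8], tilts[1:9], atol=1e-6)


def test_empty_duration_gives_empty_schedule():
    acq = AcquisitionConfig(prf_hz=1000.0, duration_s=0.0)
    assert build_schedule(acq, MirrorKinematics(12, 250.0)) == []


def test_partition_condition1_half_sweeps():
    acq = AcquisitionConfig(prf_hz=1000.0, duration_s=0.012)
    kin = MirrorKinematics(12, 250.0)
    sched = build_schedule(acq, kin)
    n_vols = max(s.volume_id for s in sched) + 1
    assert n_vols == 5  # 3 mirror cycles minus incomplete lead/tail sweeps
    for v in range(n_vols):
        vol = samples_of_volume(sched, v)
        assert len(vol) == 3
        assert sorted(round(s.tilt_deg, 6) for s in vol) == [-12.0, 0.0, 12.0]
        assert vol[0].sweep_dir in ("up", "down")
    # extremal transmits are shared: they appear in two adjacent volumes
    indices = [s.index for s in sched]
    shared = [i for i in set(indices) if indices.count(i) == 2]
    assert shared and all(
        abs(abs(tilt_angle_at(kin, i / 1000.0)) - 12.0) < 1e-9 for i in shared
    )


def test_partition_condition2_full_periods():
    acq = AcquisitionConfig(prf_hz=1062.5, duration_s=0.033)
    kin = MirrorKinematics(12, 250.0)
    sched = build_schedule(acq, kin)
    vol0 = samples_of_volume(sched, 0)
    assert len(vol0) == 17
    assert len({round(s.tilt_deg, 9) for s in vol0}) == 17  # 17 distinct angles
    assert all(s.sweep_dir == "period" for s in vol0)


def test_partition_too_short_raises():
    acq = AcquisitionConfig(prf_hz=1000.0, duration_s=0.002)
    kin = MirrorKinematics(12, 250.0)
    sched = build_schedule(acq, kin, partition=False)
    rate = volume_rate(1000.0, kin)
    with pytest.raises(ScheduleError, match="shorter than one volume"):
        partition_into_volumes(sched, rate, kin)


def test_condition1_double_coverage_per_cycle():
    # phi=0, even r: every non-extremal sampled angle occurs exactly twice
    # per mirror period
    for r in (6, 10, 80):
        kin = MirrorKinematics(10, 250.0)
        prfe = r * 250.0
        tilts = [round(tilt_angle_at(kin, n / prfe), 9) for n in range(1, r + 1)]
        for v in set(tilts):
            count = tilts.count(v)
            assert count == (1 if abs(abs(v) - 10.0) < 1e-9 else 2)


def test_monotone_tradeoff_rate_vs_sampling():
    # at fixed PRFe, faster mirrors give more volumes of fewer planes
    prfe = 14400.0
    fms = [100.0, 200.0, 400.0, 600.0]
    rates = [volume_rate(prfe, MirrorKinematics(10, fm)) for fm in fms]
    fvs = [r.volume_rate_hz for r in rates]
    nps = [planes_per_volume(prfe, r) for r in rates]
    assert all(a < b for a, b in zip(fvs, fvs[1:]))
    assert all(a > b for a, b in zip(nps, nps[1:]))


def test_multiplex_line_by_line_divides_rate_keeps_positions():
    acq = AcquisitionConfig(prf_hz=20000.0, n_scan_lines=3, duration_s=0.012)
    kin = MirrorKinematics(11.95, 250.0)
    res, sched = multiplex_schedule(acq, kin, "line_by_line")
    assert res.volume_rate_hz == pytest.approx(500.0 / 3)
    assert res.sampled_positions == 41
    # the sampled elevational angle set is unchanged from plane mode
    plane = build_schedule(acq, kin)
    assert {round(s.tilt_deg, 9) for s in sched} == {
        round(s.tilt_deg, 9) for s in plane
    }


def test_multiplex_compound_keeps_rate_reduces_positions():
    acq = AcquisitionConfig(
        prf_hz=13500.0, n_compound_angles=3, duration_s=0.01, imaging_depth_mm=28.6
    )
    kin = MirrorKinematics(11.95, 250.0)
    res, sched = multiplex_schedule(acq, kin, "compound")
    assert res.volume_rate_hz == pytest.approx(500.0)
    assert res.sampled_positions == 9  # (13500/3)/500
    steers = {s.beam_index for s in sched[:3]}
    assert steers == {0, 1, 2}


def test_multiplex_na1_identical_to_plane():
    acq = AcquisitionConfig(prf_hz=20000.0, duration_s=0.004)
    kin = MirrorKinematics(11.95, 250.0)
    res_c, sched_c = multiplex_schedule(acq, kin, "compound")
    res_p, sched_p = multiplex_schedule(acq, kin, "plane")
    assert res_c.volume_rate_hz == res_p.volume_rate_hz
    assert res_c.sampled_positions == res_p.sampled_positions
    assert [s.tilt_deg for s in sched_c] == [s.tilt_deg for s in sched_p]
    assert all(s.steer_deg == 0.0 for s in sched_c)


def test_multiplex_unknown_mode():
    acq = AcquisitionConfig()
    with pytest.raises(ValueError, match="unknown multiplex mode"):
        multiplex_schedule(acq, MirrorKinematics(10, 250.0), "zigzag")


def test_phase_normalized_to_two_pi_interval():
    kin = MirrorKinematics(10, 250.0, phase_rad=-math.pi)
    assert 0 <= kin.phase_rad < 2 * math.pi
    assert kin.phase_rad == pytest.approx(math.pi)


def test_acquisition_rejects_prf_beyond_round_trip_limit():
    with pytest.raises(ValueError, match="round-trip"):
        AcquisitionConfig(prf_hz=30000.0, imaging_depth_mm=28.6)
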