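"""Transmit scheduling for mirror-steered plane-wave 3-D imaging.

A resonant acoustic mirror tilts sinusoidally at frequency ``Fm`` while an
ultrafast plane-wave sequence fires at the (effective) pulse repetition
frequency ``PRFe``.  Each transmit ``n`` (n = 1, 2, ...) happens at
``tn = n / PRFe`` and sees the mirror at tilt angle

    theta(t) = A * sin(2*pi*Fm*t + phi) + gamma        [degrees]

The reflected beam is steered by twice the tilt (law of reflection), so the
scan angle is ``alpha = 2*theta``.  The ratio ``r = PRFe / Fm`` decides the
volume rate:

* condition 1 — ``r`` is an even integer and ``(r/pi)*phi`` is an integer:
  the up- and down-sweeps of one mirror cycle sample the same set of
  elevational angles, every location is imaged twice per cycle, and the
  volume rate is ``Fv = 2*Fm`` (one volume per half-sweep).
* condition 2 — otherwise the sampled-angle sequence only repeats after the
  smallest integer ``m`` with ``m*r`` an integer; one volume is that full
  repetition period and ``Fv = Fm / m``.

The planes per volume are ``Np = PRFe / Fv``, plus one in condition 1 when a
transmit lands exactly on a tilt extremum (the extremal plane then bounds,
and is shared by, two adjacent half-sweep volumes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "MirrorKinematics",
    "AcquisitionConfig",
    "PlaneSample",
    "RateResult",
    "MultiplexResult",
    "ScheduleError",
    "prf_from_depth",
    "effective_prf",
    "tilt_angle_at",
    "scan_angle_at",
    "volume_rate",
    "planes_per_volume",
    "build_schedule",
    "partition_into_volumes",
    "multiplex_schedule",
]

#: relative tolerance for integer / evenness classification of r = PRFe/Fm
PHASE_TOL = 1e-9
#: largest repetition multiplier m considered before a schedule is declared
#: non-repeating
DEFAULT_M_CAP = 64

_TWO_PI = 2.0 * math.pi


class ScheduleError(ValueError):
    """Raised for inconsistent or non-repeating transmit schedules."""


def _normalize_phase(phi: float) -> float:
    phi = math.fmod(phi, _TWO_PI)
    return phi + _TWO_PI if phi < 0 else phi


@dataclass(frozen=True)
class MirrorKinematics:
    """Sinusoidal tilt law of the scanning mirror.

    Parameters are the half-side tilt amplitude ``half_range_deg`` (A),
    tilt frequency ``tilt_freq_hz`` (Fm), initial phase ``phase_rad`` (phi,
    normalized to [0, 2*pi)) and tilt offset ``offset_deg`` (gamma).
    """

    half_range_deg: float
    tilt_freq_hz: float
    phase_rad: float = 0.0
    offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.half_range_deg < 0:
            raise ValueError("half_range_deg must be >= 0")
        if self.tilt_freq_hz <= 0:
            raise ValueError("tilt_freq_hz must be > 0")
        object.__setattr__(self, "phase_rad", _normalize_phase(self.phase_rad))

    @property
    def period_s(self) -> float:
        return 1.0 / self.tilt_freq_hz


@dataclass(frozen=True)
class AcquisitionConfig:
    """Plane-wave acquisition parameters.

    ``imaging_depth_mm`` is measured from the mirror plate center;
    ``mirror_offset_mm`` is the transducer-to-mirror distance added to every
    acoustic path.  The PRF must respect the round-trip travel time over the
    total path ``imaging_depth_mm + mirror_offset_mm``.
    """

    sound_speed_mps: float = 1480.0
    imaging_depth_mm: float = 28.6
    prf_hz: float = 20000.0
    n_compound_angles: int = 1
    n_scan_lines: int = 1
    mirror_offset_mm: float = 2.1
    duration_s: float = 0.008

    def __post_init__(self) -> None:
        if self.sound_speed_mps <= 0 or self.imaging_depth_mm <= 0:
            raise ValueError("sound speed and imaging depth must be positive")
        if self.n_compound_angles < 1 or self.n_scan_lines < 1:
            raise ValueError("n_compound_angles and n_scan_lines must be >= 1")
        max_prf = prf_from_depth(
            self.sound_speed_mps, self.imaging_depth_mm + self.mirror_offset_mm
        )
        if self.prf_hz > max_prf * (1 + 1e-9):
            raise ValueError(
                f"prf {self.prf_hz:g} Hz exceeds round-trip limit {max_prf:g} Hz"
            )

    @property
    def effective_prf_hz(self) -> float:
        return effective_prf(self.prf_hz, self.n_compound_angles)


@dataclass(frozen=True)
class PlaneSample:
    """One transmitted plane: when it fired and where the beam pointed."""

    index: int
    time_s: float
    tilt_deg: float
    scan_deg: float
    volume_id: int = -1
    sweep_dir: Literal["up", "down", "period", "none"] = "none"
    steer_deg: float = 0.0
    beam_index: int = 0


@dataclass(frozen=True)
class RateResult:
    """Volume-rate classification of a PRFe/Fm ratio."""

    volume_rate_hz: float
    regime: Literal["condition1", "condition2"]
    multiplier_m: int
    planes_per_volume: int
    peak_sampled: bool
    ratio: float


@dataclass(frozen=True)
class MultiplexResult:
    """Volume rate / elevational sampling of a multiplexed sequence."""

    mode: Literal["plane", "compound", "line_by_line"]
    volume_rate_hz: float
    sampled_positions: int


def prf_from_depth(sound_speed_mps: float, depth_mm: float) -> float:
    """Maximum pulse repetition frequency ``c / (2 d)`` for a round trip.

    >>> prf_from_depth(1500, 30)
    25000.0
    """
    if sound_speed_mps <= 0 or depth_mm <= 0:
        raise ValueError("sound speed and depth must be positive")
    return sound_speed_mps / (2.0 * depth_mm * 1e-3)


def effective_prf(prf_hz: float, n_compound_angles: int) -> float:
    """Per-frame rate after angular compounding: ``PRF / na``."""
    if n_compound_angles < 1:
        raise ValueError("n_compound_angles must be >= 1")
    if prf_hz <= 0:
        raise ValueError("prf must be positive")
    return prf_hz / n_compound_angles


def tilt_angle_at(kin: MirrorKinematics, time_s) -> float:
    """Mirror tilt angle (degrees) at ``time_s`` (scalar or array)."""
    t = np.asarray(time_s, dtype=float)
    theta = (
        kin.half_range_deg * np.sin(_TWO_PI * kin.tilt_freq_hz * t + kin.phase_rad)
        + kin.offset_deg
    )
    return float(theta) if np.ndim(time_s) == 0 else theta


def scan_angle_at(kin: MirrorKinematics, time_s) -> float:
    """Beam scan angle: exactly twice the tilt angle."""
    return 2.0 * tilt_angle_at(kin, time_s)


def _is_integer(x: float, tol: float = PHASE_TOL) -> bool:
    return abs(x - round(x)) <= tol * max(1.0, abs(x))


def _peak_sampled(ratio: float, phase_rad: float, period_samples: int) -> bool:
    """True if any transmit in one repetition period lands on |sin| = 1."""
    for n in range(1, period_samples + 1):
        psi = _TWO_PI * n / ratio + phase_rad
        # distance of psi from pi/2 (mod pi)
        frac = math.fmod(psi - math.pi / 2.0, math.pi)
        if frac < 0:
            frac += math.pi
        if min(frac, math.pi - frac) <= 1e-9 * max(1.0, abs(psi)):
            return True
    return False


def volume_rate(
    effective_prf_hz: float,
    kin: MirrorKinematics,
    m_cap: int = DEFAULT_M_CAP,
) -> RateResult:
    """Classify ``r = PRFe / Fm`` and return the volume rate.

    Condition 1 (``r`` even integer, ``(r/pi)*phi`` integer) gives
    ``Fv = 2 Fm``; otherwise the smallest ``m`` with ``m r`` integer gives
    ``Fv = Fm / m``.  ``peak_sampled`` records whether a transmit lands on a
    tilt extremum (the ``+1`` plane of the condition-1 count).
    """
    if effective_prf_hz <= 0:
        raise ValueError("effective PRF must be positive")
    fm = kin.tilt_freq_hz
    r = effective_prf_hz / fm

    cond1 = False
    if _is_integer(r) and round(r) % 2 == 0:
        phase_term = (r / math.pi) * kin.phase_rad
        if _is_integer(phase_term):
            cond1 = True
        else:
            warnings.warn(
                "even PRFe/Fm ratio with a phase violating the condition-1 "
                "phase requirement; classified as condition 2",
                stacklevel=2,
            )

    if cond1:
        fv = 2.0 * fm
        m = 1
        period = round(r)
        peak = _peak_sampled(r, kin.phase_rad, period)
        n_planes = round(r) // 2 + (1 if peak else 0)
        return RateResult(fv, "condition1", m, n_planes, peak, r)

    for m in range(1, m_cap + 1):
        if _is_integer(m * r):
            period = round(m * r)
            if period >= 1:
                fv = fm / m
                peak = _peak_sampled(r, kin.phase_rad, period)
                return RateResult(fv, "condition2", m, period, peak, r)
    raise ScheduleError(
        f"non-repeating schedule: PRFe/Fm = {r:g} has no multiplier m <= {m_cap}"
    )


def planes_per_volume(effective_prf_hz: float, rate: RateResult) -> int:
    """Planes sampled in one volume: ``PRFe/Fv`` (+1 for a sampled extremum
    in condition 1)."""
    q = effective_prf_hz / rate.volume_rate_hz
    if not _is_integer(q, 1e-9):
        raise ScheduleError(
            f"PRFe/Fv = {q:g} is not an integer; rate inconsistent with PRFe"
        )
    extra = 1 if (rate.regime == "condition1" and rate.peak_sampled) else 0
    return round(q) + extra


def build_schedule(
    acq: AcquisitionConfig,
    kin: MirrorKinematics,
    partition: bool = True,
) -> list[PlaneSample]:
    """Enumerate transmits ``n = 1 .. floor(duration * PRFe)``.

    Each sample carries time, tilt and scan angle; when ``partition`` is
    true, volume ids and sweep directions are filled in via
    :func:`partition_into_volumes` (requires the schedule to cover at least
    one full volume).
    """
    prfe = acq.effective_prf_hz
    n_total = int(math.floor(acq.duration_s * prfe * (1 + 1e-12)))
    samples = []
    for n in range(1, n_total + 1):
        t = n / prfe
        theta = tilt_angle_at(kin, t)
        samples.append(PlaneSample(n, t, theta, 2.0 * theta))
    if not samples:
        return samples
    if partition:
        rate = volume_rate(prfe, kin)
        samples = partition_into_volumes(samples, rate, kin)
    return samples


def _peak_times(kin: MirrorKinematics, t_min: float, t_max: float) -> list[float]:
    """Times of tilt extrema (|sin| = 1) covering [t_min, t_max]."""
    fm = kin.tilt_freq_hz
    # psi = 2 pi Fm t + phi = pi/2 + k pi
    k_lo = math.floor((_TWO_PI * fm * t_min + kin.phase_rad - math.pi / 2) / math.pi) - 1
    k_hi = math.ceil((_TWO_PI * fm * t_max + kin.phase_rad - math.pi / 2) / math.pi) + 1
    return [
        (math.pi / 2 + k * math.pi - kin.phase_rad) / (_TWO_PI * fm)
        for k in range(k_lo, k_hi + 1)
    ]


def partition_into_volumes(
    schedule: Sequence[PlaneSample],
    rate: RateResult,
    kin: MirrorKinematics,
) -> list[PlaneSample]:
    """Assign volume ids to a schedule.

    Condition 1: a volume is one monotonic half-sweep of the tilt between
    consecutive extrema; a transmit landing exactly on an extremum belongs to
    both adjacent volumes and is emitted twice (once per volume id).
    Condition 2: a volume is one full repetition period of the sampled-angle
    sequence (``m`` mirror cycles).  Samples in incomplete leading/trailing
    volumes keep ``volume_id = -1``.
    """
    if not schedule:
        raise ScheduleError("empty schedule: shorter than one volume")
    out: list[PlaneSample] = []
    n_complete = 0

    if rate.regime == "condition1":
        tol = 1e-9 / kin.tilt_freq_hz
        t0, t1 = schedule[0].time_s, schedule[-1].time_s
        peaks = _peak_times(kin, t0, t1)
        # complete intervals: [peaks[i], peaks[i+1]] fully inside sampled span
        intervals = [
            (peaks[i], peaks[i + 1])
            for i in range(len(peaks) - 1)
            if peaks[i] >= t0 - tol and peaks[i + 1] <= t1 + tol
        ]
        vol_of_interval = {}
        for a, b in intervals:
            vol_of_interval[(a, b)] = n_complete
            n_complete += 1
        for s in schedule:
            hits = []
            for (a, b) in intervals:
                if a - tol <= s.time_s <= b + tol:
                    # sweep direction from sign of sin at interval start
                    start_sin = math.sin(
                        _TWO_PI * kin.tilt_freq_hz * a + kin.phase_rad
                    )
                    direction = "down" if start_sin > 0 else "up"
                    hits.append(
                        replace(
                            s,
                            volume_id=vol_of_interval[(a, b)],
                            sweep_dir=direction,
                        )
                    )
            out.extend(hits if hits else [s])
    else:
        period = rate.planes_per_volume  # m * r samples
        first = schedule[0].index
        last = schedule[-1].index
        n_complete = (last - first + 1) // period
        for s in schedule:
            j = (s.index - first) // period
            if j < n_complete:
                out.append(replace(s, volume_id=j, sweep_dir="period"))
            else:
                out.append(s)

    if n_complete == 0:
        raise ScheduleError("schedule shorter than one volume")
    return out


def default_compound_angles(n: int, spread_deg: float = 2.0) -> list[float]:
    """Symmetric steering-angle set, e.g. (-2, 0, +2) degrees for n=3."""
    if n == 1:
        return [0.0]
    return [float(a) for a in np.linspace(-spread_deg, spread_deg, n)]


def multiplex_schedule(
    acq: AcquisitionConfig,
    kin: MirrorKinematics,
    mode: Literal["plane", "compound", "line_by_line"],
    steer_spread_deg: float = 2.0,
) -> tuple[MultiplexResult, list[PlaneSample]]:
    """Trade azimuthal image quality against elevational sampling.

    ``compound``: the ``na`` steering angles fire back-to-back at the full
    PRF, so the volume rate is unchanged but the distinct elevational
    positions per volume drop by a factor ``na``.  ``line_by_line``: each of
    the ``nl`` beams occupies a whole sweep, so the volume rate drops to
    ``Fv / nl`` while the elevational positions are unchanged.
    """
    if mode not in ("plane", "compound", "line_by_line"):
        raise ValueError(f"unknown multiplex mode {mode!r}")

    if mode in ("plane", "compound"):
        na = acq.n_compound_angles if mode == "compound" else 1
        prfe = acq.prf_hz / na
        rate = volume_rate(prfe, kin)
        n_p = planes_per_volume(prfe, rate)
        angles = default_compound_angles(na, steer_spread_deg)
        # full-PRF transmit list, cycling through steering angles
        n_total = int(math.floor(acq.duration_s * acq.prf_hz * (1 + 1e-12)))
        samples = []
        for n in range(1, n_total + 1):
            t = n / acq.prf_hz
            theta = tilt_angle_at(kin, t)
            samples.append(
                PlaneSample(
                    n,
                    t,
                    theta,
                    2.0 * theta,
                    steer_deg=angles[(n - 1) % na],
                    beam_index=(n - 1) % na,
                )
            )
        return MultiplexResult(mode, rate.volume_rate_hz, n_p), samples

    # line-by-line: plane-wave kinematics, beams rotate across sweeps
    nl = acq.n_scan_lines
    prfe = acq.prf_hz
    rate = volume_rate(prfe, kin)
    n_p = planes_per_volume(prfe, rate)
    base = build_schedule(
        replace(acq, n_compound_angles=1), kin, partition=True
    )
    samples = [
        replace(
            s,
            beam_index=(s.volume_id % nl) if s.volume_id >= 0 else 0,
            volume_id=(s.volume_id // nl) if s.volume_id >= 0 else -1,
        )
        for s in base
    ]
    return MultiplexResult(mode, rate.volume_rate_hz / nl, n_p), samples


def samples_of_volume(
    schedule: Sequence[PlaneSample], volume_id: int
) -> list[PlaneSample]:
    """Samples belonging to one volume, in time order."""
    return [s for s in schedule if s.volume_id == volume_id]
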