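"""Scan conversion of per-plane frames into a Cartesian 3-D volume.

Each beamformed plane sits at a scan angle ``alpha`` in a polar wedge; a
pixel at depth ``d`` maps to Cartesian ``(y, z) = (d sin alpha, d cos alpha)``
with lateral ``x`` unchanged.  The regular Cartesian grid is filled by
trilinear interpolation: linear across the (nonuniformly spaced) angle
dimension and bilinear within each plane.  Voxels outside the sampled wedge
are flagged invalid, not zero-filled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .beamform import BModeFrame
from .scheduler import MirrorKinematics, PlaneSample

__all__ = [
    "GridSpec",
    "Volume",
    "scan_convert_point",
    "invert_scan_convert",
    "reconstruct_volume",
    "fov_extent",
]


@dataclass(frozen=True)
class GridSpec:
    """Cartesian reconstruction grid (mm, mirror plate center = origin)."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    z_min: float
    z_max: float
    spacing_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        def ax(lo: float, hi: float) -> np.ndarray:
            n = int(round((hi - lo) / self.spacing_mm)) + 1
            return lo + np.arange(n) * self.spacing_mm

        return ax(self.x_min, self.x_max), ax(self.y_min, self.y_max), ax(
            self.z_min, self.z_max
        )


@dataclass
class Volume:
    """Reconstructed intensity on a regular grid with a validity mask."""

    intensity: np.ndarray  # (nx, ny, nz), linear units; 0 where invalid
    valid: np.ndarray  # boolean wedge mask, same shape
    x_axis_mm: np.ndarray
    y_axis_mm: np.ndarray
    z_axis_mm: np.ndarray
    volume_id: int = 0
    time_span_s: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        def step(a: np.ndarray) -> float:
            return float(a[1] - a[0]) if len(a) > 1 else 1.0

        return (step(self.x_axis_mm), step(self.y_axis_mm), step(self.z_axis_mm))


def scan_convert_point(depth_mm: float, scan_alpha_deg: float):
    """Polar (depth, scan angle) to Cartesian ``(y, z)`` in mm."""
    d = np.asarray(depth_mm, float)
    if np.any(d < 0):
        raise ValueError("depth must be >= 0")
    a = np.radians(scan_alpha_deg)
    return d * np.sin(a), d * np.cos(a)


def invert_scan_convert(y_mm: float, z_mm: float):
    """Cartesian ``(y, z)`` back to (depth, scan angle in degrees)."""
    y = np.asarray(y_mm, float)
    z = np.asarray(z_mm, float)
    return np.hypot(y, z), np.degrees(np.arctan2(y, z))


def reconstruct_volume(
    frames: Sequence[BModeFrame],
    samples: Sequence[PlaneSample],
    grid: GridSpec,
    duplicate_policy: Literal["mean", "first", "last"] = "mean",
    angle_tol_deg: float = 1e-9,
) -> Volume:
    """Scan convert one volume's frames onto a Cartesian grid.

    Frames are matched to schedule samples by plane index to obtain each
    frame's scan angle.  Frames sharing an angle (the condition-1 planes
    imaged twice per mirror cycle) are merged according to
    ``duplicate_policy`` before interpolation.
    """
    if len(frames) != len(samples):
        raise ValueError("frames and samples must align one-to-one")
    by_index = {s.index: s for s in samples}
    pairs = []
    for f in frames:
        if f.plane_index not in by_index:
            raise ValueError(f"no schedule sample for plane index {f.plane_index}")
        pairs.append((by_index[f.plane_index].scan_deg, f))
    pairs.sort(key=lambda p: p[0])

    ref = pairs[0][1]
    for _, f in pairs:
        if not (
            np.array_equal(f.x_axis_mm, ref.x_axis_mm)
            and np.array_equal(f.depth_axis_mm, ref.depth_axis_mm)
        ):
            raise ValueError("frames must share the (x, depth) pixel grid")

    # merge duplicate angles
    angles: list[float] = []
    stacks: list[np.ndarray] = []
    for a, f in pairs:
        if angles and abs(a - angles[-1]) <= angle_tol_deg:
            if duplicate_policy == "mean":
                group = stacks[-1]
                n = group["n"] + 1
                stacks[-1] = {
                    "env": group["env"] + (f.envelope - group["env"]) / n,
                    "n": n,
                }
            elif duplicate_policy == "last":
                stacks[-1] = {"env": f.envelope.astype(float), "n": 1}
            # "first": keep existing
        else:
            angles.append(a)
            stacks.append({"env": f.envelope.astype(float), "n": 1})
    if len(angles) < 2:
        raise ValueError("cannot interpolate elevationally: fewer than 2 distinct angles")

    data = np.stack([s["env"] for s in stacks], axis=0)  # (na, nx, nd)
    interp = RegularGridInterpolator(
        (np.asarray(angles), ref.x_axis_mm, ref.depth_axis_mm),
        data,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )

    xa, ya, za = grid.axes()
    xg, yg, zg = np.meshgrid(xa, ya, za, indexing="ij")
    d_v, a_v = invert_scan_convert(yg, zg)
    vals = interp(np.stack([a_v.ravel(), xg.ravel(), d_v.ravel()], axis=-1)).reshape(
        xg.shape
    )
    valid = np.isfinite(vals)
    vals = np.where(valid, vals, 0.0)

    times = [s.time_s for s in samples]
    vol_ids = {s.volume_id for s in samples if s.volume_id >= 0}
    return Volume(
        intensity=vals,
        valid=valid,
        x_axis_mm=xa,
        y_axis_mm=ya,
        z_axis_mm=za,
        volume_id=min(vol_ids) if vol_ids else 0,
        time_span_s=(min(times), max(times)),
        metadata={
            "n_angles": len(angles),
            "angle_range_deg": (float(angles[0]), float(angles[-1])),
            "duplicate_policy": duplicate_policy,
        },
    )


def volume_from_translation(
    frames: Sequence[BModeFrame],
    y_offsets_mm: np.ndarray,
) -> Volume:
    """Stack 0-degree frames from a mechanical elevational sweep.

    The elevational axis is the translation positions themselves (uniform);
    all voxels are valid.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 translation steps")
    ref = frames[0]
    data = np.stack([f.envelope for f in frames], axis=1)  # (nx, ny, nd)
    valid = np.ones_like(data, bool)
    return Volume(
        intensity=data,
        valid=valid,
        x_axis_mm=ref.x_axis_mm.copy(),
        y_axis_mm=np.asarray(y_offsets_mm, float),
        z_axis_mm=ref.depth_axis_mm.copy(),
        metadata={"mode": "mechanical_translation"},
    )


def fov_extent(depth_mm: float, kin: MirrorKinematics) -> tuple[float, float]:
    """Field-of-view of the swept wedge at a given depth.

    The beam scan range is twice the total tilt range (law of reflection),
    i.e. ``4 A`` degrees; the chord subtended at ``depth`` is
    ``2 d sin(range/2)``.
    """
    if depth_mm <= 0:
        raise ValueError("depth must be positive")
    angle_range_deg = 4.0 * kin.half_range_deg
    chord_mm = 2.0 * depth_mm * math.sin(math.radians(angle_range_deg / 2.0))
    return angle_range_deg, chord_mm
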