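"""End-to-end pipelines: schedule -> simulate -> beamform -> reconstruct.

These functions tie the modules into the two 3-D imaging modes that are
compared throughout: the mirror-swept mode (one wedge volume per half-sweep
or repetition period) and the mechanical-translation benchmark (the probe
itself stepped elevationally, wobbler style).
"""

from __future__ import annotations

import numpy as np

from .acoustic import TransducerModel, simulate_rf
from .beamform import BModeFrame, das_beamform, translate_scan
from .config import RunConfig
from .phantom import Phantom, make_cyst_phantom, make_wire_phantom
from .reconstruct import GridSpec, Volume, reconstruct_volume, volume_from_translation
from .scheduler import (
    AcquisitionConfig,
    MirrorKinematics,
    PlaneSample,
    RateResult,
    build_schedule,
    planes_per_volume,
    samples_of_volume,
    volume_rate,
)

__all__ = [
    "schedule_report",
    "default_image_grid",
    "simulate_volume_frames",
    "mirror_swept_volume",
    "translation_volume",
    "phantom_from_config",
]


def schedule_report(
    acq: AcquisitionConfig, kin: MirrorKinematics
) -> tuple[list[PlaneSample], RateResult, int]:
    """Schedule plus its rate classification and planes-per-volume count."""
    rate = volume_rate(acq.effective_prf_hz, kin)
    n_p = planes_per_volume(acq.effective_prf_hz, rate)
    schedule = build_schedule(acq, kin)
    return schedule, rate, n_p


def default_image_grid(
    tx: TransducerModel,
    acq: AcquisitionConfig,
    depth_min_mm: float | None = None,
    depth_max_mm: float | None = None,
    x_span_mm: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(x, depth) pixel grid: half-wavelength axial step, one pitch lateral."""
    lam = tx.wavelength_mm(acq.sound_speed_mps)
    lo = lam if depth_min_mm is None else depth_min_mm
    hi = acq.imaging_depth_mm if depth_max_mm is None else depth_max_mm
    span = (tx.n_elements - 1) * tx.pitch_mm if x_span_mm is None else x_span_mm
    x = np.arange(-span / 2, span / 2 + tx.pitch_mm / 2, tx.pitch_mm)
    d = np.arange(lo, hi + lam / 4, lam / 2)
    return x, d


def simulate_volume_frames(
    phantom: Phantom,
    tx: TransducerModel,
    acq: AcquisitionConfig,
    samples: list[PlaneSample],
    snr_db: float | None = None,
    seed: int | None = None,
):
    """Simulate RF for each unique transmit in a volume's sample list.

    Condition-1 volumes share their extremal plane with a neighbour; the
    shared transmit is simulated once and reused (same index, same physics).
    """
    frames = {}
    for s in samples:
        if s.index in frames:
            continue
        frames[s.index] = simulate_rf(
            phantom,
            tx,
            acq,
            scan_alpha_deg=s.scan_deg,
            steer_deg=s.steer_deg,
            plane_index=s.index,
            snr_db=snr_db,
            seed=None if seed is None else seed + s.index,
        )
    return [frames[s.index] for s in samples]


def mirror_swept_volume(
    phantom: Phantom,
    tx: TransducerModel,
    acq: AcquisitionConfig,
    kin: MirrorKinematics,
    grid: GridSpec,
    volume_id: int = 0,
    x_grid_mm: np.ndarray | None = None,
    depth_grid_mm: np.ndarray | None = None,
    snr_db: float | None = None,
    seed: int | None = None,
    schedule: list[PlaneSample] | None = None,
) -> tuple[Volume, list[BModeFrame]]:
    """Image one wedge volume with the tilting mirror.

    Simulates every plane of the requested volume, beamforms on a shared
    (x, depth) grid, and scan converts onto ``grid``.
    """
    if schedule is None:
        schedule = build_schedule(acq, kin)
    samples = samples_of_volume(schedule, volume_id)
    if not samples:
        raise ValueError(f"schedule contains no volume {volume_id}")
    if x_grid_mm is None or depth_grid_mm is None:
        x_default, d_default = default_image_grid(
            tx,
            acq,
            depth_min_mm=grid.z_min * 0.7,
            depth_max_mm=min(grid.z_max * 1.2, acq.imaging_depth_mm),
        )
        x_grid_mm = x_default if x_grid_mm is None else x_grid_mm
        depth_grid_mm = d_default if depth_grid_mm is None else depth_grid_mm
    rf_frames = simulate_volume_frames(phantom, tx, acq, samples, snr_db, seed)
    bmode = [das_beamform(fr, tx, x_grid_mm, depth_grid_mm) for fr in rf_frames]
    vol = reconstruct_volume(bmode, samples, grid)
    return vol, bmode


def translation_volume(
    phantom: Phantom,
    tx: TransducerModel,
    acq: AcquisitionConfig,
    x_grid_mm: np.ndarray,
    depth_grid_mm: np.ndarray,
    step_mm: float = 0.5,
    n_steps: int = 13,
    snr_db: float | None = None,
    seed: int | None = None,
) -> Volume:
    """Mechanical-translation benchmark volume on the same phantom."""
    frames, offsets = translate_scan(
        phantom, tx, acq, x_grid_mm, depth_grid_mm, step_mm, n_steps,
        seed=seed, snr_db=snr_db,
    )
    return volume_from_translation(frames, offsets)


def phantom_from_config(cfg: RunConfig) -> Phantom:
    spec = dict(cfg.phantom)
    kind = spec.pop("type", "wire")
    if kind == "wire":
        spec.setdefault("seed", cfg.seed)
        return make_wire_phantom(**spec)
    if kind == "cyst":
        spec.setdefault("seed", cfg.seed)
        return make_cyst_phantom(**spec)
    raise ValueError(f"unknown phantom type {kind!r}")
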