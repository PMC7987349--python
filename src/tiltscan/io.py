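"""Persistence: HDF5 RF frames and phantoms, NIfTI/TIFF volumes, CSV
schedules and metrics.  Every writer stamps provenance metadata (config
hash, seed, package version) so downstream stages can refuse mismatched
inputs."""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Sequence

import h5py
import nibabel as nib
import numpy as np
import tifffile
from PIL import Image

from . import __version__
from .acoustic import RFFrame
from .beamform import BModeFrame
from .phantom import Phantom
from .reconstruct import Volume
from .scheduler import PlaneSample

__all__ = [
    "config_hash",
    "write_schedule_csv",
    "read_schedule_csv",
    "save_phantom",
    "load_phantom",
    "save_rf_frames",
    "load_rf_frames",
    "save_volume_nifti",
    "save_volume_tiff",
    "save_frame_tiff",
    "save_frame_png",
    "write_metrics_csv",
]

SCHEDULE_COLUMNS = ["index", "time_s", "tilt_deg", "scan_deg", "volume_id", "sweep_dir"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_schedule_csv(path, schedule: Sequence[PlaneSample]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SCHEDULE_COLUMNS)
        for s in schedule:
            w.writerow(
                [s.index, f"{s.time_s:.9g}", f"{s.tilt_deg:.9g}", f"{s.scan_deg:.9g}",
                 s.volume_id, s.sweep_dir]
            )


def read_schedule_csv(path) -> list[PlaneSample]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PlaneSample(
                    index=int(row["index"]),
                    time_s=float(row["time_s"]),
                    tilt_deg=float(row["tilt_deg"]),
                    scan_deg=float(row["scan_deg"]),
                    volume_id=int(row["volume_id"]),
                    sweep_dir=row["sweep_dir"],
                )
            )
    return out


def save_phantom(path, phantom: Phantom) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions_mm", data=phantom.positions_mm)
        f.create_dataset("amplitudes", data=phantom.amplitudes)
        f.attrs["label"] = phantom.label
        f.attrs["metadata_json"] = json.dumps(phantom.metadata, default=str)
        f.attrs["version"] = __version__


def load_phantom(path) -> Phantom:
    with h5py.File(path, "r") as f:
        return Phantom(
            f["positions_mm"][()],
            f["amplitudes"][()],
            label=str(f.attrs.get("label", "")),
            metadata=json.loads(f.attrs.get("metadata_json", "{}")),
        )


def save_rf_frames(path, frames: Sequence[RFFrame], cfg_hash: str = "") -> None:
    """RF frames under /frames/<n>/channel_data with acquisition attrs."""
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = cfg_hash
        f.attrs["version"] = __version__
        grp = f.create_group("frames")
        for fr in frames:
            g = grp.create_group(str(fr.plane_index))
            g.create_dataset("channel_data", data=fr.channel_data, compression="gzip")
            g.attrs.update(
                {
                    "sampling_freq_hz": fr.sampling_freq_hz,
                    "scan_alpha_deg": fr.scan_alpha_deg,
                    "steer_deg": fr.steer_deg,
                    "t0_s": fr.t0_s,
                    "sound_speed_mps": fr.sound_speed_mps,
                    "mirror_offset_mm": fr.mirror_offset_mm,
                    "metadata_json": json.dumps(fr.metadata, default=str),
                }
            )


def load_rf_frames(path, expect_hash: str | None = None) -> list[RFFrame]:
    frames = []
    with h5py.File(path, "r") as f:
        stored = str(f.attrs.get("config_hash", ""))
        if expect_hash is not None and stored != expect_hash:
            raise ValueError(
                f"stage-input mismatch: frames carry config hash {stored!r}, "
                f"expected {expect_hash!r}"
            )
        for key in sorted(f["frames"], key=int):
            g = f["frames"][key]
            frames.append(
                RFFrame(
                    channel_data=g["channel_data"][()],
                    sampling_freq_hz=float(g.attrs["sampling_freq_hz"]),
                    scan_alpha_deg=float(g.attrs["scan_alpha_deg"]),
                    steer_deg=float(g.attrs["steer_deg"]),
                    plane_index=int(key),
                    t0_s=float(g.attrs["t0_s"]),
                    sound_speed_mps=float(g.attrs["sound_speed_mps"]),
                    mirror_offset_mm=float(g.attrs["mirror_offset_mm"]),
                    metadata=json.loads(g.attrs.get("metadata_json", "{}")),
                )
            )
    return frames


def save_volume_nifti(path, vol: Volume) -> None:
    """Intensity + validity mask as NIfTI with spacing/origin in the affine.

    Axis order (x, y, z); the companion mask is written next to the image
    with a ``_mask`` suffix.
    """
    sx, sy, sz = vol.spacing_mm
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = [vol.x_axis_mm[0], vol.y_axis_mm[0], vol.z_axis_mm[0]]
    nib.save(nib.Nifti1Image(vol.intensity.astype(np.float32), affine), str(path))
    mask_path = Path(path)
    mask_path = mask_path.with_name(mask_path.name.replace(".nii", "_mask.nii"))
    nib.save(nib.Nifti1Image(vol.valid.astype(np.uint8), affine), str(mask_path))


def save_volume_tiff(path, vol: Volume) -> None:
    """Multi-page float32 TIFF (pages along z) plus a JSON sidecar with the
    grid, mask summary, and provenance."""
    tifffile.imwrite(str(path), np.moveaxis(vol.intensity.astype(np.float32), 2, 0))
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "axes_order": "zxy pages",
                "x_axis_mm": vol.x_axis_mm.tolist(),
                "y_axis_mm": vol.y_axis_mm.tolist(),
                "z_axis_mm": vol.z_axis_mm.tolist(),
                "coordinate_convention": "right-handed, origin at mirror plate "
                "center, z axial away from mirror, y elevational, x lateral",
                "n_valid_voxels": int(vol.valid.sum()),
                "metadata": vol.metadata,
                "version": __version__,
            },
            indent=2,
            default=str,
        )
    )
    tifffile.imwrite(
        str(Path(str(path)).with_suffix(".mask.tif")),
        np.moveaxis(vol.valid.astype(np.uint8), 2, 0),
    )


def save_frame_tiff(path, frame: BModeFrame) -> None:
    """Linear envelope as 32-bit TIFF."""
    tifffile.imwrite(str(path), frame.envelope.astype(np.float32))


def save_frame_png(path, frame: BModeFrame, dyn_range_db: float = 40.0) -> None:
    """Log-compressed envelope as 8-bit PNG (dynamic range in metadata)."""
    img = frame.log_compressed(dyn_range_db)
    img8 = np.round((img + dyn_range_db) / dyn_range_db * 255.0).astype(np.uint8)
    pil = Image.fromarray(img8.T)  # depth down the page
    from PIL.PngImagePlugin import PngInfo

    info = PngInfo()
    info.add_text("dynamic_range_db", str(dyn_range_db))
    info.add_text("scan_alpha_deg", str(frame.scan_alpha_deg))
    pil.save(str(path), pnginfo=info)


def write_metrics_csv(path, rows: Sequence[dict]) -> None:
    """Metric rows (keyed by depth/mode/seed) as CSV."""
    if not rows:
        raise ValueError("no metric rows to write")
    keys = list(rows[0])
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=keys)
        w.writeheader()
        w.writerows(rows)
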