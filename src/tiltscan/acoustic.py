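"""Pulse-echo RF channel-data simulation for one steered plane wave.

The tilting mirror is modeled as an ideal reflector: imaging at scan angle
``alpha`` is a rigid rotation of the scene about the mirror hinge (the
lateral ``x`` axis), with ranges measured from the mirror plate center and
the transducer-to-mirror path added to every delay.  Scattering is
single-bounce point-target: each scatterer contributes a Gaussian-enveloped
tone burst at the round-trip delay, weighted by a parametric elevational
beam profile (the array has no elevational focusing beyond its fixed lens).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phantom import Phantom
from .scheduler import AcquisitionConfig

__all__ = [
    "TransducerModel",
    "RFFrame",
    "rotate_scene",
    "elevational_sigma",
    "elevational_fwhm",
    "elevational_weight",
    "simulate_rf",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class TransducerModel:
    """Linear-array parameters (defaults follow a 15.625-MHz, 128-element,
    12.8-mm probe with its elevational focus near 6 mm)."""

    n_elements: int = 128
    pitch_mm: float = 0.1
    center_freq_mhz: float = 15.625
    sampling_freq_mhz: float = 62.5
    pulse_cycles: float = 3.0
    elevational_focus_mm: float = 6.0
    elevational_fwhm_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if self.sampling_freq_mhz < 4.0 * self.center_freq_mhz:
            raise ValueError("sampling frequency must be >= 4x center frequency")

    def element_x_mm(self) -> np.ndarray:
        """Element centers along x, centered on 0."""
        return (np.arange(self.n_elements) - (self.n_elements - 1) / 2.0) * self.pitch_mm

    def wavelength_mm(self, sound_speed_mps: float) -> float:
        return sound_speed_mps / (self.center_freq_mhz * 1e6) * 1e3


@dataclass
class RFFrame:
    """Per-element echo data for one transmission."""

    channel_data: np.ndarray  # (n_elements, n_samples)
    sampling_freq_hz: float
    scan_alpha_deg: float
    steer_deg: float = 0.0
    plane_index: int = 0
    t0_s: float = 0.0
    sound_speed_mps: float = 1480.0
    mirror_offset_mm: float = 2.1
    metadata: dict = field(default_factory=dict)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.channel_data.shape[1]) / self.sampling_freq_hz


def rotate_scene(phantom: Phantom, scan_alpha_deg: float) -> Phantom:
    """Express the scene in the imaging-plane frame at scan angle ``alpha``.

    A scatterer lying on the plane (``y = d sin(alpha)``, ``z = d cos(alpha)``)
    maps to elevational offset 0 at range ``d``; ranges from the mirror
    center are preserved exactly (rotation about the ``x`` axis).
    """
    a = math.radians(scan_alpha_deg)
    pos = phantom.positions_mm
    y, z = pos[:, 1], pos[:, 2]
    y_new = y * math.cos(a) - z * math.sin(a)  # offset from the plane
    z_new = y * math.sin(a) + z * math.cos(a)  # in-plane range
    out = np.column_stack([pos[:, 0], y_new, z_new])
    return Phantom(out, phantom.amplitudes.copy(), phantom.label, dict(phantom.metadata))


def elevational_sigma(range_mm, tx: TransducerModel, wavelength_mm: float) -> np.ndarray:
    """Gaussian-beam elevational sd (mm) vs range.

    ``sigma(z) = sigma0 sqrt(1 + ((z - zf)/zR)^2)`` with ``sigma0`` from the
    focal FWHM and Rayleigh range ``zR = pi (2 sigma0)^2 / lambda``.
    """
    z = np.asarray(range_mm, float)
    sigma0 = tx.elevational_fwhm_mm * _FWHM_TO_SIGMA
    z_r = math.pi * (2.0 * sigma0) ** 2 / wavelength_mm
    return sigma0 * np.sqrt(1.0 + ((z - tx.elevational_focus_mm) / z_r) ** 2)


def elevational_fwhm(range_mm, tx: TransducerModel, wavelength_mm: float) -> np.ndarray:
    """Elevational beam FWHM (mm) vs range; minimal at the focus."""
    return elevational_sigma(range_mm, tx, wavelength_mm) / _FWHM_TO_SIGMA


def elevational_weight(
    offset_mm, range_mm, tx: TransducerModel, wavelength_mm: float
) -> np.ndarray:
    """Sensitivity weight in [0, 1] for a scatterer off the imaging plane."""
    rng = np.asarray(range_mm, float)
    if np.any(rng <= 0):
        raise ValueError("range must be positive")
    sigma = elevational_sigma(rng, tx, wavelength_mm)
    return np.exp(-np.asarray(offset_mm, float) ** 2 / (2.0 * sigma**2))


def _pulse(t_s: np.ndarray, f0_hz: float, sigma_s: float) -> np.ndarray:
    return np.cos(2.0 * math.pi * f0_hz * t_s) * np.exp(-(t_s**2) / (2.0 * sigma_s**2))


def simulate_rf(
    phantom: Phantom,
    tx: TransducerModel,
    acq: AcquisitionConfig,
    scan_alpha_deg: float = 0.0,
    steer_deg: float = 0.0,
    plane_index: int = 0,
    snr_db: float | None = None,
    seed: int | None = None,
    cull_sigmas: float = 3.0,
) -> RFFrame:
    """Simulate one plane-wave transmission at the given scan angle.

    The transmit delay for a scatterer at in-plane coordinates ``(x, z)``
    (mm, range from the mirror) is the plane-wave arrival
    ``(z cos(s) + x sin(s) + mirror_offset)/c``; the receive delay per
    element is the Euclidean distance to the unfolded element position at
    ``z = -mirror_offset``.  Scatterers further than ``cull_sigmas`` beam
    sigmas from the plane are skipped.
    """
    if tx.sampling_freq_mhz < 4.0 * tx.center_freq_mhz:
        raise ValueError("aliasing: sampling frequency below 4x center frequency")
    c = acq.sound_speed_mps
    fs = tx.sampling_freq_mhz * 1e6
    f0 = tx.center_freq_mhz * 1e6
    lam = tx.wavelength_mm(c)
    sigma_p = tx.pulse_cycles / f0 * _FWHM_TO_SIGMA  # envelope FWHM = n_cycles periods

    # record long enough for the oblique return path from an edge pixel to
    # the far edge element, not just the straight two-way path
    max_depth_mm = acq.imaging_depth_mm + acq.mirror_offset_mm
    aperture_mm = (tx.n_elements - 1) * tx.pitch_mm
    max_path_mm = max_depth_mm + math.hypot(2.0 * aperture_mm, max_depth_mm)
    n_samples = int(math.ceil(max_path_mm * 1e-3 / c * fs)) + int(
        math.ceil(8.0 * sigma_p * fs)
    )
    data = np.zeros((tx.n_elements, n_samples))

    scene = rotate_scene(phantom, scan_alpha_deg)
    pos = scene.positions_mm
    amp = scene.amplitudes
    if len(pos):
        x, y_off, z = pos[:, 0], pos[:, 1], pos[:, 2]
        in_field = z > 0
        sigma_e = np.ones_like(z)
        sigma_e[in_field] = elevational_sigma(z[in_field], tx, lam)
        keep = in_field & (np.abs(y_off) <= cull_sigmas * sigma_e)
        x, y_off, z, amp = x[keep], y_off[keep], z[keep], amp[keep]
        w_elev = elevational_weight(y_off, z, tx, lam)

        s_rad = math.radians(steer_deg)
        elem_x = tx.element_x_mm()
        half_w = int(math.ceil(4.0 * sigma_p * fs))
        win = np.arange(-half_w, half_w + 1)

        tx_delay_mm = z * math.cos(s_rad) + x * math.sin(s_rad) + acq.mirror_offset_mm
        chunk = 256
        for i0 in range(0, len(x), chunk):
            sl = slice(i0, min(i0 + chunk, len(x)))
            dx = x[sl][:, None] - elem_x[None, :]  # (nc, ne)
            rx_mm = np.sqrt(
                dx**2 + y_off[sl][:, None] ** 2 + (z[sl][:, None] + acq.mirror_offset_mm) ** 2
            )
            tau = (tx_delay_mm[sl][:, None] + rx_mm) * 1e-3 / c  # (nc, ne)
            center_idx = np.rint(tau * fs).astype(int)  # (nc, ne)
            idx = center_idx[:, :, None] + win[None, None, :]  # (nc, ne, nw)
            t_rel = idx / fs - tau[:, :, None]
            vals = (amp[sl] * w_elev[sl])[:, None, None] * _pulse(t_rel, f0, sigma_p)
            valid = (idx >= 0) & (idx < n_samples)
            elem_idx = np.broadcast_to(
                np.arange(tx.n_elements)[None, :, None], idx.shape
            )
            np.add.at(
                data, (elem_idx[valid], idx[valid]), vals[valid]
            )

    if snr_db is not None and np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        sig_power = float(np.mean(data**2))
        noise_sd = math.sqrt(sig_power / (10.0 ** (snr_db / 10.0))) if sig_power > 0 else 0.0
        data = data + rng.normal(0.0, noise_sd, data.shape)

    return RFFrame(
        channel_data=data,
        sampling_freq_hz=fs,
        scan_alpha_deg=scan_alpha_deg,
        steer_deg=steer_deg,
        plane_index=plane_index,
        sound_speed_mps=c,
        mirror_offset_mm=acq.mirror_offset_mm,
        metadata={"seed": seed, "snr_db": snr_db, "n_scatterers": int(len(pos))},
    )
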