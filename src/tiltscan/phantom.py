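"""Synthetic scatterer scenes: wire targets and speckle blocks with
anechoic cavities.

Coordinates are millimetres in the mirror-centered frame: ``x`` lateral
(along the array), ``y`` elevational (swept by the mirror), ``z`` axial
(range from the mirror plate center).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Phantom", "make_wire_phantom", "make_cyst_phantom"]


@dataclass
class Phantom:
    """Point-scatterer scene: positions (N, 3) in mm and reflectivities."""

    positions_mm: np.ndarray
    amplitudes: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, float))
        self.amplitudes = np.asarray(self.amplitudes, float).ravel()
        if self.positions_mm.size == 0:
            self.positions_mm = np.empty((0, 3))
        if self.positions_mm.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.amplitudes) != len(self.positions_mm):
            raise ValueError("amplitudes and positions length mismatch")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be >= 0")

    def __len__(self) -> int:
        return len(self.positions_mm)

    def shifted(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "Phantom":
        """Rigidly translated copy (used by the mechanical-translation mode)."""
        return Phantom(
            self.positions_mm + np.array([dx, dy, dz]),
            self.amplitudes.copy(),
            self.label,
            dict(self.metadata),
        )


def make_wire_phantom(
    n_wires: int = 4,
    spacing_mm: float = 3.0,
    depth_mm: float = 15.0,
    seed: int = 0,
    x_extent_mm: float = 4.0,
    point_spacing_mm: float = 0.024,
    depth_jitter_mm: float = 0.0,
) -> Phantom:
    """Parallel wires along ``x``, spaced along the elevational axis.

    Each wire is a dense line of unit scatterers at fixed ``(y, z)``; wire
    ``y`` positions are centered on 0.  ``depth_jitter_mm`` adds a per-wire
    random depth offset (in-house wire phantoms are rarely coplanar).
    ``point_spacing_mm`` defaults to about a quarter wavelength at
    15.6 MHz so the wire appears continuous in beamformed frames.
    """
    if n_wires < 1:
        raise ValueError("n_wires must be >= 1")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    n_pts = max(2, int(round(x_extent_mm / point_spacing_mm)) + 1)
    xs = np.linspace(-x_extent_mm / 2, x_extent_mm / 2, n_pts)
    ys = (np.arange(n_wires) - (n_wires - 1) / 2.0) * spacing_mm
    positions = []
    for y in ys:
        z = depth_mm + (rng.normal(0.0, depth_jitter_mm) if depth_jitter_mm else 0.0)
        positions.append(np.column_stack([xs, np.full(n_pts, y), np.full(n_pts, z)]))
    pos = np.vstack(positions)
    return Phantom(
        pos,
        np.ones(len(pos)),
        label="wire",
        metadata={
            "n_wires": n_wires,
            "spacing_mm": spacing_mm,
            "depth_mm": depth_mm,
            "wire_y_mm": ys.tolist(),
            "seed": seed,
        },
    )


def make_cyst_phantom(
    cavity_centers_mm=((0.0, 0.0, 17.0),),
    cavity_radius_mm: float = 1.5,
    scatterer_density_per_mm3: float = 30.0,
    seed: int = 0,
    block_min_mm=(-2.5, -3.5, 14.5),
    block_max_mm=(2.5, 3.5, 19.5),
) -> Phantom:
    """Uniform speckle block minus spherical anechoic cavities.

    Scatterer count is Poisson with mean ``density * block volume``;
    amplitudes are Rayleigh with unit mean, which yields fully developed
    speckle once several scatterers fall in each resolution cell.
    """
    if scatterer_density_per_mm3 <= 0:
        raise ValueError("density must be positive")
    lo = np.asarray(block_min_mm, float)
    hi = np.asarray(block_max_mm, float)
    if np.any(hi <= lo):
        raise ValueError("zero-volume phantom block")
    rng = np.random.default_rng(seed)
    volume = float(np.prod(hi - lo))
    n = rng.poisson(scatterer_density_per_mm3 * volume)
    pos = rng.uniform(lo, hi, size=(n, 3))
    # Rayleigh(sigma) has mean sigma*sqrt(pi/2); unit mean -> sigma = sqrt(2/pi)
    amp = rng.rayleigh(np.sqrt(2.0 / np.pi), size=n)
    centers = np.atleast_2d(np.asarray(cavity_centers_mm, float)) if len(
        np.atleast_1d(cavity_centers_mm)
    ) else np.empty((0, 3))
    keep = np.ones(n, bool)
    for c in centers:
        keep &= np.linalg.norm(pos - c, axis=1) > cavity_radius_mm
    return Phantom(
        pos[keep],
        amp[keep],
        label="cyst",
        metadata={
            "cavity_centers_mm": np.asarray(centers).tolist(),
            "cavity_radius_mm": cavity_radius_mm,
            "density_per_mm3": scatterer_density_per_mm3,
            "block_min_mm": lo.tolist(),
            "block_max_mm": hi.tolist(),
            "seed": seed,
        },
    )
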