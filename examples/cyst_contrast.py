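"""Anechoic-cavity contrast: mirror-swept volume vs mechanical translation.

Images one speckle phantom with a 1.5-mm anechoic cavity at 17-mm depth
with both 3-D modes — the 500-Hz mirror-swept wedge and a wobbler-style
0.5-mm-step probe translation — and compares contrast-to-noise ratio
computed on linear envelope intensities in matched regions of interest.
"""

from tiltscan import (
    AcquisitionConfig,
    GridSpec,
    MirrorKinematics,
    ROI,
    TransducerModel,
    cnr,
    make_cyst_phantom,
)
from tiltscan.pipeline import (
    default_image_grid,
    mirror_swept_volume,
    translation_volume,
)

acq = AcquisitionConfig(prf_hz=20000.0, duration_s=0.004)
kin = MirrorKinematics(11.95, 250.0)
tx = TransducerModel()

phantom = make_cyst_phantom(seed=3)
print(f"speckle phantom: {len(phantom)} scatterers, cavity r=1.5 mm at 17 mm")

x, d = default_image_grid(tx, acq, depth_min_mm=13.5, depth_max_mm=20.5,
                          x_span_mm=5.0)
grid = GridSpec(-2.0, 2.0, -3.0, 3.0, 15.0, 19.0, 0.1)
vol_swept, _ = mirror_swept_volume(phantom, tx, acq, kin, grid,
                                   x_grid_mm=x, depth_grid_mm=d, seed=3)
vol_mech = translation_volume(phantom, tx, acq, x, d, step_mm=0.5, n_steps=13,
                              seed=3)

target = ROI((0.0, 0.0, 17.0), (0.8, 0.8, 0.8))
background = ROI((0.0, 2.4, 17.0), (0.8, 0.8, 0.8))
for name, vol in [("mirror-swept", vol_swept), ("translation ", vol_mech)]:
    rep = cnr(vol, target, background)
    print(f"{name}: CNR {rep.cnr:5.2f}, contrast {rep.contrast_db:5.1f} dB "
          f"(target mean {rep.mean_target:.3g}, background {rep.mean_background:.3g})")
print("Similar CNR on the identical phantom shows the swept-wedge geometry"
      "\ncosts little contrast relative to physically stepping the probe.")
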