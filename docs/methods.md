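# Methods

`tiltscan` models a 3-D ultrasound imaging mode in which a conventional 1-D
linear array fires unfocused (plane-wave) transmissions at a water-immersible
acoustic mirror that tilts sinusoidally at its resonance. Each transmit is
reflected into a different elevational direction, so a wedge-shaped volume is
swept at a rate set by the mirror rather than by any mechanical motion of the
probe. This note records the model, its assumptions, the defaults, and the
numerical choices.

## Timing and kinematics

The round-trip travel time bounds the pulse repetition frequency at
`PRF = c / 2d`; angular compounding with `na` steering angles reduces it to
`PRFe = PRF / na`. The mirror tilt follows

    theta(t) = A sin(2*pi*Fm*t + phi) + gamma     [deg]

and the reflected beam is steered by `alpha = 2*theta` (law of reflection).
Transmit `n` fires at `t_n = n / PRFe`, n = 1, 2, …

The ratio `r = PRFe / Fm` classifies the schedule:

* **condition 1** — `r` an even integer with `(r/pi)*phi` an integer: the
  up- and down-sweeps of one mirror cycle sample the same elevational angles,
  so every location is imaged twice per cycle and one volume is a monotonic
  half-sweep; volume rate `Fv = 2 Fm`.
* **condition 2** — otherwise; the sampled-angle sequence repeats after the
  smallest integer `m` with `m*r` integer, one volume is that repetition
  period, and `Fv = Fm / m`. A multiplier cap (default 64) turns effectively
  non-repeating ratios into an explicit error.

Planes per volume are `Np = PRFe / Fv`, plus one in condition 1 when a
transmit lands exactly on a tilt extremum: that extremal plane bounds two
adjacent half-sweeps and is assigned to both (the only assignment that makes
a 4:1 ratio yield 3 positions per volume). In the flat schedule export the
shared transmit appears once per volume id. Integer/evenness tests on `r` and
on the phase term use a relative tolerance of 1e-9 so ratios such as
1062.5/250 classify robustly. The phase clause is applied literally as
`(r/pi)*phi ∈ Z`; for even `r` this is algebraically equivalent to the
up/down-sweep symmetry of the sampled phase grid, and configurations where an
even ratio fails the phase test are demoted to condition 2 with a warning
rather than silently classified.

Multiplexing trades in-plane quality against the elevational dimension in two
ways. Compounding interleaves `na` steering angles at the full PRF: the
volume rate is unchanged and the distinct elevational positions drop by `na`.
Line-by-line scanning gives each of `nl` beams a whole sweep: positions are
kept and the volume rate becomes `Fv / nl`.

Angles are degrees at every API boundary (radians only inside
trigonometric kernels); phase is normalized to [0, 2*pi). The defaults
(`A = 11.95°`, the mean of a measured +12.6/−11.3° range at a 10-Vpp drive;
`Fm = 250 Hz`; `phi = gamma = 0`; PRF 20 kHz; 2.1-mm transducer-to-mirror
spacing) are the reference operating point shipped in
`tiltscan/data/default.yaml` and give a 500-Hz volume rate, 41 planes per
volume and a 47.8° swept field of view (20.3-mm chord at 25-mm depth). An
asymmetric measured range can instead be mapped to `A = (up+low)/2`,
`gamma = (up−low)/2` via `calibrate.kinematics_from_range`; both readings are
supported because a symmetric sinusoid cannot represent an asymmetric range
with zero offset.

## Acoustic model

The mirror is treated as an ideal planar reflector: imaging at scan angle
`alpha` is a rigid rotation of the scene about the hinge (lateral) axis, with
ranges measured from the mirror plate center and the transducer-to-mirror
path added to all delays. This idealization is deliberate — a flat
high-impedance reflector neither distorts the beam nor changes its amplitude
appreciably — and it keeps the simulator at desk scale.

Scattering is single-bounce point-target: each scatterer returns a
Gaussian-enveloped tone burst (default 3 cycles at 15.625 MHz, 62.5-MHz
sampling) at the plane-wave transmit delay plus the per-element Euclidean
return path; no attenuation, multiple scattering, or element directivity is
modeled. Superposition is therefore exact, which the tests exploit as an
oracle. Optional additive white noise is specified as per-channel SNR in dB
with a recorded seed.

Elevational sensitivity uses a parametric Gaussian beam:
`sigma(z) = sigma0 * sqrt(1 + ((z − zf)/zR)^2)` with the focus `zf = 6 mm`,
focal FWHM 0.5 mm (`sigma0 = FWHM/2.355`), and Rayleigh range
`zR = pi (2 sigma0)^2 / lambda`. The weight of a scatterer at elevational
offset `y` is `exp(−y^2 / 2 sigma(z)^2)`; scatterers beyond 3 sigma are
culled. No numerical beamwidth is asserted anywhere — the model exists to
give depth-dependent elevational resolution with the right shape (narrowest
at the focus, growing roughly linearly beyond it: FWHM ≈ 0.60/0.90/1.27/1.67
mm at 10/15/20/25 mm).

Sound speed defaults to 1480 m/s (water-tank conditions). The RF record is
sized to cover the oblique return path from an edge pixel to the far edge
element, not just the straight two-way path.

## Beamforming

Delay-and-sum on the analytic (Hilbert-transformed) channel signals:
per pixel, the plane-wave transmit arrival plus each element's return path is
sampled by linear interpolation of the complex channel data and summed over
the full aperture (rectangular apodization; Hann and f-number growth are
deliberately absent from the default to keep the point-spread function
analyzable). The envelope is the magnitude of the complex sum, which is exact
at any pixel spacing — an envelope taken by a spatial Hilbert transform of a
sampled image aliases once the axial step approaches a quarter wavelength,
since the two-way fringe period is lambda/2. Coherent compounding sums the
complex beamformed data across steering angles before taking the magnitude,
so it is associative and order-independent by construction. Default pixel
grid: half a wavelength axially, one element pitch laterally.

The mechanical-translation benchmark reuses the same simulator and
beamformer with the scene shifted elevationally in fixed steps at a 0°
scan angle; stacking the envelopes gives the wobbler-style reference volume.

## Scan conversion

A pixel at depth `d` in the plane at scan angle `alpha` sits at Cartesian
`(y, z) = (d sin alpha, d cos alpha)`; `x` is unchanged. The Cartesian grid
(default 0.1-mm isotropic, about one wavelength) is filled by trilinear
interpolation — linear across the angle dimension and bilinear in-plane —
implemented on the rectilinear `(alpha, x, d)` stack. Interpolation is done
in angle, not in sample index: sinusoidal sampling makes plane position a
nonlinear function of time, so index-linear interpolation would be
geometrically wrong. Voxels outside the sampled wedge carry an explicit
invalid mask (serialized alongside every volume) rather than zeros, so
contrast statistics can refuse padding. Frames sharing an angle (the
condition-1 double coverage) are merged before interpolation; the default
policy is averaging (configurable to first/last), which is a noise reduction
with no geometric effect. Reconstruction requires at least two distinct
angles and reproduces constant fields exactly inside the wedge — a property
the tests assert to machine precision.

## Calibration

The sweep calibration emulates tracking the reflected beam acoustically: an
elevational intensity map over time is reduced to per-column beam-peak
positions (argmax with 3-point parabolic refinement; flat columns are marked
missing, never interpolated), converted to scan angles against the known
range and halved to tilt angles. With the drive frequency known, the
sinusoid fit is linear in a sin/cos/constant basis; with it unknown, the
residual is scanned on a 1-Hz grid over a configurable band (default
100–350 Hz, the drive band a resonant mirror of this type is characterized
over) and refined by bounded scalar minimization — a deliberate choice over
a joint nonlinear fit, which can diverge. Amplitude is reported
non-negative with the phase folded accordingly. At 0.2° tracking noise over
10 mirror periods (80 samples per period), 100 seeded trials recover the
amplitude and offset within 0.1° and the frequency within 0.5 Hz in every
trial. Drive characterization is ordinary least squares for voltage-to-angle
linearity and a 3-point parabolic vertex for the resonance peak; monotone
responses return the band edge with a warning instead of a fabricated peak.

## Image quality metrics

CNR is `|mean_t − mean_b| / sqrt(var_t + var_b)` computed **on linear
envelope intensities**; variance semantics break on log-compressed data, so
dB images are never accepted. Contrast is additionally reported as
`20 log10` of the larger-to-smaller mean ratio (a convention choice; for
anechoic targets this is background over target). ROIs are axis-aligned
boxes in millimetres and must lie entirely inside valid voxels. FWHM locates
half-maximum crossings by linear interpolation on either side of the highest
peak and raises "unresolved" when a side never falls below half. RMS
intensity supports optional low-pass filtering and window-power-normalized
windowing (so a constant signal keeps RMS |c|).

## What the synthetic data does and does not show

The wire phantom (dense scatterer lines, 3-mm elevational spacing,
optional per-wire depth jitter) and the speckle block with spherical
anechoic cavities (Poisson scatterer count, Rayleigh amplitudes of unit
mean, default 30 /mm^3 — several scatterers per resolution cell once the
elevational beam width is accounted for) reproduce the *geometry* and
*first/second-order statistics* that the reconstruction and metrics consume.
They do not model attenuation, sound-speed heterogeneity, reverberation,
element directivity, or the real transducer's bandwidth, so passing tests
demonstrate correctness of scheduling, geometry, interpolation and
statistics — not absolute dB values of any physical phantom. Measured
contrast/CNR tables from physical experiments are accordingly not treated
as numeric targets; the simulated check is *parity* between the mirror-swept
and translation modes on identical phantoms and seeds (observed: CNR 1.18 vs
1.07, ~10% apart, with matched ROIs).

## Problem sizes

The shipped tests and examples use desk-scale scenes chosen as the smallest
that still exercise every code path with realistic sampling: wires spanning
±2 mm laterally discretized at about half a wavelength, a 5×7×5-mm speckle
block, 41-plane volumes at the 80:1 PRF/Fm ratio, and a 13-step × 0.5-mm
translation benchmark. The full end-to-end suite runs in about a minute on
one CPU.

## Known limitations

* No synthetic-aperture elevational refocusing; elevational resolution is
  whatever the fixed lens model gives.
* The mirror fold is a pure rotation: finite mirror size, edge diffraction
  and multiple reflections are out of scope.
* Scan conversion assumes a static scene within one volume (no motion
  compensation between planes).
* Compounding steering angles default to (−2°, 0°, +2°); the set is
  configurable and nothing asserts a particular choice.
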