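# Reference operating profile: 15.625-MHz 128-element linear array over a
# 250-Hz resonant tilting mirror, single plane-wave transmit at 20-kHz PRF
# (500-Hz volume rate).  Tilt amplitude is the mean of the measured
# +12.6/-11.3 degree half-ranges at the 10-Vpp drive; the tilt offset is 0.
acquisition:
  sound_speed_mps: 1480.0
  imaging_depth_mm: 28.6
  prf_hz: 20000.0
  n_compound_angles: 1
  n_scan_lines: 1
  mirror_offset_mm: 2.1
  duration_s: 0.008
mirror:
  half_range_deg: 11.95
  tilt_freq_hz: 250.0
  phase_rad: 0.0
  offset_deg: 0.0
transducer:
  n_elements: 128
  pitch_mm: 0.1
  center_freq_mhz: 15.625
  sampling_freq_mhz: 62.5
  pulse_cycles: 3.0
  elevational_focus_mm: 6.0
  elevational_fwhm_mm: 0.5
phantom:
  type: wire
  n_wires: 4
  spacing_mm: 3.0
  depth_mm: 15.0
  x_extent_mm: 4.0
reconstruction:
  spacing_mm: 0.1
  dyn_range_db: 40.0
seed: 0
output_dir: runs
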