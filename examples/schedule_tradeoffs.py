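"""Volume-rate vs elevational-sampling tradeoff of a mirror-swept sequence.

For a 250-Hz resonant mirror, different pulse repetition frequencies put
the schedule in different regimes: an even integer PRF/Fm ratio images
every elevational position twice per mirror cycle (one volume per
half-sweep, rate 2*Fm), while a non-integer ratio repeats only after m
mirror cycles (rate Fm/m) but visits more distinct positions.
"""

from tiltscan import MirrorKinematics, fov_extent, planes_per_volume, volume_rate

kin = MirrorKinematics(half_range_deg=11.95, tilt_freq_hz=250.0)

print(f"{'PRF (Hz)':>10} {'ratio':>7} {'regime':>11} {'m':>3} "
      f"{'Fv (Hz)':>8} {'planes/vol':>10}")
for prf in (1000.0, 1125.0, 1062.5, 4500.0, 20000.0):
    rate = volume_rate(prf, kin)
    n_p = planes_per_volume(prf, rate)
    print(f"{prf:>10g} {rate.ratio:>7.3g} {rate.regime:>11} "
          f"{rate.multiplier_m:>3d} {rate.volume_rate_hz:>8g} {n_p:>10d}")

angle, chord = fov_extent(25.0, kin)
print(f"\nSwept field of view: {angle:.1f} deg ({chord:.1f} mm chord at 25 mm"
      " depth)")
print("Higher PRF -> more planes per volume at the same rate; a fractional"
      "\nPRF/Fm ratio trades volume rate for finer elevational sampling.")
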