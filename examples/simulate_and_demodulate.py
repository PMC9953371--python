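"""Synthesize a radar return and recover the chest-motion phase.

Builds a noiseless quadrature record for a subject breathing at 15 BPM
with a 72 BPM heartbeat, demodulates it with the four-quadrant arctangent,
and compares the recovered phase against the synthesis ground truth.  Also
prints the quarter-wavelength null-point geometry of the 2.4 GHz carrier.
"""

import numpy as np

from sdrvitals import (
    NoiseSpec,
    RadarConfig,
    VitalProfile,
    arctan_demodulate,
    null_point_positions,
    synthesize_quadrature,
)

config = RadarConfig()
profile = VitalProfile(rr_bpm=15, hr_bpm=72)

record = synthesize_quadrature(config, profile, NoiseSpec(seed=0), duration=30.0)
phase = arctan_demodulate(record)

residual = phase.phase_samples - record.truth_phase
residual -= 2 * np.pi * np.round(residual[0] / (2 * np.pi))
rms = np.sqrt(np.mean(residual**2))

nulls = null_point_positions(config, max_distance=0.5)

print(f"wavelength:            {config.wavelength * 100:.1f} cm")
print(f"null-point spacing:    {nulls.spacing * 100:.3f} cm "
      f"({len(nulls.positions)} nulls inside 0.5 m)")
print(f"range phase theta:     {config.range_phase:.3f} rad at d0 = {config.distance} m")
print(f"phase excursion:       {np.ptp(phase.phase_samples):.3f} rad peak-to-peak")
print(f"reconstruction RMS:    {rms:.2e} rad")
# The RMS residual is numerical noise only: with both quadrature channels
# the arctangent recovers the modulated phase exactly, at any distance.
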