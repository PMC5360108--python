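"""Estimate a traveling front's propagation speed.

Programs a sharp net-excitation front crossing the full 464-channel
aperture at 0.2 mm/ms, then recovers the speed with the amplitude-level
position-vs-time regression: values above the interval mean are split
into 10 levels, the farthest channel at or above each level is tracked
per frame, and a single least-squares fit of distance on time gives the
velocity and its significance.
"""

import numpy as np

import vsd_spacetime as vs

geometry = vs.build_hex_geometry(464, 0.18)
origin = geometry.pos[np.argmin(geometry.pos[:, 1])]  # peripheral start
reach = geometry.distances_from(origin).max()

waves = (vs.WaveSpec(origin=tuple(origin), onset_ms=150.0, sign=1,
                     temporal_width_ms=3.0, speed_mm_per_ms=0.2,
                     spatial_decay_mm=50.0, peak_amplitude=4e-4),)
dataset = vs.compose_dataset(geometry, conditions={"front": waves},
                             n_trials=10, seed=0, gain_log_sd=0.0)
_, deriv = vs.preprocess(dataset.recordings["front"], dataset.blank,
                         sigma_ms=5.0)

estimate = vs.estimate_speed(
    deriv, geometry, interval_ms=(150.0, 150.0 + (reach - 0.9) / 0.2),
    origin=origin, polarity="nex")

print(f"programmed speed: 0.200 mm/ms over a {reach:.1f} mm path")
print(f"estimated speed:  {estimate.speed_mm_per_ms:.3f} mm/ms "
      f"(p = {estimate.p_value:.1e}, {estimate.n_points} level points)")
print(f"propagating: {estimate.propagating}")
# The estimate lands within a few percent of the programmed speed, inside
# the 0.08-0.4 mm/ms range typical of cortical net-excitation fronts.
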