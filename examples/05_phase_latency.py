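"""Phase-latency maps and the delay between visual areas.

The analytic-signal (Hilbert) phase turns a single snapshot of the wave
into a per-channel latency map in ms.  Here channels in areas 19/21 carry
the same waveform as areas 17/18 delayed by 8 ms; the inter-area latency
difference recovers that lag directly from the phases.
"""

import numpy as np

import vsd_spacetime as vs
from vsd_spacetime.preprocessing import gaussian_smooth

geometry = vs.build_hex_geometry(169, 0.18)
late = np.isin(geometry.area, (19, 21))

n = 800  # 500 ms window
t = np.arange(n) / 1.6
omega = 2 * np.pi * 10.0 / 1000.0  # 10 Hz
signal = 1e-3 * np.cos(omega * (t[None, :]
                                - np.where(late, 8.0, 0.0)[:, None]))
noise = vs.generate_baseline(geometry, 10, n / 1.6, 1600.0,
                             vs.BaselineParams(), seed=0).mean(axis=0)
field = gaussian_smooth(signal + noise, 12.0, 1600.0)

z = vs.analytic_signal(field)
phase_map = vs.phase_latency_map(z, 1600.0, eval_index=n // 2)
delay = vs.inter_area_delay(phase_map, geometry)

print(f"reference (earliest) channel: {phase_map.reference_channel}")
print(f"latency range: {np.nanmin(phase_map.latency_ms):.2f} .. "
      f"{np.nanmax(phase_map.latency_ms):.2f} ms")
print(f"areas 17/18 -> 19/21 delay: {delay:.2f} ms (programmed 8.00 ms)")
# The recovered inter-area delay matches the programmed lag to a fraction
# of a sample; phase latency is amplitude-free, so uneven staining or
# illumination does not bias it.
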