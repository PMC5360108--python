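"""Analytic-signal phase, latency maps and inter-area delays.

If the whole monitored cortex carries one wave of net excitation (or net
inhibition), positions reached later sit at a lagging phase.  The analytic
signal z(x, t) — the recorded signal plus i times its Hilbert transform —
turns each channel's time course into an instantaneous phase
theta(x, t) = atan2(Im z, Re z).  Evaluated at one moment inside a short
analysis window (100 ms by default), the phase differences to the earliest
channel x0, divided by the instantaneous angular frequency at x0, give a
per-channel latency map in ms.  Averaging the map over two groups of
channels and differencing yields an inter-area delay, tested against zero
across replicates with a one-sample t-test.

Numerical notes: the principal-value integral defining the Hilbert
transform is realized by the standard discrete frequency-domain analytic
signal; the per-channel window mean is removed first to avoid the DC
singularity.  Phase differences are wrapped into (-pi, pi] before
conversion, and latencies beyond half a period of the reference channel are
ambiguous and flagged.  The conversion from radians to ms uses the
instantaneous frequency of the reference channel — exact for narrowband
signals, an approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import hilbert

from .geometry import HexGeometry

__all__ = [
    "PhaseMap", "analytic_signal", "phase_latency_map", "inter_area_delay",
    "inter_area_delay_test", "normalize_vsd", "InterAreaDelay",
]

DEFAULT_AREA_PAIR = ((17, 18), (19, 21))


def _wrap(angle: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.pi - np.mod(np.pi - angle, 2.0 * np.pi)


def analytic_signal(field, window=None, min_samples: int = 64) -> np.ndarray:
    """Complex analytic signal per channel over a time window.

    ``field`` is channels x time (or a single time series); ``window`` a
    (start, stop) sample pair (default: the full record).  The per-channel
    mean over the window is removed before the transform.
    """
    field = np.atleast_2d(np.asarray(field, dtype=float))
    if window is None:
        window = (0, field.shape[1])
    start, stop = int(window[0]), int(window[1])
    seg = field[:, start:stop]
    if seg.shape[1] < min_samples:
        raise ValueError(
            f"analysis window has {seg.shape[1]} samples; need >= {min_samples}"
        )
    seg = seg - seg.mean(axis=1, keepdims=True)
    return hilbert(seg, axis=1)


@dataclass
class PhaseMap:
    """Instantaneous phase and per-channel latency relative to the earliest
    channel."""

    theta: np.ndarray          # channels x window-time phase (radians)
    latency_ms: np.ndarray     # per channel; 0 at the reference; NaN undefined
    reference_channel: int
    eval_index: int            # sample inside the window where phase was read
    ambiguous: np.ndarray      # True where |latency| exceeds half a period
    angular_frequency: float   # rad/ms at the reference channel


def phase_latency_map(
    z: np.ndarray, sampling_rate_hz: float, eval_index: int
) -> PhaseMap:
    """Latency map from the analytic signal, in ms.

    The reference channel x0 is the one with the largest phase advance at
    ``eval_index`` (phases compared circularly about their mean);
    per-channel latency is the wrapped phase difference to x0 divided by the
    instantaneous angular frequency of x0.  ``eval_index`` must lie in the
    central half of the window, away from transform edge effects.
    """
    z = np.atleast_2d(np.asarray(z))
    n_ch, n_t = z.shape
    if not n_t // 4 <= eval_index < 3 * n_t // 4:
        raise ValueError("eval_index must lie in the central half of the window")
    dt_ms = 1000.0 / sampling_rate_hz

    theta = np.angle(z)
    amp = np.abs(z[:, eval_index])
    dead = amp <= 1e-12 * max(np.max(amp), 1e-300)

    phi = theta[:, eval_index]
    mean_dir = np.angle(np.mean(np.exp(1j * phi[~dead])))
    delta = _wrap(phi - mean_dir)  # phase advance about the circular mean
    delta = np.where(dead, np.nan, delta)
    ref = int(np.nanargmax(delta))

    unwrapped = np.unwrap(theta[ref])
    omega = float(np.gradient(unwrapped, dt_ms)[eval_index])  # rad/ms
    if omega <= 0:
        raise ValueError(
            "instantaneous frequency of the reference channel is not "
            "positive at eval_index; choose a different evaluation time"
        )
    lag = _wrap(delta[ref] - delta)
    latency = lag / omega
    # wrapping bounds |latency| by half a period; differences close to +-pi
    # may have wrapped a full cycle and are flagged as unresolvable
    ambiguous = np.abs(lag) > 0.9 * np.pi
    latency = np.where(dead, np.nan, latency)
    return PhaseMap(theta=theta, latency_ms=latency, reference_channel=ref,
                    eval_index=int(eval_index), ambiguous=ambiguous,
                    angular_frequency=omega)


def inter_area_delay(
    phase_map: PhaseMap,
    geometry: HexGeometry,
    area_pair=DEFAULT_AREA_PAIR,
    min_channels: int = 3,
) -> float:
    """Mean latency of the second area group minus the first, in ms.

    ``area_pair`` is a pair of area-label groups, by default
    ((17, 18), (19, 21)); swapping the pair negates the delay exactly.
    """
    means = []
    for areas in area_pair:
        idx = geometry.area_channels(areas)
        lat = phase_map.latency_ms[idx]
        lat = lat[np.isfinite(lat)]
        if lat.size < min_channels:
            raise ValueError(
                f"area group {areas} has {lat.size} channels with defined "
                f"latency; need >= {min_channels}"
            )
        means.append(float(lat.mean()))
    return means[1] - means[0]


@dataclass(frozen=True)
class InterAreaDelay:
    delays_ms: np.ndarray
    mean_ms: float
    t_statistic: float
    p_value: float
    n: int


def inter_area_delay_test(delays_ms) -> InterAreaDelay:
    """One-sample t-test of per-replicate inter-area delays against zero."""
    delays = np.asarray(delays_ms, dtype=float)
    delays = delays[np.isfinite(delays)]
    if delays.size < 2:
        raise ValueError("need >= 2 replicate delays for the t-test")
    res = stats.ttest_1samp(delays, popmean=0.0)
    return InterAreaDelay(delays_ms=delays, mean_ms=float(delays.mean()),
                          t_statistic=float(res.statistic),
                          p_value=float(res.pvalue), n=delays.size)


def normalize_vsd(signal, post_window) -> tuple[np.ndarray, np.ndarray]:
    """Divide each channel by its own post-stimulus maximum (nVSD).

    Removes amplitude differences while preserving phase relations and
    per-channel peak times exactly.  Channels whose post-window maximum is
    not positive cannot be normalized; they come back NaN with a False entry
    in the validity mask.  Returns ``(normalized, valid)``.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    start, stop = int(post_window[0]), int(post_window[1])
    vmax = signal[:, start:stop].max(axis=1)
    valid = vmax > 0
    out = np.full_like(signal, np.nan)
    out[valid] = signal[valid] / vmax[valid, None]
    return out, valid
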