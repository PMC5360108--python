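"""Wavefront propagation speed by amplitude-level position-time regression.

The estimator tracks how far successive amplitude levels of the derivative
field travel from an origin over time.  Within a region of interest and a
time interval, the interval mean d-bar of the field is computed; the value
range above d-bar is split into 10 equal-width amplitude levels; for every
level and every time frame the distance (from the origin) of the farthest
channel at or above that level's lower edge is recorded; and a single
ordinary-least-squares fit of distance on time over the pooled points gives
the speed in mm/ms with its significance (threshold p < 0.01).  Because the
levels are defined relative to d-bar and the running maximum, the estimate
is invariant to positive affine rescaling of the field, and the front need
not progress with constant amplitude or velocity.

Net-inhibition fronts are handled by negating the field first (polarity
``"ninh"``), so a NINH estimate on a field equals a NEX estimate on its
negative.  A spatially synchronous activation has no ordered level
progression: its regression is either non-significant or absurdly steep,
and the estimate is flagged non-propagating (slope above 5 mm/ms, far
beyond the 0.08-0.4 mm/ms physiological range, or p >= 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import HexGeometry
from .preprocessing import DerivativeField

__all__ = ["SpeedEstimate", "estimate_speed"]


@dataclass(frozen=True)
class SpeedEstimate:
    speed_mm_per_ms: float
    stderr: float
    p_value: float
    n_points: int
    polarity: str
    interval_ms: tuple
    propagating: bool
    points: pd.DataFrame  # columns level, time_ms, distance_mm


def estimate_speed(
    deriv: DerivativeField,
    geometry: HexGeometry,
    interval_ms: tuple,
    origin,
    roi_channels=None,
    polarity: str = "nex",
    n_levels: int = 10,
    significance: float = 0.01,
    max_speed_mm_per_ms: float = 5.0,
) -> SpeedEstimate:
    """Estimate the propagation speed of a NEX or NINH front.

    Parameters
    ----------
    interval_ms : (start, stop) in ms relative to stimulus onset.
    origin : (x, y) in mm or a channel id; distances are measured from here.
        The natural default is the location of the first significantly
        net-excited channel (see the event table).
    roi_channels : channel ids covering the progress of the front
        (default: all channels); at least 5.
    polarity : ``"nex"`` tracks increases, ``"ninh"`` negates the field first.
    """
    if polarity not in ("nex", "ninh"):
        raise ValueError("polarity must be 'nex' or 'ninh'")
    if roi_channels is None:
        roi_channels = np.arange(deriv.n_channels)
    roi_channels = np.asarray(roi_channels, dtype=int)
    if roi_channels.size < 5:
        raise ValueError("ROI must contain at least 5 channels")

    i0, i1 = deriv.index_at(interval_ms[0]), deriv.index_at(interval_ms[1])
    i0, i1 = max(i0, 0), min(i1, deriv.n_times)
    if i1 - i0 < 10:
        raise ValueError("interval must span at least 10 samples")

    field = deriv.values[np.ix_(roi_channels, np.arange(i0, i1))]
    if polarity == "ninh":
        field = -field
    dbar = field.mean()
    vmax = field.max()
    if vmax <= dbar:
        raise ValueError("no wavefront in ROI/interval: no values above the "
                         "interval mean")

    edges = np.linspace(dbar, vmax, n_levels + 1)[:-1]
    dist = geometry.distances_from(origin)[roi_channels]
    times = deriv.times_ms[i0:i1]

    recs = []
    for level, edge in enumerate(edges):
        above = field >= edge  # channels x frames
        for j in np.flatnonzero(above.any(axis=0)):
            d = dist[above[:, j]].max()
            recs.append((level, times[j], d))
    points = pd.DataFrame(recs, columns=["level", "time_ms", "distance_mm"])
    if len(points) < 3:
        raise ValueError("fewer than 3 regression points; cannot estimate speed")
    if points["time_ms"].nunique() < 2:
        raise ValueError("wavefront points collapse onto a single time frame")
    if np.ptp(points["distance_mm"].to_numpy()) == 0.0:
        # synchronous activation: every level is everywhere at once, the
        # "front" never moves -- nothing propagates
        return SpeedEstimate(
            speed_mm_per_ms=0.0, stderr=0.0, p_value=1.0,
            n_points=len(points), polarity=polarity,
            interval_ms=(float(interval_ms[0]), float(interval_ms[1])),
            propagating=False, points=points,
        )

    fit = stats.linregress(points["time_ms"], points["distance_mm"])
    speed = float(fit.slope)
    propagating = bool(fit.pvalue < significance
                       and 0.0 < speed <= max_speed_mm_per_ms)
    return SpeedEstimate(
        speed_mm_per_ms=speed, stderr=float(fit.stderr),
        p_value=float(fit.pvalue), n_points=len(points), polarity=polarity,
        interval_ms=(float(interval_ms[0]), float(interval_ms[1])),
        propagating=propagating, points=points,
    )
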