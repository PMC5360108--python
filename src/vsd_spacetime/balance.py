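"""Delayed-balance statistics: E(NEX), E(NINH), their regression, delays.

The delayed-balance claim is quantitative: at each cortical spot the amount
of net excitation accumulated over the post-stimulus period is matched by an
equal amount of net inhibition arriving ~125 ms later.  Three measurements
carry it:

* ``time_average_events`` — per channel, the mean of dVSD/dt over the samples
  where NEX (respectively NINH) is defined within the 0-800 ms window;
* ``balance_regression`` — ordinary least squares of |E(NINH)| on E(NEX)
  across channels; a slope of 1 means excitation balanced by an equal amount
  of inhibition (the absolute value makes the slope read as a magnitude
  ratio);
* ``delay_statistics`` — per channel, t(NINHmin) - t(NEXmax) wherever both
  events are defined, with the condition mean and SD.  Delays are reported
  raw; negative values at noisy pixels are kept, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detection import NEX, NINH, NexNinhClassification
from .preprocessing import DerivativeField

__all__ = [
    "BalanceRegression", "DelayStats", "time_average_events",
    "balance_regression", "delay_statistics",
]

DEFAULT_WINDOW_MS = (0.0, 800.0)


@dataclass(frozen=True)
class BalanceRegression:
    slope: float
    intercept: float
    r: float
    p_value: float
    n_channels: int


@dataclass(frozen=True)
class DelayStats:
    delays_ms: np.ndarray  # per channel, NaN where undefined
    mean_ms: float
    sd_ms: float
    n_channels: int


def time_average_events(
    classification: NexNinhClassification,
    deriv: DerivativeField,
    window_ms: tuple = DEFAULT_WINDOW_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel E(NEX) and E(NINH) over a post-stimulus window.

    E(NEX) is the sum of dVSD/dt over NEX-labeled samples divided by the
    number of such samples — the mean over the intervals where net excitation
    is defined — and likewise E(NINH); NaN where a channel has no labeled
    sample in the window.  Unlabeled samples never contribute.
    ``classification`` may also be a bare channels x time label array.
    """
    labels = getattr(classification, "labels", classification)
    times = deriv.times_ms
    in_window = (times >= window_ms[0]) & (times < window_ms[1])
    e = {}
    for name, label in (("nex", NEX), ("ninh", NINH)):
        mask = (labels == label) & in_window[None, :]
        count = mask.sum(axis=1)
        total = np.where(mask, deriv.values, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            e[name] = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return e["nex"], e["ninh"]


def balance_regression(e_nex: np.ndarray, e_ninh: np.ndarray) -> BalanceRegression:
    """OLS of |E(NINH)| on E(NEX) across channels with both defined.

    Returns slope, intercept, Pearson r and the regression significance
    (for simple OLS the slope t-test and the model F-test coincide).
    """
    e_nex = np.asarray(e_nex, dtype=float)
    e_ninh = np.asarray(e_ninh, dtype=float)
    ok = np.isfinite(e_nex) & np.isfinite(e_ninh)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 channels with both events defined, got {n}")
    x = e_nex[ok]
    y = np.abs(e_ninh[ok])
    if np.ptp(x) == 0:
        raise ValueError("E(NEX) has zero variance across channels; "
                         "slope undefined")
    fit = stats.linregress(x, y)
    return BalanceRegression(slope=float(fit.slope),
                             intercept=float(fit.intercept),
                             r=float(fit.rvalue), p_value=float(fit.pvalue),
                             n_channels=n)


def delay_statistics(events: pd.DataFrame) -> DelayStats:
    """Per-channel NEXmax -> NINHmin delay map with condition mean and SD.

    ``events`` is the table from :func:`~vsd_spacetime.detection.extract_events`.
    The SD uses ddof=1 and is reported as 0 when a single channel defines the
    delay (n = 1 is visible in ``n_channels``); an empty result (no channel
    with both events) comes back with n = 0 and NaN summaries.
    """
    delays = (events["t_ninhmin_ms"] - events["t_nexmax_ms"]).to_numpy(float)
    ok = np.isfinite(delays)
    n = int(ok.sum())
    if n == 0:
        return DelayStats(delays_ms=delays, mean_ms=np.nan, sd_ms=np.nan,
                          n_channels=0)
    mean = float(np.mean(delays[ok]))
    sd = float(np.std(delays[ok], ddof=1)) if n > 1 else 0.0
    return DelayStats(delays_ms=delays, mean_ms=mean, sd_ms=sd, n_channels=n)
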