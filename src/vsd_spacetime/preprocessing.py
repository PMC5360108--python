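"""From raw trials to the averaged, filtered VSD(t) and its derivative.

The fixed order of operations is: blank subtraction and division by the
background fluorescence (dF/F0), trial averaging (8-12 trials by default),
temporal Gaussian smoothing (sigma = 40 ms, robust down to 12 ms), and the
temporal derivative.  The derivative field dVSD(t)/dt, in dF/F0 per ms, is
what every balance statistic downstream consumes: it is proportional to the
summed membrane currents of the imaged compartment, so significant positive
and negative excursions read as net excitation and net inhibition.

Numerical choices: central differences (zero phase lag, which the delay
estimates rely on) with one-sided differences at the record ends; smoothing
by a unit-sum Gaussian kernel truncated at +-4 sigma with reflection at the
edges, so the signal mean is preserved and stimulus-onset transients are not
smeared into artificial edge ramps.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .recording import VSDRecording

__all__ = [
    "DerivativeField", "fractional_fluorescence", "to_fractional",
    "average_trials", "gaussian_smooth", "temporal_derivative", "preprocess",
]

DEFAULT_SIGMA_MS = 40.0
DEFAULT_N_TRIALS_AVERAGED = 10  # within the 8-12 range used experimentally


@dataclass
class DerivativeField:
    """channels x time dVSD(t)/dt in dF/F0 per ms, with provenance."""

    values: np.ndarray
    sampling_rate_hz: float
    stimulus_onset_index: int
    condition: str = ""
    sigma_ms: float = DEFAULT_SIGMA_MS
    n_trials_averaged: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be channels x time")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_times) - self.stimulus_onset_index) * self.dt_ms

    def index_at(self, time_ms: float) -> int:
        """Nearest sample index to a time given in ms relative to onset."""
        return int(round(self.stimulus_onset_index
                         + time_ms * self.sampling_rate_hz / 1000.0))


def fractional_fluorescence(stim_trials, blank_trials, f0) -> np.ndarray:
    """Per-trial dF/F0: (stim - mean over blank trials) / F0.

    ``stim_trials`` and ``blank_trials`` are trials x channels x time on the
    same time axis; ``f0`` is the per-channel background fluorescence.
    """
    stim = np.asarray(stim_trials, dtype=float)
    blank = np.asarray(blank_trials, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if stim.shape[1:] != blank.shape[1:]:
        raise ValueError("stimulus and blank trials must share channel/time axes")
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        raise ValueError(f"non-positive background F0 on channels {bad.tolist()}")
    return (stim - blank.mean(axis=0, keepdims=True)) / f0[None, :, None]


def to_fractional(stim: VSDRecording, blank: VSDRecording) -> VSDRecording:
    """Recording-level wrapper around :func:`fractional_fluorescence`."""
    if stim.background_f0 is None:
        raise ValueError("raw recording lacks background_f0")
    values = fractional_fluorescence(stim.values, blank.values, stim.background_f0)
    out = stim.with_values(values, signal_kind="fractional")
    out.background_f0 = None
    return out


def average_trials(trials, subset=None) -> np.ndarray:
    """Arithmetic mean over the trial axis -> channels x time VSD(t).

    ``subset`` selects trial indices; the default takes the first
    ``DEFAULT_N_TRIALS_AVERAGED`` trials (or all, if fewer), a deterministic
    stand-in for the experimenter's hand-picked 8-12 artifact-free trials.
    """
    trials = np.asarray(trials, dtype=float)
    if subset is None:
        subset = np.arange(min(trials.shape[0], DEFAULT_N_TRIALS_AVERAGED))
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("trial subset is empty")
    return trials[subset].mean(axis=0)


def gaussian_smooth(signal, sigma_ms: float, sampling_rate_hz: float) -> np.ndarray:
    """Temporal Gaussian filter along the last axis.

    Unit-sum kernel truncated at +-4 sigma, reflection at the edges;
    ``sigma_ms = 0`` is the identity.
    """
    signal = np.asarray(signal, dtype=float)
    if sigma_ms < 0:
        raise ValueError("sigma_ms must be >= 0")
    if sigma_ms == 0:
        return signal.copy()
    sigma_samples = sigma_ms * sampling_rate_hz / 1000.0
    if sigma_samples > signal.shape[-1] / 2:
        warnings.warn(
            "filter sigma exceeds half the record length; the result is "
            "dominated by edge reflection", stacklevel=2,
        )
    return gaussian_filter1d(signal, sigma_samples, axis=-1, mode="reflect",
                             truncate=4.0)


def temporal_derivative(signal, sampling_rate_hz: float) -> np.ndarray:
    """Temporal derivative along the last axis, in signal units per ms.

    Central differences in the interior, one-sided at the ends (exact on
    affine signals everywhere); output has the same length as the input.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] < 3:
        raise ValueError("need at least 3 time samples to differentiate")
    dt_ms = 1000.0 / sampling_rate_hz
    return np.gradient(signal, dt_ms, axis=-1)


def preprocess(
    stim: VSDRecording,
    blank: VSDRecording,
    sigma_ms: float = DEFAULT_SIGMA_MS,
    subset=None,
) -> tuple[np.ndarray, DerivativeField]:
    """Full pipeline raw trials -> (filtered VSD(t), dVSD(t)/dt).

    Returns the channels x time filtered average and the derivative field.
    """
    frac = fractional_fluorescence(stim.values, blank.values, stim.background_f0)
    vsd = average_trials(frac, subset=subset)
    n_avg = len(subset) if subset is not None else min(
        stim.n_trials, DEFAULT_N_TRIALS_AVERAGED
    )
    vsd = gaussian_smooth(vsd, sigma_ms, stim.sampling_rate_hz)
    deriv = temporal_derivative(vsd, stim.sampling_rate_hz)
    return vsd, DerivativeField(
        values=deriv, sampling_rate_hz=stim.sampling_rate_hz,
        stimulus_onset_index=stim.stimulus_onset_index,
        condition=stim.condition, sigma_ms=sigma_ms, n_trials_averaged=n_avg,
    )
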