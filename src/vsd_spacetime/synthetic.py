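"""Ground-truthed synthetic VSD datasets.

Real recordings of this kind are not publicly deposited, so the analysis is
exercised on a generator that emulates their statistical structure:

* a single-compartment conductance model whose membrane-potential derivative
  is the sum of ionic currents over the specific capacitance — the biophysical
  rationale for reading dVSD(t)/dt as the instantaneous excitation-inhibition
  balance;
* spatio-temporally correlated Ornstein-Uhlenbeck baseline noise standing in
  for the small "tight balance" fluctuations of the pre-stimulus cortex;
* programmable traveling net-excitation (NEX) waves followed, after a
  configurable ~125 ms delay, by matched net-inhibition (NINH) waves radiating
  from the two retinotopic CFOV representations (areas 17/18 and 19/21, the
  second lagging the first by a configurable ~8 ms);
* composition into raw-fluorescence trials F0 * (1 + signal + noise) per
  condition, plus a blank (noise-only) condition, with a GroundTruth record
  sufficient to reconstruct every programmed quantity.

Every generator takes an explicit seed or numpy Generator; there is no hidden
global random state, and a fixed seed reproduces a dataset bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
from scipy.signal import lfilter

from .geometry import HexGeometry, cfov_centers
from .recording import VSDRecording

__all__ = [
    "ConductanceTransient", "IonChannel", "ConductanceParams",
    "simulate_compartment_vm", "WaveSpec", "generate_wave_field",
    "BaselineParams", "generate_baseline", "GroundTruth", "SyntheticDataset",
    "default_conditions", "compose_dataset", "write_dataset", "read_ground_truth",
]


# --------------------------------------------------------------------------
# Single-compartment conductance model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductanceTransient:
    """A stimulus-locked conductance excursion (double-exponential).

    g(t) = peak * h(t - onset) where h rises with time constant ``rise_tau_ms``
    and decays with ``decay_tau_ms``, normalized so its maximum is 1.
    """

    onset_ms: float
    rise_tau_ms: float
    decay_tau_ms: float
    peak: float  # mS/cm^2

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        if self.rise_tau_ms <= 0 or self.decay_tau_ms <= 0:
            raise ValueError("transient time constants must be positive")
        s = np.asarray(t_ms, dtype=float) - self.onset_ms
        h = np.where(
            s > 0,
            (1.0 - np.exp(-np.maximum(s, 0.0) / self.rise_tau_ms))
            * np.exp(-np.maximum(s, 0.0) / self.decay_tau_ms),
            0.0,
        )
        # peak of (1-exp(-s/r))exp(-s/d) sits at s* = r*log(1 + d/r)
        s_star = self.rise_tau_ms * np.log1p(self.decay_tau_ms / self.rise_tau_ms)
        h_max = (1.0 - np.exp(-s_star / self.rise_tau_ms)) * np.exp(
            -s_star / self.decay_tau_ms
        )
        return self.peak * h / h_max


@dataclass(frozen=True)
class IonChannel:
    """Reversal potential (mV) and conductance time course (mS/cm^2)."""

    reversal_mv: float
    baseline: float
    transient: ConductanceTransient | None = None

    def conductance(self, t_ms: np.ndarray) -> np.ndarray:
        g = np.full_like(np.asarray(t_ms, dtype=float), self.baseline)
        if self.transient is not None:
            g = g + self.transient.waveform(t_ms)
        if np.any(g < 0):
            raise ValueError("conductance must stay non-negative")
        return g


@dataclass(frozen=True)
class ConductanceParams:
    """Parameters of the one-compartment membrane model.

    The membrane obeys  dVm/dt = -(1/Cm) * sum_x g_x(t) (Vm - E_x)  over the
    four ionic species Na+, Ca2+, Cl- and K+.  The dye signal derivative is
    dVSD/dt = k * dVm/dt with the dimensionless proportionality ``k``.
    Units: Cm in uF/cm^2, g in mS/cm^2, E in mV, so dVm/dt is in mV/ms.
    """

    cm: float = 1.0
    k: float = 1.0e-5
    channels: dict = field(default_factory=lambda: {
        "Na": IonChannel(reversal_mv=50.0, baseline=0.3),
        "Ca": IonChannel(reversal_mv=120.0, baseline=0.02),
        "Cl": IonChannel(reversal_mv=-70.0, baseline=0.6),
        "K": IonChannel(reversal_mv=-90.0, baseline=0.4),
    })

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise ValueError("Cm must be positive")
        v_rest = self.steady_state_vm(0.0)
        for name in ("Na", "Ca"):
            if self.channels[name].reversal_mv <= v_rest:
                raise ValueError(f"E_{name} must exceed the resting Vm")
        for name in ("Cl", "K"):
            if self.channels[name].reversal_mv >= v_rest:
                raise ValueError(f"E_{name} must be below the resting Vm")

    def steady_state_vm(self, t_ms: float) -> float:
        """Conductance-weighted mean of the reversal potentials at time t."""
        g = np.array([c.conductance(np.asarray([t_ms]))[0]
                      for c in self.channels.values()])
        e = np.array([c.reversal_mv for c in self.channels.values()])
        return float(np.sum(g * e) / np.sum(g))


def simulate_compartment_vm(
    params: ConductanceParams, duration_ms: float, dt_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-integrate the compartment membrane potential.

    Explicit (forward Euler) integration with step ``dt_ms``; the initial
    condition is the analytic steady state of the baseline conductances.
    Returns ``(t_ms, vm_mv)``.  A step changing Vm by more than 50 mV aborts
    with a suggestion to reduce ``dt_ms``.
    """
    if duration_ms <= 0 or dt_ms <= 0:
        raise ValueError("duration_ms and dt_ms must be positive")
    t = np.arange(0.0, duration_ms + 0.5 * dt_ms, dt_ms)
    g = {name: ch.conductance(t) for name, ch in params.channels.items()}
    e = {name: ch.reversal_mv for name, ch in params.channels.items()}
    vm = np.empty_like(t)
    vm[0] = params.steady_state_vm(0.0)
    for i in range(len(t) - 1):
        dv = -dt_ms / params.cm * sum(
            g[name][i] * (vm[i] - e[name]) for name in g
        )
        if abs(dv) > 50.0:
            raise ValueError(
                "integration unstable (|dVm| > 50 mV per step); "
                "use a smaller dt_ms"
            )
        vm[i + 1] = vm[i] + dv
    return t, vm


# --------------------------------------------------------------------------
# Baseline (tight-balance) noise
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineParams:
    """Spatio-temporal statistics of the pre-stimulus fluctuations.

    ``ou_sigma`` is the stationary standard deviation in dF/F0 units,
    ``ou_tau_ms`` the Ornstein-Uhlenbeck time constant, and
    ``spatial_corr_mm`` the Gaussian correlation length across the array.
    """

    ou_tau_ms: float = 20.0
    ou_sigma: float = 1.0e-4
    spatial_corr_mm: float = 0.5


def _spatial_mixing_matrix(geometry: HexGeometry, corr_mm: float) -> np.ndarray:
    d = geometry.pos[:, None, :] - geometry.pos[None, :, :]
    d2 = np.sum(d * d, axis=-1)
    cov = np.exp(-d2 / (2.0 * corr_mm**2))
    cov[np.diag_indices_from(cov)] += 1e-10
    return np.linalg.cholesky(cov)


def generate_baseline(
    geometry: HexGeometry,
    n_trials: int,
    duration_ms: float,
    sampling_rate_hz: float = 1600.0,
    params: BaselineParams = BaselineParams(),
    seed=None,
) -> np.ndarray:
    """Zero-mean correlated baseline noise, trials x channels x time (dF/F0).

    Temporal correlation is an exact discrete Ornstein-Uhlenbeck (AR(1))
    process initialised from its stationary distribution; spatial correlation
    is imposed by the Cholesky factor of a Gaussian kernel with unit diagonal,
    which preserves the per-channel stationary SD ``ou_sigma``.
    """
    if params.ou_tau_ms <= 0:
        raise ValueError("ou_tau_ms must be positive")
    if params.ou_sigma < 0:
        raise ValueError("ou_sigma must be non-negative")
    n_times = int(round(duration_ms * sampling_rate_hz / 1000.0))
    shape = (n_trials, geometry.n_channels, n_times)
    if params.ou_sigma == 0.0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_rate_hz
    rho = np.exp(-dt / params.ou_tau_ms)
    innov_sd = params.ou_sigma * np.sqrt(1.0 - rho**2)
    e = innov_sd * rng.standard_normal(shape)
    e[..., 0] *= params.ou_sigma / innov_sd  # stationary start
    x = lfilter([1.0], [1.0, -rho], e, axis=-1)
    if params.spatial_corr_mm > 0:
        chol = _spatial_mixing_matrix(geometry, params.spatial_corr_mm)
        x = np.einsum("ck,tkn->tcn", chol, x)
    return x


# --------------------------------------------------------------------------
# Traveling NEX / NINH waves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveSpec:
    """A radially traveling Gaussian net-current wave.

    The wave leaves ``origin`` at ``onset_ms`` (ms after stimulus onset) and
    reaches a channel at distance d after d/speed ms, contributing
    ``sign * peak * exp(-(t - onset - d/v)^2 / (2 w^2)) * exp(-d / decay)``
    to the *net membrane current*, i.e. to dVSD(t)/dt in dF/F0 per ms.
    ``sign`` +1 marks a net-excitation event, -1 a net-inhibition event; a
    NEX wave therefore depolarizes the local population (the integrated VSD
    signal steps up as the wave passes) and a matched NINH wave ``delay`` ms
    later repolarizes it by the same amount, so the programmed NEXmax and
    NINHmin of the derivative sit exactly at the kernel peaks and the
    excitation-inhibition budget closes to zero by construction.
    """

    origin: tuple
    onset_ms: float
    speed_mm_per_ms: float = 0.2
    sign: int = 1
    peak_amplitude: float = 4.0e-5  # dF/F0 per ms; derivative-peak scale
    temporal_width_ms: float = 25.0
    spatial_decay_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.speed_mm_per_ms <= 0:
            raise ValueError("speed must be positive")
        if self.temporal_width_ms <= 0:
            raise ValueError("temporal_width_ms must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 (NEX) or -1 (NINH)")


def generate_wave_field(
    geometry: HexGeometry,
    waves,
    duration_ms: float,
    sampling_rate_hz: float = 1600.0,
    t0_ms: float = 0.0,
) -> np.ndarray:
    """Sum of traveling-wave contributions, channels x time (dF/F0 per ms).

    This is the programmed *net-current* field — the ground-truth
    dVSD(t)/dt; its running time-integral is the dF/F0 signal composed into
    raw trials.  The time axis starts at ``t0_ms`` (ms relative to stimulus
    onset), so a full record including the pre-stimulus period uses a
    negative ``t0_ms``.  The field is exactly linear in each wave's
    ``peak_amplitude``.
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    n_times = int(round(duration_ms * sampling_rate_hz / 1000.0))
    t = t0_ms + np.arange(n_times) * 1000.0 / sampling_rate_hz
    out = np.zeros((geometry.n_channels, n_times))
    for w in waves:
        d = geometry.distances_from(w.origin)
        arrival = w.onset_ms + d / w.speed_mm_per_ms
        amp = w.sign * w.peak_amplitude * np.exp(-d / w.spatial_decay_mm)
        out += amp[:, None] * np.exp(
            -((t[None, :] - arrival[:, None]) ** 2)
            / (2.0 * w.temporal_width_ms**2)
        )
    return out


# --------------------------------------------------------------------------
# Dataset composition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score a recovery against the programmed signal."""

    conditions: dict            # name -> tuple[WaveSpec, ...]
    delay_ms: float             # programmed NEX -> NINH delay
    inter_area_lag_ms: float    # programmed area 17/18 -> 19/21 NEX lag
    baseline: BaselineParams
    sampling_rate_hz: float
    onset_ms: float
    duration_ms: float
    seed: int | None
    response_gain: np.ndarray | None = None  # per-channel multiplicative gain

    def noiseless_current_field(
        self, geometry: HexGeometry, condition: str
    ) -> np.ndarray:
        """The programmed dVSD/dt field of one condition, channels x time."""
        field = generate_wave_field(
            geometry, self.conditions[condition], self.duration_ms,
            self.sampling_rate_hz, t0_ms=-self.onset_ms,
        )
        if self.response_gain is not None:
            field = field * self.response_gain[:, None]
        return field

    def noiseless_field(self, geometry: HexGeometry, condition: str) -> np.ndarray:
        """The programmed dF/F0 signal (time-integral of the current field)."""
        current = self.noiseless_current_field(geometry, condition)
        return np.cumsum(current, axis=1) * 1000.0 / self.sampling_rate_hz


@dataclass
class SyntheticDataset:
    geometry: HexGeometry
    recordings: dict            # condition -> raw VSDRecording
    blank: VSDRecording
    ground_truth: GroundTruth


def default_conditions(
    geometry: HexGeometry,
    delay_ms: float = 125.0,
    inter_area_lag_ms: float = 8.0,
    speed_mm_per_ms: float = 0.2,
    peak_amplitude: float = 4.0e-5,
    temporal_width_ms: float = 25.0,
    spatial_decay_mm: float = 1.5,
    cfov_onset_ms: float = 110.0,
    periphery_onset_ms: float = 180.0,
) -> dict:
    """The five stimulus conditions of the emulated experiment.

    Bars moving up/down from the CFOV, up/down from the peripheral field of
    view, and a stationary bar.  Each condition launches a NEX wave from the
    CFOV representation in areas 17/18 and, ``inter_area_lag_ms`` later, from
    the one in areas 19/21; matched NINH waves follow both after ``delay_ms``
    simultaneously in the two areas (the net-inhibition onset carries no
    measurable inter-area lag).  Moving-bar conditions are told apart by a
    lateral displacement of the wave origin mimicking the cortical mapping of
    the bar trajectory.

    The Gaussian wave kernel is acausal, so the default event onsets sit a
    couple of effective widths after stimulus onset; this keeps the whole NEX
    event (including the smoothing-widened rising tail) inside the 0-800 ms
    post-stimulus integration window, as it is for the causal responses the
    generator emulates.
    """
    centers = cfov_centers(geometry)
    c1718 = np.asarray(centers["cfov_1718"])
    c1921 = np.asarray(centers["cfov_1921"])
    shift = 2.0 * geometry.pitch_mm

    def waves(origin_offset, onset):
        kw = dict(
            speed_mm_per_ms=speed_mm_per_ms,
            peak_amplitude=peak_amplitude,
            temporal_width_ms=temporal_width_ms,
            spatial_decay_mm=spatial_decay_mm,
        )
        o1 = tuple(c1718 + origin_offset)
        o2 = tuple(c1921 + origin_offset)
        ninh_onset = onset + delay_ms  # simultaneous in both areas
        return (
            WaveSpec(origin=o1, onset_ms=onset, sign=1, **kw),
            WaveSpec(origin=o2, onset_ms=onset + inter_area_lag_ms, sign=1, **kw),
            WaveSpec(origin=o1, onset_ms=ninh_onset, sign=-1, **kw),
            WaveSpec(origin=o2, onset_ms=ninh_onset, sign=-1, **kw),
        )

    return {
        "bar_down_cfov": waves(np.array([-shift, 0.0]), cfov_onset_ms),
        "bar_up_cfov": waves(np.array([shift, 0.0]), cfov_onset_ms),
        "bar_down_periphery": waves(np.array([-shift, -shift]), periphery_onset_ms),
        "bar_up_periphery": waves(np.array([shift, shift]), periphery_onset_ms),
        "stationary_bar": waves(np.array([0.0, 0.0]), cfov_onset_ms),
    }


def _default_f0(geometry: HexGeometry) -> np.ndarray:
    # mild illumination gradient so the dF/F0 division is exercised
    x = geometry.pos[:, 0]
    span = np.ptp(x) or 1.0
    return 900.0 + 200.0 * (x - x.min()) / span


def compose_dataset(
    geometry: HexGeometry,
    conditions: dict | None = None,
    n_trials: int = 50,
    duration_ms: float = 1300.0,
    onset_ms: float = 500.0,
    sampling_rate_hz: float = 1600.0,
    baseline: BaselineParams = BaselineParams(),
    f0: np.ndarray | None = None,
    seed: int | None = 0,
    delay_ms: float = 125.0,
    inter_area_lag_ms: float = 8.0,
    gain_log_sd: float = 0.5,
    gain_corr_mm: float = 0.6,
) -> SyntheticDataset:
    """Compose raw-fluorescence trials for every condition plus a blank.

    Raw fluorescence is F0 * (1 + signal + noise) with per-channel F0 > 0;
    noise is added in fractional units before conversion so the dF/F0
    preprocessing stage is exercised nontrivially.  The defaults mirror the
    emulated experiment: 6 conditions (5 stimuli + blank) x 50 trials,
    1.6 kHz, 800 ms of post-stimulus record.

    Real integrated NEX/NINH maps are patchy rather than smooth radial
    gradients, so a seeded log-normal per-channel response gain (spatially
    smooth, log-SD ``gain_log_sd``, correlation length ``gain_corr_mm``)
    multiplies the programmed current field of every condition.  The gain
    applies to net excitation and net inhibition alike, leaving the local
    excitation-inhibition budget balanced by construction; ``gain_log_sd=0``
    disables it.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if conditions is None:
        conditions = default_conditions(
            geometry, delay_ms=delay_ms, inter_area_lag_ms=inter_area_lag_ms
        )
    if f0 is None:
        f0 = _default_f0(geometry)
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise ValueError("per-channel F0 must be positive")

    onset_index = int(round(onset_ms * sampling_rate_hz / 1000.0))
    root = np.random.default_rng(seed)
    # independent child streams per condition, order-stable
    streams = {name: np.random.default_rng(root.integers(2**63))
               for name in list(conditions) + ["blank", "gain"]}

    gain = None
    if gain_log_sd > 0:
        chol = _spatial_mixing_matrix(geometry, gain_corr_mm)
        log_gain = gain_log_sd * (
            chol @ streams["gain"].standard_normal(geometry.n_channels)
        )
        gain = np.exp(log_gain - log_gain.mean())

    dt_ms = 1000.0 / sampling_rate_hz
    recordings = {}
    for name, waves in conditions.items():
        current = generate_wave_field(
            geometry, waves, duration_ms, sampling_rate_hz, t0_ms=-onset_ms
        )
        if gain is not None:
            current = current * gain[:, None]
        signal = np.cumsum(current, axis=1) * dt_ms  # dF/F0 level
        noise = generate_baseline(
            geometry, n_trials, duration_ms, sampling_rate_hz, baseline,
            seed=streams[name],
        )
        raw = f0[None, :, None] * (1.0 + signal[None, :, :] + noise)
        recordings[name] = VSDRecording(
            values=raw, sampling_rate_hz=sampling_rate_hz,
            stimulus_onset_index=onset_index, condition=name,
            signal_kind="raw_fluorescence", background_f0=f0, geometry=geometry,
        )

    blank_noise = generate_baseline(
        geometry, n_trials, duration_ms, sampling_rate_hz, baseline,
        seed=streams["blank"],
    )
    blank = VSDRecording(
        values=f0[None, :, None] * (1.0 + blank_noise),
        sampling_rate_hz=sampling_rate_hz, stimulus_onset_index=onset_index,
        condition="blank", signal_kind="raw_fluorescence",
        background_f0=f0, geometry=geometry,
    )
    truth = GroundTruth(
        conditions={k: tuple(v) for k, v in conditions.items()},
        delay_ms=delay_ms, inter_area_lag_ms=inter_area_lag_ms,
        baseline=baseline, sampling_rate_hz=sampling_rate_hz,
        onset_ms=onset_ms, duration_ms=duration_ms, seed=seed,
        response_gain=gain,
    )
    return SyntheticDataset(geometry=geometry, recordings=recordings,
                            blank=blank, ground_truth=truth)


def write_dataset(dataset: SyntheticDataset, out_dir) -> None:
    """Write one HDF5 file per condition plus the ground-truth JSON sidecar."""
    from .recording import write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, rec in dataset.recordings.items():
        write_recording(rec, out / f"{name}.h5")
    write_recording(dataset.blank, out / "blank.h5")

    gt = dataset.ground_truth
    sidecar = {
        "delay_ms": gt.delay_ms,
        "inter_area_lag_ms": gt.inter_area_lag_ms,
        "baseline": asdict(gt.baseline),
        "sampling_rate_hz": gt.sampling_rate_hz,
        "onset_ms": gt.onset_ms,
        "duration_ms": gt.duration_ms,
        "seed": gt.seed,
        "conditions": {
            name: [asdict(w) for w in waves]
            for name, waves in gt.conditions.items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))


def read_ground_truth(path) -> GroundTruth:
    """Load the JSON sidecar written by :func:`write_dataset`."""
    d = json.loads(Path(path).read_text())
    conditions = {
        name: tuple(
            WaveSpec(**{**w, "origin": tuple(w["origin"])}) for w in waves
        )
        for name, waves in d["conditions"].items()
    }
    return GroundTruth(
        conditions=conditions, delay_ms=d["delay_ms"],
        inter_area_lag_ms=d["inter_area_lag_ms"],
        baseline=BaselineParams(**d["baseline"]),
        sampling_rate_hz=d["sampling_rate_hz"], onset_ms=d["onset_ms"],
        duration_ms=d["duration_ms"], seed=d["seed"],
    )
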