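import numpy as np
import pytest

import vsd_spacetime as vs
from vsd_spacetime.synthetic import (ConductanceParams, ConductanceTransient,
                                     IonChannel)


def params_with(transients):
    """Default conductance set with selected transients attached."""
    base = ConductanceParams()
    channels = dict(base.channels)
    for name, tr in transients.items():
        ch = channels[name]
        channels[name] = IonChannel(reversal_mv=ch.reversal_mv,
                                    baseline=ch.baseline, transient=tr)
    return ConductanceParams(cm=base.cm, k=base.k, channels=channels)


class TestCompartmentModel:
    def test_no_transients_holds_steady_state(self):
        p = ConductanceParams()
        t, vm = vs.simulate_compartment_vm(p, 200.0, 0.5)
        expected = p.steady_state_vm(0.0)
        np.testing.assert_allclose(vm, expected, atol=1e-9)

    def test_sodium_step_depolarizes_monotonically(self):
        tr = ConductanceTransient(onset_ms=50.0, rise_tau_ms=5.0,
                                  decay_tau_ms=1e6, peak=0.5)
        p = params_with({"Na": tr})
        t, vm = vs.simulate_compartment_vm(p, 300.0, 0.25)
        rising = (t > 50.0) & (t < 250.0)
        steps = np.diff(vm[rising])
        # the slow 1e6 ms "decay" leaks a vanishing negative drift late on
        assert np.all(steps >= -1e-4 * steps.max())
        assert vm[-1] > vm[0] + 1.0

    def test_delayed_potassium_yields_programmed_current_delay(self):
        # independent oracle: locate the extrema of the integrated dVm/dt
        delay = 125.0
        na = ConductanceTransient(onset_ms=100.0, rise_tau_ms=3.0,
                                  decay_tau_ms=15.0, peak=0.4)
        k = ConductanceTransient(onset_ms=100.0 + delay, rise_tau_ms=3.0,
                                 decay_tau_ms=15.0, peak=0.8)
        p = params_with({"Na": na, "K": k})
        dt = 0.25
        t, vm = vs.simulate_compartment_vm(p, 500.0, dt)
        dvm = np.gradient(vm, dt)
        lag = t[np.argmin(dvm)] - t[np.argmax(dvm)]
        assert abs(lag - delay) <= 2.0  # both extrema located to ~dt

    def test_unstable_step_suggests_smaller_dt(self):
        tr = ConductanceTransient(onset_ms=1.0, rise_tau_ms=0.5,
                                  decay_tau_ms=50.0, peak=500.0)
        with pytest.raises(ValueError, match="smaller dt"):
            vs.simulate_compartment_vm(params_with({"Na": tr}), 100.0, 5.0)


class TestBaselineNoise:
    def test_zero_sigma_is_silent(self, hex7):
        x = vs.generate_baseline(hex7, 3, 100.0, 1600.0,
                                 vs.BaselineParams(ou_sigma=0.0), seed=1)
        assert np.all(x == 0)

    def test_same_seed_reproduces_bit_identically(self, hex7):
        a = vs.generate_baseline(hex7, 2, 100.0, seed=11)
        b = vs.generate_baseline(hex7, 2, 100.0, seed=11)
        assert np.array_equal(a, b)

    def test_lag_one_autocorrelation_matches_ou_closed_form(self, hex7):
        tau, fs = 20.0, 1600.0
        x = vs.generate_baseline(
            hex7, 200, 400.0, fs,
            vs.BaselineParams(ou_tau_ms=tau, ou_sigma=1.0,
                              spatial_corr_mm=0.0), seed=5,
        )
        x0, x1 = x[..., :-1].ravel(), x[..., 1:].ravel()
        rho = np.corrcoef(x0, x1)[0, 1]
        assert abs(rho - np.exp(-(1000.0 / fs) / tau)) < 0.02

    def test_spatial_mixing_preserves_marginal_sd(self, hex61):
        x = vs.generate_baseline(hex61, 50, 500.0, 1600.0,
                                 vs.BaselineParams(ou_sigma=1.0), seed=2)
        sds = x.std(axis=(0, 2))
        np.testing.assert_allclose(sds, 1.0, atol=0.1)


class TestWaveField:
    def test_peak_at_origin_occurs_at_onset(self, hex61):
        origin_ch = int(np.argmin(hex61.distances_from((0.0, 0.0))))
        w = vs.WaveSpec(origin=tuple(hex61.pos[origin_ch]), onset_ms=40.0)
        field = vs.generate_wave_field(hex61, [w], 100.0, 1600.0)
        t_peak = np.argmax(field[origin_ch]) / 1.6
        assert t_peak == pytest.approx(40.0, abs=0.626)

    def test_arrival_is_distance_over_speed(self, hex169):
        w = vs.WaveSpec(origin=(0.0, 0.0), onset_ms=20.0, speed_mm_per_ms=0.2,
                        spatial_decay_mm=50.0)
        field = vs.generate_wave_field(hex169, [w], 150.0, 1600.0)
        d = hex169.distances_from((0.0, 0.0))
        ch = int(np.argmin(np.abs(d - 1.0)))  # a channel ~1 mm out
        t_peak = np.argmax(field[ch]) / 1.6
        assert t_peak == pytest.approx(20.0 + d[ch] / 0.2, abs=0.7)

    def test_matched_pair_extremes_separated_by_programmed_delay(self, hex61):
        delta = 80.0
        kw = dict(origin=(0.0, 0.0), speed_mm_per_ms=0.2)
        waves = [vs.WaveSpec(onset_ms=50.0, sign=1, **kw),
                 vs.WaveSpec(onset_ms=50.0 + delta, sign=-1, **kw)]
        field = vs.generate_wave_field(hex61, waves, 300.0, 1600.0)
        gaps = (np.argmin(field, axis=1) - np.argmax(field, axis=1)) / 1.6
        np.testing.assert_allclose(gaps, delta, atol=1.3)  # 2-sample grid

    def test_field_is_exactly_linear_in_amplitude(self, hex61):
        w1 = vs.WaveSpec(origin=(0.1, 0.2), onset_ms=30.0, peak_amplitude=1e-5)
        w2 = vs.WaveSpec(origin=(0.1, 0.2), onset_ms=30.0, peak_amplitude=2e-5)
        f1 = vs.generate_wave_field(hex61, [w1], 100.0, 1600.0)
        f2 = vs.generate_wave_field(hex61, [w2], 100.0, 1600.0)
        assert np.array_equal(2.0 * f1, f2)


class TestComposeDataset:
    def test_default_condition_set_and_shapes(self, small_dataset):
        assert set(small_dataset.recordings) == {
            "bar_down_cfov", "bar_up_cfov", "bar_down_periphery",
            "bar_up_periphery", "stationary_bar",
        }
        rec = small_dataset.recordings["stationary_bar"]
        assert rec.values.shape == (8, 61, 2080)
        assert small_dataset.blank.values.shape == (8, 61, 2080)
        assert rec.signal_kind == "raw_fluorescence"

    def test_paper_scale_time_axis(self, hex61):
        # 625 ms at 1.6 kHz -> the canonical 1000-sample time axis
        ds = vs.compose_dataset(hex61, n_trials=2, duration_ms=625.0,
                                onset_ms=200.0, seed=0)
        assert ds.recordings["stationary_bar"].values.shape == (2, 61, 1000)

    def test_seed_reproducibility_is_bit_exact(self, hex7):
        a = vs.compose_dataset(hex7, n_trials=2, seed=42)
        b = vs.compose_dataset(hex7, n_trials=2, seed=42)
        for name in a.recordings:
            assert np.array_equal(a.recordings[name].values,
                                  b.recordings[name].values)
        assert np.array_equal(a.blank.values, b.blank.values)

    def test_empty_conditions_are_blank_like(self, hex7):
        ds = vs.compose_dataset(hex7, conditions={"sham": ()}, n_trials=30,
                                seed=9)
        sham = ds.recordings["sham"].values
        blank = ds.blank.values
        # same F0 scaling, same noise statistics, no evoked structure
        assert abs(sham.mean() - blank.mean()) < 0.05 * blank.std()
        assert abs(sham.std() / blank.std() - 1.0) < 0.05

    def test_trial_count_validated(self, hex7):
        with pytest.raises(ValueError):
            vs.compose_dataset(hex7, n_trials=0)

    def test_balance_closes_by_construction(self, hex61):
        # the time-integral of the programmed current over a window holding
        # both events returns to zero: equal net excitation and inhibition
        ds = vs.compose_dataset(hex61, n_trials=1, seed=3)
        gt = ds.ground_truth
        current = gt.noiseless_current_field(hex61, "stationary_bar")
        budget = current.sum(axis=1) * (1000.0 / gt.sampling_rate_hz)
        assert np.max(np.abs(budget)) < 1e-3 * np.max(np.abs(current))

    def test_ground_truth_sidecar_round_trips(self, tmp_path, hex7):
        ds = vs.compose_dataset(hex7, n_trials=1, seed=5)
        vs.write_dataset(ds, tmp_path)
        gt = vs.read_ground_truth(tmp_path / "ground_truth.json")
        assert gt.delay_ms == ds.ground_truth.delay_ms
        assert gt.conditions.keys() == ds.ground_truth.conditions.keys()
        assert (gt.conditions["stationary_bar"]
                == ds.ground_truth.conditions["stationary_bar"])
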