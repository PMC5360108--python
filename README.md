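# vsd-spacetime

Space-time analysis of the excitation-inhibition balance in
voltage-sensitive-dye (VSD) imaging of visual cortex.

VSD imaging with a hexagonal photodiode array (464 channels, 1.6 kHz)
reports the population membrane potential of the upper cortical layers
over several visual areas at once.  Because the temporal derivative of the
fractional dye signal is proportional to the summed membrane currents,

    dVSD(t)/dt ≈ k·dVm(t)/dt = -(k/Cm) Σ_x g_x(t)·(Vm(t) - E_x),

a statistically significant increase of dVSD/dt over the pre-stimulus
fluctuations marks **net excitation (NEX)** and a significant decrease
**net inhibition (NINH)**.  This package implements the full analysis
chain around that idea, for experimenters and modelers working with
mesoscopic optical recordings:

* **Preprocessing** — blank-subtracted dF/F0, 8-12-trial averaging,
  temporal Gaussian filtering (σ = 40 ms), zero-phase temporal derivative.
* **NEX/NINH detection** — per-sample normal deviates against the
  pre-stimulus baseline with Benjamini-Hochberg FDR (0.05) over the joint
  channels × time family, plus per-channel event tables (NEXmax, NINHmin,
  first-NEX onset).
* **Delayed balance** — time-averaged E(NEX) and E(NINH) per channel,
  their across-channel regression (slope 1 ⇒ excitation balanced by an
  equal amount of inhibition), and the NEXmax → NINHmin delay map.
* **State space** — SVD-based spatial PCA (X = UΣVᵀ) with 3-D
  trajectories, divergence-time detection between conditions, and a
  temporal-domain condition-difference test via principal-component
  regression with FDR over time.
* **Wavefront speed** — the amplitude-level position-vs-time regression
  (10 levels above the interval mean, pooled OLS, mm/ms).
* **Phase latency** — analytic-signal (Hilbert) phase maps, per-channel
  latencies in ms, and inter-area (17/18 vs 19/21) delays.
* **Synthetic data** — a ground-truthed generator (conductance-model
  baseline, spatio-temporally correlated noise, programmable traveling
  NEX/NINH waves) emulating the 464-channel recordings, used throughout
  the test suite for parameter-recovery validation.

## Worked example

```python
import vsd_spacetime as vs

geometry = vs.build_hex_geometry(169, 0.18)
dataset = vs.compose_dataset(geometry, n_trials=10, seed=1)

_, deriv = vs.preprocess(dataset.recordings["bar_up_cfov"], dataset.blank)
classification = vs.classify(deriv)
events = vs.extract_events(classification, deriv)

e_nex, e_ninh = vs.time_average_events(classification, deriv)
reg = vs.balance_regression(e_nex, e_ninh)
delays = vs.delay_statistics(events)
print(f"slope {reg.slope:.2f}, r {reg.r:.2f}, p {reg.p_value:.1e}")
print(f"delay {delays.mean_ms:.0f} +- {delays.sd_ms:.0f} ms")
```

prints

```
slope 0.84, r 0.97, p 6.8e-101
delay 128 +- 1 ms
```

— the generator programs matched NEX/NINH wave pairs 125 ms apart, and
the recovered delay sits within a filter width of that value, with the
amount of net inhibition tracking the amount of net excitation channel by
channel (r 0.97).  The scripts in `examples/` walk through each
capability the same way (detection, balance, state-space divergence,
wavefront speed, phase latency) and print the numbers they recover.

A thin CLI chains the stages on HDF5/TSV/JSON files:

```sh
vsd-spacetime run --seed 0 --out-dir out/      # simulate ... phase, all stages
```

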