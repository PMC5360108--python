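# Methods

## The measurement model

Voltage-sensitive-dye (VSD) imaging reports the population membrane
potential of the upper cortical layers: after blank subtraction and
division by the background fluorescence, the fractional signal VSD(t)
(dF/F0) is proportional to the mean membrane potential Vm(t) of the
imaged compartment, so its temporal derivative is proportional to the sum
of the ionic membrane currents divided by the specific capacitance,

    dVSD(t)/dt ≈ k dVm(t)/dt
              = -(k/Cm) Σ_x g_x(t) (Vm(t) - E_x),   x ∈ {Na, Ca, Cl, K}.

dVSD/dt therefore reads as the instantaneous excitation-inhibition
balance of the local network: a statistically significant increase over
the pre-stimulus fluctuations is a net excitation (NEX), a significant
decrease a net inhibition (NINH).  The single-compartment conductance
model in `synthetic.simulate_compartment_vm` integrates exactly this
equation (forward Euler; initial condition at the analytic steady state
Σ g E / Σ g) and is the biophysical anchor of the generator: a sodium /
calcium conductance transient produces a positive current lobe, a delayed
potassium / chloride transient the matching negative lobe.

## The analysis chain

1. **Fractional fluorescence.** (stim − mean blank)/F0 per trial; the
   blank mean uses every blank trial.
2. **Trial averaging.** Arithmetic mean of 8-12 trials (default 10,
   taken deterministically from the front of the trial list).
3. **Temporal Gaussian filter.** σ = 40 ms (unit-sum kernel, ±4σ
   truncation, reflection at the edges so the mean is preserved and onset
   transients are not smeared into edge ramps).  σ = 12 ms is the
   standard robustness setting; the label maps sharpen at event edges but
   signs, delays and balance statistics are unchanged.
4. **Temporal derivative.** Central differences (zero phase lag — the
   delay estimates depend on this), one-sided at the record ends, exact
   on affine signals.
5. **NEX/NINH classification.** Per-channel baseline mean/SD over the
   pre-stimulus window (trimmed by 3 filter σ at each edge); two-sided
   normal-deviate p-values per post-stimulus sample;
   Benjamini-Hochberg FDR at 0.05 jointly over channels × post-stimulus
   times; surviving samples labeled by the deviate's sign.
6. **Balance statistics.** E(NEX)/E(NINH) = mean of dVSD/dt over the
   NEX-/NINH-labeled samples within 0-800 ms; OLS of |E(NINH)| on E(NEX)
   across channels (slope 1 = equal amounts); delay = t(NINHmin) −
   t(NEXmax) per channel, reported raw (negative values kept).
7. **State space.** Observations = per-time samples stacked over
   replicates and conditions, channels as columns, each field centered on
   its own per-channel pre-stimulus mean so the origin is the
   pre-stimulus operating point; SVD; trajectories are the first three
   columns of U·Σ; component signs fixed by making each component's
   largest-magnitude loading positive.  Divergence of two trajectories:
   first post-stimulus time their 3-D distance exceeds mean + 3 SD of its
   pre-stimulus distribution for 20 ms continuously (both parameters
   exposed).  The temporal-domain condition test pools both conditions'
   zone-mean time vectors from all replicates, projects each vector on
   the first three principal component time courses, differences the
   reconstructions per replicate, t-tests each time point across
   replicates and corrects over time with BH-FDR at 0.05.
8. **Wavefront speed.** Within an ROI and interval, values above the
   interval mean are split into 10 equal-width amplitude levels; the
   farthest channel at or above each level per frame gives (time,
   distance-from-origin) points; one pooled OLS slope is the speed in
   mm/ms (significance threshold p < 0.01).  Estimates are invariant to
   positive affine rescaling and do not require constant amplitude or
   velocity.  A front whose tracked positions never move is returned as
   non-propagating (slope 0, p 1), as are fits with p ≥ 0.01 or slopes
   above 5 mm/ms.
9. **Phase latency.** Discrete analytic signal (window mean removed
   first to avoid the DC singularity); phase differences to the
   most-advanced channel, wrapped to (−π, π], divided by the reference
   channel's instantaneous angular frequency (exact for narrowband
   signals, an approximation otherwise; differences within 10% of ±π are
   flagged as potentially wrapped).  Inter-area delay = mean latency of
   areas 19/21 minus areas 17/18, t-tested against zero across
   replicates.  nVSD normalization divides each channel by its own
   post-stimulus maximum, preserving peak times exactly.

## The synthetic-data generator

No recordings of this kind are public, so the pipeline is validated on a
generator that emulates their structure on a centered hexagonal lattice
(464 channels at 0.18 mm pitch ≈ the 12 mm² aperture; areas 17/18/19/21
as horizontal bands; the two CFOV representations at the 17/18 and 19/21
borders).

* **Baseline ("tight balance") fluctuations** — Ornstein-Uhlenbeck noise
  (τ = 20 ms) with Gaussian spatial correlation (0.5 mm), stationary SD
  1e-4 dF/F0.  That SD is calibrated so the trial-averaged, filtered
  derivative fluctuates at a few 1e-7 per ms, the scale on which real
  non-significant cortex sits.
* **Waves** — each wave is a radially traveling Gaussian *net-current*
  kernel: sign · peak · exp(−(t − onset − d/v)²/2w²) · exp(−d/λ) added to
  dVSD/dt and integrated to the dF/F0 signal.  Programming the current
  rather than the fluorescence makes the ground truth exact: NEXmax and
  NINHmin sit at the kernel peaks, a matched NEX/NINH pair closes the
  excitation-inhibition budget to zero by construction, and a programmed
  delay is literally the separation of the derivative extremes.  Default
  peak 4e-5 per ms (the scale of real evoked derivative peaks), width
  25 ms, speed 0.2 mm/ms (within the 0.08-0.4 mm/ms range of cortical
  fronts), spatial decay 1.5 mm.
* **Conditions** — five stimuli (bars moving up/down from the center or
  periphery of the field of view, plus a stationary bar) and a blank.
  Each stimulus launches a NEX wave from the 17/18 CFOV representation
  and, 8 ms later, from the 19/21 one; matched NINH waves follow both
  after 125 ms, simultaneously in the two areas.  Raw fluorescence is
  F0 · (1 + signal + noise) with a mild illumination gradient in F0.
* **Response gain** — a seeded log-normal per-channel gain (log-SD 0.5,
  correlation 0.6 mm) multiplies the current field of every condition:
  real integrated NEX/NINH maps are patchy, and that heterogeneity is
  what gives the across-channel balance regression its leverage.  The
  gain scales both polarities equally, so local balance is unaffected.
  `gain_log_sd=0` switches it off for experiments that need pure radial
  waves.
* **Event timing** — the Gaussian kernel is acausal, so default event
  onsets (110 ms CFOV, 180 ms periphery) sit a couple of effective widths
  after stimulus onset; this keeps the whole smoothing-widened event
  inside the fixed 0-800 ms integration window, as causal physiological
  responses are.  Experiments that need other onsets set them explicitly.

What the generator does **not** emulate: laminar structure, spiking,
pharmacology, heartbeat/respiration artifacts, histology-derived area
borders, or single-trial variability beyond stationary Gaussian noise.
Passing recovery tests therefore demonstrates that the estimators are
correct and well-calibrated under the assumed signal model — not that
real cortex obeys that model.

## Estimator validity conditions (found while validating)

These are properties of the estimators themselves, mapped out with the
generator and respected by the validation protocols:

* **Delay bias from lobe overlap.**  With matched opposite-sign
  derivative lobes separated by Δ and effective width
  s = sqrt(w² + σ_filter²), overlap shifts NEXmax earlier and NINHmin
  later symmetrically; at Δ = 60 ms and σ = 40 ms the recovered delay
  would be ~90 ms.  The bias is negligible once Δ ≳ 4s, so delay-recovery
  experiments use 12 ms waves with the 12 ms filter (bias < 1 sample at
  Δ = 60-250 ms).  At the default σ = 40 the 125 ms delay carries a
  ~+4 ms bias — within the filter width, as expected.
* **Baseline duration for the normal-deviate classifier.**  The filtered
  derivative decorrelates over roughly a filter width, so a pre-stimulus
  window holds few effective samples per channel; worse, the spatially
  correlated field shares its SD estimation error across channels, and a
  joint underestimate can fire cluster-wise BH rejections.  Null
  calibration therefore uses 5 s pre-stimulus records (mean empirical
  false-discovery proportion 0.05 at nominal 0.05); with short baselines
  the empirical FDP inflates to ~0.1 and should not be trusted.
* **Front sharpness and level spacing for the speed estimator.**  The
  level-crossing tracker needs (i) the front's blur v·s to be small
  against the aperture, (ii) the interval to end before every level
  saturates at the ROI edge, and (iii) one amplitude-level spacing to
  exceed the maximum-over-channels noise, or far channels false-trigger
  the farthest-above-level rule and bias the slope downward.  The speed
  calibration programs 3 ms fronts (4 ms analysis filter, amplitude
  8e-4/ms, negligible decay) from a peripheral origin (~4 mm path),
  interval [onset, onset + (R − 1.2 mm)/v]; programmed 0.1 / 0.2 /
  0.4 mm/ms are then recovered within ~6% for both polarities.  In the
  default slow-wave regime (25 ms waves, 40 ms filter) the blur spans the
  aperture and the estimator reports a significant but strongly
  downward-biased slope — an inherent limitation of level-crossing
  methods, not of this implementation.
* **Filter width and the balance readout.**  E(NEX)/E(NINH) average over
  the labeled intervals, and with the 40 ms filter each interval edge
  drags ~120 ms of near-threshold tail samples whose chance inclusion
  jitters the per-channel estimates; that noise dilutes the OLS balance
  slope toward r² (~0.87 for a construction whose true slope is exactly
  1).  With the 12 ms filter the boundaries are crisp and the same
  construction reads out at slope ~0.95-0.98, which is why the balance
  validation analyzes at 12 ms.
* **Sustain window for divergence detection.**  The sustained-threshold
  rule (3 SD for 20 ms) is only a real filter when 20 ms spans at least
  two correlation lengths of the trajectory noise; with the 12-40 ms
  temporal filters a single chance excursion of the correlated 3-D
  distance already lasts that long, and identical-condition pairs
  false-diverge in 6-14% of runs.  Trajectory studies therefore analyze
  with an 8 ms filter, where the null false-divergence rate is ≤ 2% and
  distinct-origin conditions still diverge within 50 ms of the first
  significant net excitation.
* **Phase windows.**  Latency maps are exact for plane waves when the
  analysis window holds several cycles (spectral leakage otherwise
  distorts the phase) and the latency spread stays below half a period;
  the validation uses 10 Hz waves in 500 ms windows.  Transient
  (non-oscillatory) fields yield usable but approximate latencies via the
  instantaneous frequency of the reference channel.

## Problem sizes

Validation ensembles run at desk scale: null-FDP and trajectory-null
ensembles on 61-channel arrays, parameter recovery on 169 channels, the
balance study and speed calibration on the full 464-channel aperture, and
one complete command-line pipeline run at the full experimental scale
(6 conditions × 50 trials × 464 channels × 2080 samples, ~75 s, ~2.3 GB
of raw HDF5).

## Known limitations

* The per-sample normal-deviate test treats filtered samples as the test
  family; dependence makes the nominal BH guarantee loose, which is why
  control is demonstrated empirically.
* The balance regression is plain OLS; with noisy E maps its slope is
  attenuated toward r² (no errors-in-variables correction is applied,
  matching the original analysis).
* Divergence times depend on the declared threshold rule (3 SD sustained
  20 ms); other operationalizations shift them by a few ms.
* Hexagon-pixel sub-sampling for display, movie rendering, histological
  borders and cross-animal alignment are out of scope.
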