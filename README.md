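# mnpool

Simulation and analysis of spinal motor-neuron (MN) pool synchronization:
do MN pools receive part of their drive as **impulsive** common inputs
(iCI) — brief shared bursts that transiently align firings — rather than
only as **continuous** common inputs (cCI), and what do such impulses do
to the pool's behaviour as a linear amplifier of continuous drive?

The package is written for motor-control and motor-unit-physiology
researchers who work with decomposed spike trains (HD-EMG / intramuscular
decompositions) and with conductance-based pool models.

## What is inside

* a two-compartment Hodgkin–Huxley pool of 177 slow-type MNs with 64
  recurrent Renshaw cells, integrated with the exponential scheme at
  0.2 ms, drive-calibrated so the pool fires at 10.4 ± 1.4 spikes/s
  (range 7.3–13.4 Hz) — `mnpool.model`;
* common-input generators (rectangular 5 ms burst trains with bounded
  occurrence jitter; RMS-normalised narrowband noise; power-matched
  sinusoids) with amplitude/power calibrations — `mnpool.inputs`;
* the analysis pipeline: cumulative spike trains, the discharge-variability
  exclusion filter, Welch pooled PSD, intramuscular coherence, the
  time-resolved SPIKE distance `S(t) ∈ [0,1]`, synchronization-event
  detection on the F_DR-band Hilbert envelope (threshold mean + 1 SD),
  event-triggered SPIKE-distance profiles, circular-shift surrogates, and
  bounded-lag transmission correlations — `mnpool.spikes`,
  `mnpool.spectral`, `mnpool.synchrony`, `mnpool.transmission`;
* a biophysics-free synthetic generator of decomposition-style spike
  trains with injectable common impulses (ground truth for every
  estimator) — `mnpool.synthetic`;
* scenario orchestration plus a thin `mnpool` CLI — `mnpool.experiments`,
  `mnpool.cli` — and numbered drivers under `analysis/`.

The central statistic: around moments when the pool's summed activity has
high power at the mean discharge rate F_DR (synchronization events), the
multivariate SPIKE distance of the pool is averaged in 2 s windows; its
minimum quantifies how strongly the pool transiently synchronizes. An
impulsive input that recruits ~50% of the pool per 5 ms burst produces a
sharp trough near lag 0 that no continuous input reproduces.

## Worked example

Generate synthetic decomposed-style trains with injected 1/s common
impulses and run the synchronization analysis:

```bash
mnpool synth --n-units 20 --impulse-rate 1.0 --seed 2 --out spikes.csv
mnpool analyze-sync --spikes spikes.csv --surrogates 20 \
    --out sync_out --figure profile.svg
```

which prints (numbers from this exact invocation):

```json
{
  "event_rate": 0.766768902520336,
  "min": 0.270979349704545,
  "n_units_retained": 20,
  "surrogate_mean_min": 0.2974350707400618
}
```

Reading: the detector finds synchronization events at 0.77/s (28 impulses
were injected over the 30 s record); the event-triggered SPIKE-distance
minimum (0.271) lies below the mean of 20 circular-shift surrogates
(0.297), so the synchronization is a property of cross-train timing, not
of the single-train statistics — the same logic the study applies to
experimental pools.

The full simulation study runs as numbered scripts (each prints what it
found and writes tables under `results/`):

```bash
python analysis/01_calibrate_pool.py        # drives, burst amplitude, powers
python analysis/02_scenario_synchronization.py
python analysis/03_spectra.py               # pooled PSD + IMC per scenario
python analysis/04_gain_nonlinearity.py     # exponential vs linear gain growth
python analysis/05_transmission.py          # cCI transmission with/without iCI
```

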