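# adaptif

Simulators and closed-form theory for spiking neurons whose
spike-frequency adaptation is carried by a **finite population of
stochastic two-state channels**, contrasted with the classical case of
deterministic adaptation plus fast (white) current noise.

The package implements a hierarchy of models around the perfect
integrate-and-fire (PIF) neuron:

* **channel model** — PIF coupled to N two-state adaptation channels with
  spike-gated opening rates, simulated with an exact Gillespie scheme
  (event-driven and exact when the white-noise intensity is zero);
* **diffusion model** — deterministic adaptation filter plus an
  Ornstein-Uhlenbeck fluctuation with matched moments;
* **white-noise model** — deterministic adaptation, fast fluctuations only
  (infinite-channel limit);
* **colored-noise reduction** — a plain PIF driven by an OU process whose
  drive, correlation time and variance are all scaled by the degree of
  adaptation `alpha`;
* **Traub-Miles model** — a conductance-based neuron with an M-type
  adaptation current, in deterministic-M + white-noise and stochastic-M
  (hybrid Gillespie) variants.

The `stats` module estimates everything the analysis needs from interspike
intervals (unbiased cumulants, CV, rescaled skewness/kurtosis normalized to
one for an inverse Gaussian, serial correlation coefficients with
block-bootstrap errors, histograms, PSTHs), and the `theory` module
provides the matching closed forms: inverse-Gaussian density and moments,
self-consistent stationary rate, weak-noise ISI density and cumulants of the
colored-noise model, serial-correlation formulas for both stochastic
(positive, geometric) and deterministic (negative, geometric) adaptation,
the noise-free limit cycle, and the exponential step response.

Headline result reproduced by the test suite: with *stochastic* adaptation
the ISI density is more peaked and heavier-tailed than an inverse Gaussian
(rescaled skewness/kurtosis > 1) and ISIs are *positively* correlated,
whereas *deterministic* adaptation with white noise gives an
inverse-Gaussian-like density and *negative* ISI correlations; mixing both
noise sources interpolates smoothly between the two regimes.

## Command line

```bash
# simulate one variant and write spikes + ISI statistics
adaptif simulate --config examples/pif.yaml --variant channel \
    --seed 7 --t-end 100000 --out out/run1

# statistics of an external spike-time list (one time per row)
adaptif analyze --spikes spikes.txt --out out/analysis

# closed-form curves as CSV
adaptif theory --config examples/pif.yaml --curve scc-deterministic \
    --out out/scc.csv

# channel vs diffusion vs colored-noise comparison suite
adaptif experiment --config examples/pif.yaml --seed 3 --out out/exp
```

A PIF configuration file (YAML or JSON) looks like

```yaml
base_drive: 0.2            # mu, threshold units per ms
adaptation_strength: 1.0   # Delta
white_noise_intensity: 0.0 # D
kinetics:
  n_channels: 100          # null = infinite (deterministic adaptation)
  tau_a: 100.0             # channel time constant, ms
  pulse_duration: 1.0      # spike pulse width, ms
```

Every stochastic entry point takes an explicit `seed`; identical
(config, seed) pairs give byte-identical outputs.

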