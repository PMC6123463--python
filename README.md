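# circpop

Population coding of multidimensional circular stimuli: analytic Fisher
information and simulated maximum-likelihood (ML) / population-vector (PV)
decoding for populations of *pure* (single-dimension) and *conjunctive*
(multi-dimension) von-Mises neurons, plus behavioral kinematics and
velocity-conditioned head-direction cell classification — all exercisable on
synthetic data.

## What's inside

| Module | Role |
| --- | --- |
| `circpop.tuning` | Von-Mises tuning curves, populations, peak-rate normalization schemes (`equal_population_rate`, `equal_fisher_information`) |
| `circpop.fisher` | Closed-form Fisher information, Cramér–Rao bounds, expected spike counts |
| `circpop.spiking` | Independent Poisson spike counts and dependent variants: distance-structured noise correlations (Gaussian copula), shared additive/multiplicative gains, a two-layer feed-forward pooling model |
| `circpop.decoders` | ML (grid + local refinement), PV, and Gaussian-approximation correlated-likelihood decoders; circular error conventions |
| `circpop.experiments` | Error surfaces over (N, T), regime maps and critical population sizes, 2D/1D error ratios and distributions, spike-conditioned errors, mixed-population synergy, error-vs-FI collapse |
| `circpop.kinematics` | Heading/angular velocities from trajectories, navigation/maneuvering segmentation, low/high angular-velocity split |
| `circpop.hd_analysis` | Occupancy-normalized tuning curves, Rayleigh vector, tuning width, circular-shift shuffle significance, untuned/pure/conjunctive classification, transition tables |
| `circpop.synthetic` | Two-mode synthetic trajectories and inhomogeneous-Poisson spike trains with optional velocity-gated tuning |

## CLI

The `circpop` entry point exposes the analysis drivers:

```bash
circpop fisher --n 1000 --t 10 --kappa 9.11            # closed-form tables
circpop surface --kind pure --repeats 200 --out s.csv  # (N, T) error surface
circpop regimes --repeats 200                          # ratio map + N_cr
circpop ncrit --kappa-list 2.37,9.11 --d-list 2,3
circpop ratio2d1d --kind pure --n 1000
circpop conditional --n 1000 --t 0.075
circpop mixed --fractions 0,0.5,1.0
circpop fi-collapse --kind pure
circpop synth --duration 600 --cells 20 --out-dir session/
circpop classify --head-angles session/head_angles.csv \
    --spikes session/spikes_cell000.csv --out classes.csv
```

`surface --full` switches to the full-resolution grid (slow); YAML configs can be
passed with `--config` where supported.

## Conventions

- Angles are radians internally, degrees at every user-facing interface.
- "Tuning width" is always the full width at half-height above baseline;
  `kappa = ln 2 / (1 - cos(width / 2))`.
- Scalar decoding error is the square root of the summed squared
  per-dimension shorter-arc errors; trials where the relevant population
  emitted no spikes count as 180° per dimension.
- All simulations are reproducible given a seed.
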