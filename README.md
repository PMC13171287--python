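# popstate

Population coupling and ON/OFF cortical-state analysis for laminar spike
recordings, with a synthetic-session generator that provides ground truth for
every stage.

The package implements, as a tested reusable pipeline:

- **Population coupling** of single units: raw zero-lag coupling `C[0]`
  (spike-count-normalized cross-covariance of the smoothed unit train with
  the smoothed summed activity of the other channels), its Pearson-normalized
  form `C_norm`, and the Fisher transform `Z = atanh(C_norm)` — including
  own-channel exclusion, a 300 µm leakage control, rate matching, and a
  stimulus-responsiveness filter.
- **A multichannel Poisson hidden Markov model** of ON/OFF population states:
  10 ms spike-count bins, Baum–Welch EM with 10 random restarts
  (Dirichlet-initialized transition/start probabilities, uniform emissions),
  Viterbi decoding, and fourfold leave-one-channel-out cross-validation with
  a 10% elbow rule for selecting the number of phases.
- **State metrics**: per-trial ON/OFF firing-rate ratios, the attention
  modulation index `attMI = (A_RF − A_away)/(A_RF + A_away)`, pairwise
  spike-count noise correlations in the 500–0 ms pre-dimming window, and the
  cross-metric correlation/regression analyses.
- **Laminar utilities**: finite-difference current source density, SNR
  screening, a 5-parameter visual-response latency fit with the 33% rule,
  layer-compartment assignment relative to the granular reference channel,
  and z-scored receptive-field maps.
- **A synthetic generator** producing sessions with a latent two-state Markov
  process at 10 ms resolution, per-channel state-dependent Poisson
  multi-unit counts, and single units on a soloist→chorister continuum via a
  tunable ON/OFF rate ratio `rho`; attention lengthens ON dwell times and
  scales rates.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, parameter recovery, phase selection, metric orderings) at their
stated tolerances; the rest of the suite covers each module with unit,
property (hypothesis), and oracle tests.

## CLI

```sh
popstate simulate --seed 1 --out session_dir
popstate compute-pc session_dir --out pc.tsv
popstate fit-hmm session_dir --select --out hmm_out
popstate run config.yaml          # full pipeline
popstate validate config.yaml
```

A minimal pipeline config:

```yaml
seed: 7
output_dir: out
generator:
  n_channels: 16
  n_trials: [20, 20]
  units:
    - {channel_index: 3, base_rate_hz: 15.0, rho: 4.0, gain: 0.2}
hmm:
  s_range: [1, 2, 3]
```

`popstate run` writes `unit_metrics.tsv`, `pair_metrics.tsv`,
`correlations.json`, `trajectories.tsv`, `hmm_models.json`,
`cv_report.json`, and a `manifest.json` recording seed and config hash.
Sessions are plain-text directories (`units.tsv`, `spikes.tsv`,
`trials.tsv`, `session.json`, optional `continuous.tsv`).

## Conventions

- Times are floating milliseconds from session start; intervals are
  half-open `[start, end)`.
- Channel index 0 is the most superficial contact; contacts are 150 µm
  apart.
- The Gaussian "half-width" used for smoothing is the kernel standard
  deviation; the unit train uses a √2-narrower kernel than the population
  rate by default (`unit_kernel_mode: literal`), or both use the narrower
  kernel (`matched`).
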