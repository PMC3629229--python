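# stochconn

Directed functional connectivity and background-noise structure from
multichannel recordings, via multivariate Ornstein–Uhlenbeck (OU) fitting.

The model is the linear stochastic system `dx/dt = W x + xi`:

* `W` (N×N, units 1/s) is the drift matrix, read as directed functional
  connectivity — `W[i, j]` is the coupling from channel *j* onto channel *i*,
  with sign interpreted as functional excitation/inhibition;
* `xi` is Gaussian white noise with spatial covariance `Q`, the background
  input driving the network.

From a centered multichannel recording the package estimates `W` from lagged
covariances (`W = (C(tau) C(0)^+ − I)/tau`), extracts the residual noise
traces, and computes the noise covariance twice — empirically from the
residuals (`Q_E`) and theoretically from the stationary Lyapunov identity
(`Q_T = −(W C0 + C0 Wᵀ)`) — whose agreement validates the model on a given
dataset. On top of the per-subject fits it runs a full two-group comparison
battery:

* linear-stability spectra and excitation/inhibition balance correlations;
* connection-wise permutation tests with z-scores, change maps and ranked
  directed changes;
* linear-SVM separability of vectorized `W`/`Q` features under leave-one-out
  cross-validation with label-permutation significance;
* dominant spatial noise patterns (eigenvalue-weighted eigenvectors of `Q`),
  leave-one-out biharmonic-spline spatial complexity, and
  covariance-vs-distance cross-talk profiles;
* Wilcoxon rank-sum comparisons of all scalar summaries.

A built-in simulator generates stationary recordings (exact AR(1) sampling
or Euler–Maruyama) and whole synthetic cohorts with planted connection
differences and configurable noise correlation lengths, so every analysis
stage is testable end to end without any external data.

## Layout

| module                  | contents                                                        |
|-------------------------|-----------------------------------------------------------------|
| `stochconn.core`        | recording/fit types, W estimation, residuals, Q_E/Q_T, stability, residual diagnostics |
| `stochconn.simulate`    | stable drift construction, spatial noise kernels, OU sampling, cohort synthesis, PCA artifact removal |
| `stochconn.cohort`      | two-group cohort container and batch fitting                    |
| `stochconn.stats`       | permutation difference tests, change maps, ranked changes, balance, rank-sum |
| `stochconn.classify`    | vectorization, PCA projection, linear SVM, LOOCV, permutation significance |
| `stochconn.spatial`     | sensor layouts, stereographic projection, dominant patterns, spatial complexity, cross-talk |
| `stochconn.io` / `.cli` | text readers/writers, cohort manifests, pipeline driver, CLI    |

## CLI

All file formats are plain text (tab-separated matrices/recordings, JSON
manifests and reports); every stochastic stage takes an explicit seed.

```sh
# generate a synthetic two-group cohort (recordings + manifest + ground truth)
stochconn simulate --config cohort.json --out-dir data/

# per-subject fits: W, Q_E, Q_T matrices + diagnostics JSON
stochconn fit data/manifest.json --out-dir fits/ --lag-steps 1

# connection-wise permutation comparison (maps + ranked changes)
stochconn compare data/manifest.json --n-perm 10000 --seed 0 --out-dir maps/

# SVM separability of W- or Q-features with permutation p-values
stochconn classify data/manifest.json --feature Q --n-perm 10000 --seed 0 --out report.json

# dominant noise patterns and spatial complexity
stochconn noise data/manifest.json --out-dir noise/
stochconn complexity data/manifest.json --out complexity.tsv

# everything, bundled into one deterministic JSON report
stochconn run-all data/manifest.json --seed 0 --n-perm 10000 --out-dir out/
```

A minimal simulation config:

```json
{
  "n_channels": 32,
  "duration": 30.0,
  "dt": 0.0016,
  "seed": 7,
  "groups": [
    {"label": "control", "n_subjects": 10, "noise_correlation_length": 0.02},
    {"label": "case", "n_subjects": 9,
     "connection_deltas": [[1, 6, 5.0]],
     "noise_correlation_length": 0.06}
  ]
}
```

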