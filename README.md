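# neuralpf

Weight-free particle filtering for continuous-time nonlinear state-space
models, with online maximum-likelihood parameter/gain learning and a set of
reference filters for benchmarking.

The core filter propagates an ensemble of N *equally weighted* particles by

```
z <- z + f(z) dt + W (dy - g(z) dt) + Sigma_x^{1/2} dw,
W  = cov_N(z, g(z)^T) Sigma_y^{-1},
```

so the observation stream steers every particle directly through a
cross-covariance gain instead of reweighting trajectories. This avoids the
weight degeneracy that makes importance-weighted particle filters need
exponentially many particles as the hidden dimension grows.

## Contents

| module                  | what it does                                                             |
|-------------------------|--------------------------------------------------------------------------|
| `neuralpf.models`       | state-space SDE models, Euler–Maruyama simulation, stationary densities, model zoo (`frog`, `frog_visual`, `linear_d`, `bimodal_d`) |
| `neuralpf.npf`          | the weight-free filter: empirical gain, novelty, particle update, posterior readouts |
| `neuralpf.learning`     | online ML learning of the generative weight `J` and the gain `W` via forward sensitivity (filter-derivative) propagation; Hebbian small-noise rule |
| `neuralpf.baselines`    | exact Kalman–Bucy filter, weighted bootstrap particle filter with systematic resampling, EnKBF (averaged-innovation) variant |
| `neuralpf.experiments`  | time-averaged MSE, particles-needed search, linear/exponential scaling fits, multisensory tracking and scaling studies |
| `neuralpf.cli`          | `npf` command-line entry point                                           |

## CLI

All commands are driven by a small YAML/JSON config:

```yaml
# frog.yaml
model:
  name: frog            # frog | frog_visual | linear_d | bimodal_d
  params: {sigma_v2: 0.1, sigma_a2: 0.1}
dt: 0.01
T: 50.0
seed: 0
```

```bash
npf simulate --model frog.yaml --out sim.csv
npf filter   --model frog.yaml --filter npf -N 1000 --out track.csv
npf filter   --model frog.yaml --filter pf  -N 1000 --out pf.csv
npf learn    --model visual.yaml --learn both --rule ml --eta 0.005 --out learn.csv
npf frog-demo --out frog/                      # two-channel tracking study
npf bench-scaling --family linear --filters npf,enkbf,pf --out scaling.csv
```

Each CSV gets a JSON sidecar embedding the resolved config, its hash and the
seed; identical config + seed reproduce outputs byte for byte.

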