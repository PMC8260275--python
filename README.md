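# multinoise

Multistage noise models for neural spike-count responses: simulation, exact
likelihood, maximum-likelihood inference, and parameter-recovery studies.

## The problem

Linear-nonlinear-Poisson (LNP) models describe a neuron's spike count in a
time bin as Poisson with rate `f(x_t)`, where `x_t` is the linearly filtered
stimulus and `f` a static nonlinearity. Real neurons — retinal ganglion
cells prominently — show variability that is often strongly non-Poisson and
changes with stimulus conditions. Because a Poisson model's variability is
pinned to its mean, fitting it to such data systematically biases the
inferred nonlinearity and says nothing about where the noise arises.

`multinoise` implements a cascade model with **three separately
identifiable noise sources** around the nonlinearity and deterministic
spike generation:

```
r_t = R[ n_mult,t · f(x_t + n_up,t) + n_down,t ]
```

- `f(x) = β1·ln(1 + exp(β2·x + β3)) + β4` — a softplus nonlinearity
  spanning hard-rectified to near-linear shapes;
- `n_up ~ N(0, σ_up²)` — additive noise **upstream** of the nonlinearity,
  whose effect is shaped by the local slope of `f`;
- the **multiplicative** stage makes the output conditionally Gaussian with
  mean `λ = f(x + n_up)` and variance `σ_mult²·λ` (Poisson-like
  mean-variance scaling with a free factor);
- `n_down` — additive **downstream** noise, either Gaussian
  `N(0, σ_down²)` or, in the *mixture* variant, present only with
  probability `p_down` (an intermittent noise source that produces excess
  zeros);
- `R` rounds to the nearest nonnegative integer — spike generation itself
  is deterministic.

Because both post-nonlinearity stages are conditionally Gaussian given
`λ`, the exact count probability reduces to a one-dimensional expectation
over the upstream noise,

```
P(r = k | x) = E_u[ F(k + ½ | λ) − F(k − ½ | λ) ],   λ = f(x + u),
```

which the package evaluates to ~1e-9 per bin with a calibrated hybrid
quadrature (Gauss–Hermite where the integrand is smooth, an exact-CDF
scheme via `f⁻¹` plus a localized correction where it is nearly a step).
All seven (Gaussian variant) or eight (mixture) parameters are estimated
simultaneously by multi-start bounded Nelder–Mead maximum likelihood;
~5000 binned observations (roughly 8 minutes of recording at ~100 ms bins)
suffice to recover both the nonlinearity and the noise decomposition.

## Worked example

```python
import numpy as np
from multinoise import (MultistageModel, NoiseParams, SoftplusParams,
                        simulate_responses, response_pmf)

model = MultistageModel(
    nonlinearity=SoftplusParams(beta1=1.0, beta2=2.0, beta3=0.0, beta4=0.1),
    noise=NoiseParams(sigma_up=0.4, sigma_mult=0.8, sigma_down=0.5),
)
x = np.random.default_rng(0).standard_normal(5000)
counts = simulate_responses(model, x, seed=1)
pmf = response_pmf(model, x=1.0)
```

Running `python examples/01_simulate_and_likelihood.py` prints:

```
simulated 5000 bins: mean count 1.255, variance 2.164 (super-Poisson: variance > mean)

count distribution at x = 1.0:
  P(r=0)  exact 0.1082   simulated 0.1064
  P(r=1)  exact 0.2069   simulated 0.2071
  P(r=2)  exact 0.2704   simulated 0.2699
  ...
Jensen-Shannon divergence exact vs simulated: 1.48e-05 bits (Monte-Carlo noise only)
```

The simulated counts are over-dispersed (variance 2.16 at mean 1.26 — a
Poisson model cannot produce this), and the analytic count distribution
matches a 200 000-draw simulation to within Monte-Carlo noise.

The other examples cover fitting and the bias of the Poisson baseline
(`02_fit_model.py`: on data with purely downstream noise the multistage fit
recovers the nonlinearity to 0.02 spikes while the LNP fit inflates the
low-input response by rectified noise), reverse-correlation preprocessing
(`03_preprocess_recording.py`), and a reduced recovery study
(`04_recovery_study.py`).

A thin CLI wraps the same functionality:

```bash
multinoise simulate --model model.json --n 5000 --seed 0 --out data.csv
multinoise fit --data data.csv --variant mixture --starts 8 --seed 7 --out fit.json
multinoise loglik --model model.json --data data.csv
multinoise metrics --fit fit.json --truth model.json
multinoise recover --datasets 5 --points 2000 --starts 3 --out report.json
```

## Package layout

| module | contents |
|---|---|
| `multinoise.model` | parameter types, softplus calculus, forward simulator |
| `multinoise.likelihood` | stage densities, exact count pmf, dataset log-likelihood (multistage + LNP) |
| `multinoise.fitting` | least-squares initializer, randomized starts, multi-start Nelder–Mead MLE |
| `multinoise.preprocess` | reverse-correlation filter, 13 Hz smoothing, half-max-width binning, z-scoring |
| `multinoise.metrics` | SNR, Jensen–Shannon divergence, weighted nonlinearity error, curvature |
| `multinoise.recovery` | synthetic suite generation, noise-contribution decomposition, recovery reports |
| `multinoise.cli` | `multinoise` command-line entry point |

See `docs/methods.md` for the model's assumptions, numerical choices, and
limitations.
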