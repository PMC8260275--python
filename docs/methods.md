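# Methods

## Model

A spike count `r_t` in a time bin is generated from the z-scored filtered
stimulus `x_t` as

```
r_t = R[ n_mult,t · f(x_t + n_up,t) + n_down,t ]
```

with a four-parameter softplus nonlinearity
`f(x) = β1·ln(1+exp(β2·x+β3)) + β4` (β1, β2 > 0, so `f` is strictly
increasing and invertible; β4 ≥ 0 in all fitting paths so the output is
nonnegative). The three noise stages:

- **Upstream** (`σ_up`, in z-scored input units): `n_up ~ N(0, σ_up²)` added
  to the input. Its effect on the response is scaled by the local slope of
  `f` — amplified on the steep limb, suppressed where `f` is flat.
- **Multiplicative** (`σ_mult`, dimensionless): given `λ = f(x + n_up)`,
  the stage output is Gaussian with mean `λ` and variance `σ_mult²·λ`.
  This is the mean–variance scaling contract: output variance proportional
  to the output, with a free constant (Poisson-like at `σ_mult = 1`). A
  literal reading of a noise draw `n_mult ~ N(1, σ_mult²·λ)` *multiplied*
  by `λ` would instead give conditional variance `σ_mult²·λ³`; we pin the
  conditional law, which is the property the model is meant to express.
  The variance law enters the code in exactly one place per module
  (branch coefficients `s²(λ) = aλ + b`), so an alternative scaling could
  be substituted without touching the quadrature machinery.
- **Downstream** (`σ_down`, in spikes/bin): additive `N(0, σ_down²)`,
  input-independent. In the **mixture** variant the draw is present only
  with probability `p_down` and exactly zero otherwise — an intermittent
  noise source that produces a large excess of zero counts while keeping
  a long nonzero tail. The Gaussian variant is the `p_down = 1` subset.
- **Spike generation `R`** is deterministic: the nearest nonnegative
  integer. Half-integer ties round up (`0.5 → 1`); any consistent tie rule
  affects only measure-zero events. The model attributes *all* variability
  to the three noise sources, reflecting that spike generation itself is
  nearly deterministic.

An optional history term adds `w·r_{t−1}` (spikes converted to input
units) inside `f`; simulation feeds back simulated counts sequentially,
likelihood evaluation conditions on the observed previous count, and the
first bin uses `r_0 = 0`.

## Likelihood

The response distribution factors through the stages: the upstream-noise
law pushed through `f` by change of variables
(`P_Λ(λ) = P_up(f⁻¹(λ) − x)·df⁻¹/dλ`, supported on `(β4, ∞)`), a
λ-dependent Gaussian smearing for the multiplicative stage, a convolution
(or `p_down`-blend) for the downstream stage, and integration of the
resulting density over `(k−½, k+½]` windows (with `(−∞, ½]` for zero) for
the count probabilities. These stage densities are exposed as tabulated
grids (`p_lambda`, `p_y`, `p_z`) for inspection and testing.

For computation, both post-nonlinearity stages are conditionally Gaussian
given `λ`, so each per-bin probability collapses to a one-dimensional
Gaussian expectation of branch CDFs with variance `s²(λ) = σ_mult²λ + b`
(`b = σ_down²` for the downstream-present branch, `b = 0` otherwise).
Each half-integer edge `e` is evaluated by one of three schemes, selected
by the ratio of the CDF transition width `w = s(e)/f′(f⁻¹(e))` to `σ_up`:

- `w ≥ 0.7·σ_up` (or `σ_up = 0`): 41-node Gauss–Hermite quadrature;
- `w < 0.7·σ_up`: the exact indicator part `Φ((f⁻¹(e) − x)/σ_up)` plus a
  Gauss–Legendre correction (25 nodes per half-interval, span ±12 widths,
  split at the transition) whose `x`-independent integrand values are
  precomputed per edge;
- degenerate branch (`s ≡ 0`): the indicator part alone.

The switch threshold and node counts were calibrated against adaptive
quadrature so the per-edge error stays below ~1e-9 in all regimes,
including vanishing noise scales where plain Gauss–Hermite fails. The
per-bin loop is compiled with numba; a 5000-bin log-likelihood evaluates
in ~20 ms on one core. Per-bin probabilities are floored at 1e-300 (with a
reported counter) so the optimizer never sees −∞.

`response_pmf` instead uses adaptive quadrature (`scipy.integrate.quad`
with a breakpoint at the transition) per edge, extending the truncation
point until the tail mass falls below 1e-8; it agrees with the compiled
path to ~1e-10 and with 10⁶-draw simulated histograms to JSD < 1e-5,
providing an internal dual route.

The LNP baseline likelihood is the Poisson log-pmf with rate `f(x_t)`.

### Numerical caveats

Stage-density grids integrate to 1 within 1e-6 (trapezoid) for models away
from total rectification. When `β4 = 0` and inputs sit far below threshold,
a large fraction of the output mass concentrates in a near-singular spike
at the softplus floor (the multiplicative kernel collapses as `λ → 0`); a
tabulated grid cannot represent that spike to 1e-6, but the likelihood and
pmf paths are unaffected because they never integrate a gridded density.
Quadrature spans are ±8.5 upstream SDs (truncation error < 1e-16).

## Fitting

Maximum likelihood via Nelder–Mead from randomized starts (default 8;
studies here use 3 for the reduced runs). Positivity and range constraints
are enforced by smooth reparameterization — log for `β1, β2, β4` and all
`σ`, logit for `p_down` — rather than clip-penalties, keeping the simplex
in the feasible region while leaving the search effectively unbounded
(bounds exclude only impossible parameter values). Convergence: simplex
size 1e-4 (transformed units), function tolerance 1e-6, at most 5000
evaluations per start; the highest-likelihood start is reported together
with all per-start diagnostics.

Starts: the nonlinearity is initialized by least squares on ~20
equal-count input-quantile bins of the mean counts, perturbed
multiplicatively by ±40% per parameter per start; noise levels are drawn
uniformly on `[0, s*]` where `s*` is the level at which that source alone
yields SNR 0.5 under the initializer's nonlinearity (found by bisection
with common random numbers, monotone in the level); `p_down` starts
uniform on `[0.05, 1]`. Degenerate data (constant counts or constant
inputs) fall back to a flat softplus with a warning.

## Metrics

- **SNR** `Var_s[E[r|s]] / E_s[Var[r|s]]`, Monte-Carlo with defaults
  2000 stimuli × 200 repeats; the numerator subtracts the Monte-Carlo
  variance of the conditional means so the estimator is unbiased at
  moderate repeat counts. A pre-quantization mode supports closed-form
  checks (linear regime with downstream noise: SNR = slope²/σ_down²).
- **Noise contribution** of a source: mean conditional response variance
  with that source alone, normalized across the three single-source
  values. Recovery studies report relative errors only for sources
  contributing at least 20%, since weakly contributing sources are poorly
  constrained in relative terms while barely affecting the response.
- **Jensen–Shannon divergence** in bits (base-2 logs, so disjoint supports
  give exactly 1); computed on raw count pmfs over a shared support.
- **Nonlinearity error**: `∫|f_true − f_est|·w(x) dx` with standard-normal
  weights (inputs are z-scored), trapezoid on ±5 SD; units spikes/bin.
- **Curvature** (rectification sharpness): max of `f″`, which for the
  softplus is `β1β2²/4` at `β2x + β3 = 0`.

## Preprocessing

The linear filter is the spike-triggered average decorrelated by the
stimulus autocovariance (Toeplitz solve; ridge fallback with a warning for
ill-conditioned stimuli), optionally smoothed by a zero-phase
Hamming-windowed-sinc low-pass with a 13 Hz cutoff. Data are partitioned
into contiguous windows of twice the filter's half-max width — measured on
the absolute filter around its global extremum, secondary lobes ignored —
rounded down to whole frames (a trailing partial window is dropped and
reported). Each window stores the mean filtered value and summed count;
filtered values are z-scored. Bins are half-open `[start, end)` in frame
units. This window length makes neighboring filtered values nearly
uncorrelated for white-noise stimuli (lag-1 autocorrelation below 0.2),
which supports the likelihood's independent-bins assumption.

## Synthetic suites and recovery studies

`generate_suite` draws models with `β1, β2 ~ U[0.5, 5]`, `β3 ~ U[−2, 2]`,
`β4 ~ U[0, 0.5]` — spanning strongly rectified to near-linear shapes — and
cycles dominant-source assignments (upstream, multiplicative, downstream,
all-mixed), so each source dominates in at least a quarter of datasets.
Noise levels are expressed relative to each source's single-source SNR-0.5
anchor under that dataset's true nonlinearity: dominant sources draw
`U[0.1, 1.0]×anchor`, minor sources `U[0, 0.3]×anchor`, and the mixed case
treats all three as dominant; `p_down ~ U[0.3, 1]` in the mixture variant.
Inputs are i.i.d. standard normal — emulating z-scored filtered stimuli
with decorrelated bins, but not the residual temporal correlations, firing
adaptation, or filter-estimation error of real recordings, so recovery
results bound estimator quality under the model's own assumptions rather
than under model mismatch. Datasets default to 5000 points (~8 minutes of
recording at ~100 ms bins). Everything regenerates deterministically from
the master seed.

`run_recovery` fits each dataset with the matching-variant multistage
model and the LNP baseline, reporting input-weighted nonlinearity errors,
per-source relative noise errors above the 20% contribution cutoff (the
mixture downstream source summarized by its effective SD
`√p_down·σ_down`), and each dataset's error as a percentage of its
nonlinearity output range over ±3 input SDs.

Problem sizes used in the shipped studies: the test suite runs the
Gaussian-variant study at 5 datasets × 5000 points × 3 starts and the
mixture-variant study at 4 datasets × 5000 points × 3 starts;
`scripts/acceptance.py` defaults to 10 Gaussian-variant datasets. The
full-scale designs (30 and 12 datasets, 8 starts) run through the same
code path via flags.

## Known limitations

- Counts per bin only; no sub-bin spike timing and no refractory
  dynamics. The single-lag history term is the only temporal dependence.
- The linear filter is estimated separately by reverse correlation, not
  jointly with the nonlinearity and noise parameters.
- The softplus is non-saturating by design; saturating response regimes
  need a different nonlinearity family.
- Likelihood accuracy is tied to the conditional-Gaussian structure of
  the post-nonlinearity stages; non-Gaussian multiplicative laws would
  need a different (slower) integration path.
- The recovery targets are distributional: suites are random draws from
  declared parameter ranges, so summary errors carry sampling variability
  across seeds at the reduced scale.
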