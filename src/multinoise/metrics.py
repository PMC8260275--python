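"""Quantitative comparison tools: SNR, Jensen-Shannon divergence,
input-weighted nonlinearity error, and nonlinearity curvature."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .model import MultistageModel, SoftplusParams, softplus_eval, spike_quantize
from .model import _sample_stage_z

__all__ = [
    "DiscreteDistribution",
    "snr",
    "noise_level_for_snr",
    "jsd",
    "nonlinearity_error",
    "curvature_max",
]


@dataclass
class DiscreteDistribution:
    """A probability vector over a shared integer count support."""

    probs: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1 within 1e-9")

    @classmethod
    def from_counts(cls, counts, support_size: Optional[int] = None, label: str = "") -> "DiscreteDistribution":
        counts = np.asarray(counts)
        n = support_size if support_size is not None else int(counts.max()) + 1
        p = np.bincount(counts, minlength=n).astype(float)
        return cls(p / p.sum(), label=label)


def _standard_normal_sampler(rng, n):
    return rng.standard_normal(n)


def snr(
    m: MultistageModel,
    input_sampler: Callable = None,
    n_stimuli: int = 2000,
    n_reps: int = 200,
    seed=None,
    quantize: bool = True,
) -> float:
    """Monte-Carlo response SNR: Var_s[E[r|s]] / E_s[Var[r|s]].

    Stimuli are drawn from ``input_sampler(rng, n)`` (standard normal by
    default); per stimulus, ``n_reps`` responses are simulated.  The
    numerator is corrected for the Monte-Carlo noise of the conditional
    means (law-of-total-variance correction), keeping the estimator unbiased
    at moderate ``n_reps``.  With ``quantize=False`` the continuous
    pre-quantization output is used.  A noiseless model (zero conditional
    variance) has no finite SNR and raises.
    """
    rng = np.random.default_rng(seed)
    sampler = input_sampler or _standard_normal_sampler
    s = np.asarray(sampler(rng, n_stimuli), dtype=float)
    X = np.repeat(s, n_reps)
    z = _sample_stage_z(m, X, rng)
    r = spike_quantize(z).astype(float) if quantize else z
    R = r.reshape(n_stimuli, n_reps)
    cond_mean = R.mean(axis=1)
    cond_var = R.var(axis=1, ddof=1)
    denom = float(cond_var.mean())
    if denom <= 0:
        raise ZeroDivisionError("noiseless model: conditional variance is zero (infinite SNR)")
    num = float(cond_mean.var(ddof=1)) - denom / n_reps
    return max(num, 0.0) / denom


def noise_level_for_snr(
    m: MultistageModel,
    source: str,
    target: float = 0.5,
    input_sampler: Callable = None,
    seed=None,
    rel_tol: float = 0.05,
    n_stimuli: int = 2000,
    n_reps: int = 200,
    max_level: float = 1e4,
) -> float:
    """Noise level of a single source giving the requested SNR, the other two
    sources zeroed and the nonlinearity fixed.

    SNR decreases monotonically in the level, so the level is found by
    bisection (common random numbers across evaluations) until the SNR is
    within ``rel_tol`` relative of the target.
    """
    if target <= 0:
        raise ValueError("target SNR must be positive")
    if source not in ("up", "mult", "down"):
        raise ValueError(f"unknown noise source {source!r}")

    base = m.with_noise(sigma_up=0.0, sigma_mult=0.0, sigma_down=0.0, p_down=1.0,
                        variant="gaussian")

    def snr_at(level):
        kw = {f"sigma_{source}": level}
        try:
            return snr(base.with_noise(**kw), input_sampler, n_stimuli, n_reps, seed=seed)
        except ZeroDivisionError:
            # level so small that quantized responses are deterministic
            return math.inf

    lo, hi = 1e-6, 1.0
    v_hi = snr_at(hi)
    while v_hi > target:
        hi *= 2.0
        if hi > max_level:
            raise RuntimeError(f"target SNR {target} unreachable below level {max_level} "
                               f"(snr({hi / 2})={v_hi:.3g})")
        v_hi = snr_at(hi)
    v_lo = snr_at(lo)
    if v_lo < target:
        raise RuntimeError(f"target SNR {target} unreachable: snr({lo})={v_lo:.3g} < target")
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        v = snr_at(mid)
        if abs(v - target) <= rel_tol * target:
            return mid
        if v > target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def jsd(P: DiscreteDistribution, Q: DiscreteDistribution) -> float:
    """Jensen-Shannon divergence in bits: JSD = (D_KL(P,R) + D_KL(Q,R))/2
    with R = (P+Q)/2.  Symmetric, always finite, and bounded by 1 bit;
    0*log(0/.) terms vanish by convention."""
    p, q = P.probs, Q.probs
    if p.shape != q.shape:
        raise ValueError("distributions must share a common support")
    r = 0.5 * (p + q)

    def kl(a):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / r[mask])))

    return 0.5 * (kl(p) + kl(q))


def nonlinearity_error(
    true_p: SoftplusParams,
    est_p: SoftplusParams,
    input_weights: Callable = None,
    span: float = 5.0,
    n_grid: int = 2001,
) -> float:
    """Input-distribution-weighted mean absolute difference between two
    nonlinearities, int |f_true(x) - f_est(x)| w(x) dx, in spikes per bin.

    ``input_weights`` is a density over inputs (standard normal by default,
    matching z-scored filtered stimuli); the quadrature spans ``+-span``.
    """
    x = np.linspace(-span, span, n_grid)
    if input_weights is None:
        w = np.exp(-0.5 * x ** 2) / math.sqrt(2 * math.pi)
    else:
        w = np.asarray(input_weights(x), dtype=float)
    diff = np.abs(np.asarray(softplus_eval(true_p, x)) - np.asarray(softplus_eval(est_p, x)))
    return float(np.trapezoid(diff * w, x))


def curvature_max(p: SoftplusParams, search_range: Optional[tuple] = None) -> float:
    """Maximum of the softplus second derivative, the rectification sharpness.

    Unrestricted, the maximum beta1*beta2^2/4 is attained where
    beta2*x + beta3 = 0; with a ``search_range`` the maximum is taken over
    that input interval.
    """
    xstar = -p.beta3 / p.beta2
    if search_range is None:
        return p.beta1 * p.beta2 ** 2 / 4.0
    lo, hi = search_range
    if lo <= xstar <= hi:
        return p.beta1 * p.beta2 ** 2 / 4.0
    from .model import softplus_derivatives
    return float(max(softplus_derivatives(p, lo)[1], softplus_derivatives(p, hi)[1]))
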