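"""Core model types, the softplus nonlinearity, and the forward simulator.

The multistage noise model describes a neuron's spike count ``r_t`` in a time
bin as a linear-nonlinear cascade corrupted by noise at three stages::

    r_t = R[ n_mult,t * f(x_t + n_up,t) + n_down,t ]

where ``x_t`` is the (z-scored) linearly filtered stimulus, ``f`` is a
softplus nonlinearity, ``n_up`` is additive Gaussian noise upstream of the
nonlinearity, the multiplicative stage produces an output with conditional
mean ``lambda = f(x + n_up)`` and conditional variance ``sigma_mult**2 *
lambda``, ``n_down`` is additive downstream noise (Gaussian, or a
Gaussian/zero mixture present with probability ``p_down``), and ``R`` rounds
to the nearest nonnegative integer.  Spike generation itself is
deterministic: all variability comes from the three noise sources.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

__all__ = [
    "SoftplusParams",
    "NoiseParams",
    "MultistageModel",
    "BinnedDataset",
    "CountPMF",
    "softplus_eval",
    "softplus_inverse",
    "softplus_derivatives",
    "spike_quantize",
    "sample_downstream",
    "simulate_responses",
]

_EXP_CLIP = 700.0  # exp overflow guard


@dataclass(frozen=True)
class SoftplusParams:
    """Parameters of the softplus nonlinearity f(x) = b1*ln(1+exp(b2*x+b3))+b4.

    beta1 : output scale (spikes per bin), > 0
    beta2 : input gain (per z-scored input unit), > 0
    beta3 : input offset (dimensionless)
    beta4 : output offset (spikes per bin)

    With beta1, beta2 > 0 the function is strictly increasing and convex,
    with range (beta4, inf), so its inverse exists.
    """

    beta1: float
    beta2: float
    beta3: float
    beta4: float

    def __post_init__(self) -> None:
        vals = (self.beta1, self.beta2, self.beta3, self.beta4)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite softplus parameters: {vals}")
        if self.beta1 <= 0 or self.beta2 <= 0:
            raise ValueError("beta1 and beta2 must be positive (monotone increasing nonlinearity)")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta1, self.beta2, self.beta3, self.beta4], dtype=float)


@dataclass(frozen=True)
class NoiseParams:
    """Strengths of the three noise sources.

    sigma_up   : SD of upstream additive Gaussian noise (z-scored input units)
    sigma_mult : multiplicative noise scale; the post-nonlinearity value has
                 conditional variance sigma_mult**2 * lambda given lambda
    sigma_down : SD of downstream additive noise (spikes per bin)
    p_down     : probability the downstream noise is present in a bin
    variant    : "gaussian" (p_down fixed at 1) or "mixture"
    """

    sigma_up: float
    sigma_mult: float
    sigma_down: float
    p_down: float = 1.0
    variant: Literal["gaussian", "mixture"] = "gaussian"

    def __post_init__(self) -> None:
        if min(self.sigma_up, self.sigma_mult, self.sigma_down) < 0:
            raise ValueError("noise SDs must be nonnegative")
        if not (0.0 <= self.p_down <= 1.0):
            raise ValueError("p_down must lie in [0, 1]")
        if self.variant not in ("gaussian", "mixture"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "gaussian" and self.p_down != 1.0:
            raise ValueError("gaussian variant requires p_down == 1")
        if not all(map(math.isfinite, (self.sigma_up, self.sigma_mult, self.sigma_down, self.p_down))):
            raise ValueError("non-finite noise parameters")


@dataclass(frozen=True)
class MultistageModel:
    """A full multistage noise model: nonlinearity + noise (+ optional history).

    ``history_weight``, when set, adds w * r_{t-1} to the nonlinearity input
    (spike counts converted to input units), modelling dependence on the
    response in the previous time bin.
    """

    nonlinearity: SoftplusParams
    noise: NoiseParams
    history_weight: Optional[float] = None

    def with_noise(self, **kwargs) -> "MultistageModel":
        return replace(self, noise=replace(self.noise, **kwargs))

    def to_dict(self) -> dict:
        d = {
            "beta1": self.nonlinearity.beta1,
            "beta2": self.nonlinearity.beta2,
            "beta3": self.nonlinearity.beta3,
            "beta4": self.nonlinearity.beta4,
            "sigma_up": self.noise.sigma_up,
            "sigma_mult": self.noise.sigma_mult,
            "sigma_down": self.noise.sigma_down,
            "p_down": self.noise.p_down,
            "variant": self.noise.variant,
        }
        if self.history_weight is not None:
            d["history_weight"] = self.history_weight
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "MultistageModel":
        nl = SoftplusParams(d["beta1"], d["beta2"], d["beta3"], d["beta4"])
        noise = NoiseParams(
            d["sigma_up"], d["sigma_mult"], d["sigma_down"],
            d.get("p_down", 1.0), d.get("variant", "gaussian"),
        )
        return cls(nl, noise, d.get("history_weight"))

    @classmethod
    def from_json(cls, path) -> "MultistageModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class BinnedDataset:
    """Paired filtered-stimulus values and spike counts, one entry per time bin."""

    inputs: np.ndarray
    counts: np.ndarray
    bin_width: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.inputs.ndim != 1 or self.counts.ndim != 1:
            raise ValueError("inputs and counts must be 1-D arrays")
        if len(self.inputs) != len(self.counts) or len(self.inputs) < 1:
            raise ValueError("inputs and counts must have equal length >= 1")
        if not np.all(np.isfinite(self.inputs)):
            raise ValueError("inputs must be finite")
        if not np.all(self.counts == np.floor(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative integers")
        self.counts = self.counts.astype(np.int64)
        if not (self.bin_width > 0):
            raise ValueError("bin_width must be positive")

    def __len__(self) -> int:
        return len(self.inputs)


@dataclass
class CountPMF:
    """Probability mass over spike counts 0..r_max for a fixed input."""

    probs: np.ndarray
    r_max: int
    tail_mass: float = 0.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < -1e-12):
            raise ValueError("probabilities must be nonnegative")
        self.probs = np.clip(self.probs, 0.0, None)
        total = self.probs.sum() + self.tail_mass
        if not (1 - 1e-6 <= total <= 1 + 1e-6):
            raise ValueError(f"count pmf mass {total} deviates from 1 beyond tolerance")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.r_max + 1)

    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))


# ---------------------------------------------------------------------------
# softplus calculus
# ---------------------------------------------------------------------------

def softplus_eval(p: SoftplusParams, x) -> np.ndarray | float:
    """Evaluate f(x) = beta1*ln(1+exp(beta2*x+beta3)) + beta4, overflow-safe.

    For large positive arguments ln(1+e^u) ~ u; for large negative ones the
    log1p form is exact.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("softplus_eval requires finite inputs")
    u = p.beta2 * x + p.beta3
    out = p.beta1 * np.where(u > 30.0, u, np.log1p(np.exp(np.minimum(u, 30.0)))) + p.beta4
    return float(out) if out.ndim == 0 else out


def softplus_inverse(p: SoftplusParams, lam) -> np.ndarray | float:
    """Inverse of the softplus: x with f(x) = lam, defined for lam > beta4.

    Uses x = (ln(expm1((lam-beta4)/beta1)) - beta3)/beta2, with the expm1
    branch keeping accuracy as lam approaches the beta4 asymptote.
    """
    lam = np.asarray(lam, dtype=float)
    t = (lam - p.beta4) / p.beta1
    if np.any(t <= 0):
        raise ValueError("softplus_inverse requires lam > beta4")
    with np.errstate(over="ignore"):
        inner = np.where(t > 30.0, t, np.log(np.expm1(np.minimum(t, 30.0))))
    out = (inner - p.beta3) / p.beta2
    return float(out) if out.ndim == 0 else out


def softplus_derivatives(p: SoftplusParams, x) -> tuple:
    """First and second derivatives of the softplus at x.

    f'(x) = b1*b2*sigma(u), f''(x) = b1*b2^2*sigma(u)*(1-sigma(u)) with
    u = b2*x + b3 and sigma the logistic function; both are nonnegative.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("softplus_derivatives requires finite inputs")
    u = p.beta2 * x + p.beta3
    sig = 1.0 / (1.0 + np.exp(-np.clip(u, -_EXP_CLIP, _EXP_CLIP)))
    first = p.beta1 * p.beta2 * sig
    second = p.beta1 * p.beta2 ** 2 * sig * (1.0 - sig)
    if first.ndim == 0:
        return float(first), float(second)
    return first, second


def spike_quantize(z) -> np.ndarray | int:
    """Round to the nearest nonnegative integer; half-integer ties round up."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("spike_quantize requires finite inputs")
    out = np.maximum(np.floor(z + 0.5), 0.0).astype(np.int64)
    return int(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def sample_downstream(noise: NoiseParams, n: int, seed=None, rng=None) -> np.ndarray:
    """Draw n downstream-noise values: N(0, sigma_down^2) with probability
    p_down, exactly zero otherwise."""
    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = noise.sigma_down * rng.standard_normal(n)
    if noise.p_down < 1.0:
        present = rng.random(n) < noise.p_down
        draws = np.where(present, draws, 0.0)
    return draws


def _sample_stage_z(m: MultistageModel, inputs: np.ndarray, rng) -> np.ndarray:
    """Continuous pre-quantization output z for i.i.d. bins (no history)."""
    noise = m.noise
    x = inputs
    if noise.sigma_up > 0:
        x = x + noise.sigma_up * rng.standard_normal(len(x))
    lam = softplus_eval(m.nonlinearity, x)
    lam = np.maximum(lam, 0.0)  # beta4 >= 0 in practice; guard the variance
    y = lam
    if noise.sigma_mult > 0:
        y = lam + noise.sigma_mult * np.sqrt(lam) * rng.standard_normal(len(x))
    z = y + sample_downstream(noise, len(x), rng=rng)
    return z


def simulate_responses(
    m: MultistageModel,
    inputs,
    seed=None,
    prev_count: Optional[int] = None,
    rng=None,
) -> np.ndarray:
    """Simulate spike counts for each input bin.

    Per bin: draw upstream noise, pass through the softplus, apply the
    multiplicative stage (conditional mean lambda, conditional variance
    sigma_mult^2 * lambda), add a downstream draw, and quantize.  With
    ``history_weight`` set the bins are simulated sequentially, feeding each
    simulated count back into the next bin's nonlinearity input.
    """
    inputs = np.asarray(inputs, dtype=float)
    if not np.all(np.isfinite(inputs)):
        raise ValueError("inputs must be finite")
    if rng is None:
        rng = np.random.default_rng(seed)

    if m.history_weight is None:
        return spike_quantize(_sample_stage_z(m, inputs, rng))

    w = float(m.history_weight)
    noise = m.noise
    n = len(inputs)
    up = noise.sigma_up * rng.standard_normal(n) if noise.sigma_up > 0 else np.zeros(n)
    mult = rng.standard_normal(n)
    down = sample_downstream(noise, n, rng=rng)
    counts = np.zeros(n, dtype=np.int64)
    prev = 0 if prev_count is None else int(prev_count)
    for t in range(n):
        lam = max(softplus_eval(m.nonlinearity, inputs[t] + w * prev + up[t]), 0.0)
        y = lam + noise.sigma_mult * math.sqrt(lam) * mult[t] if noise.sigma_mult > 0 else lam
        counts[t] = spike_quantize(y + down[t])
        prev = counts[t]
    return counts
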