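"""Exact spike-count distribution and dataset log-likelihood.

The response distribution is built in stages mirroring the generative model:
the upstream-noise-corrupted input passes through the nonlinearity
(change of variables, ``p_lambda``), the multiplicative stage smears it with
a lambda-dependent Gaussian kernel (``p_y``), the downstream stage convolves
with the downstream noise law (``p_z``), and integrating the resulting
density over half-integer windows gives the count pmf (``response_pmf``).

Because both post-nonlinearity stages are conditionally Gaussian given
lambda, the count probabilities reduce to a single expectation over the
upstream noise,

    P(r = k | x) = E_u[ F(k + 1/2 | lam) - F(k - 1/2 | lam) ],
    lam = f(x + u),  u ~ N(0, sigma_up^2),

where F(.|lam) is a Gaussian (or two-component Gaussian mixture) CDF.  The
dataset log-likelihood evaluates this expectation with a calibrated hybrid
quadrature (see _kernels); ``response_pmf`` uses independent adaptive
quadrature with breakpoints at the CDF transition points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln, ndtr, roots_hermitenorm, roots_legendre

from . import _kernels
from .model import (
    BinnedDataset,
    CountPMF,
    MultistageModel,
    SoftplusParams,
    softplus_derivatives,
    softplus_eval,
    softplus_inverse,
)

__all__ = [
    "DensityGrid",
    "p_lambda",
    "p_y",
    "p_z",
    "response_pmf",
    "log_likelihood",
    "log_likelihood_lnp",
]

_GH_NODES = 41          # Gauss-Hermite nodes for smooth edges
_LOC_NODES = 25         # Gauss-Legendre nodes per half-interval, sharp edges
_LOC_SPAN = 12.0        # correction support in units of the transition width
_LOCAL_RATIO = 0.7      # below this width/sigma_up ratio, use the localized scheme
_SIGMA_UP_TINY = 1e-12
_PROB_FLOOR = 1e-300
_SPAN_SD = 8.5          # integration span in upstream-noise SDs

_gh_g, _gh_w = roots_hermitenorm(_GH_NODES)
_gh_w = _gh_w / _gh_w.sum()
_gl_g, _gl_w = roots_legendre(_LOC_NODES)


# ---------------------------------------------------------------------------
# branch decomposition: conditional variance s^2(lam) = a*lam + b per branch
# ---------------------------------------------------------------------------

def _branches(m: MultistageModel):
    ns = m.noise
    a = ns.sigma_mult ** 2
    if ns.variant == "gaussian" or ns.p_down >= 1.0 or ns.sigma_down == 0.0:
        return [(1.0, a, ns.sigma_down ** 2)]
    if ns.p_down <= 0.0:
        return [(1.0, a, 0.0)]
    return [(ns.p_down, a, ns.sigma_down ** 2), (1.0 - ns.p_down, a, 0.0)]


def _edge_tables(nl: SoftplusParams, su: float, branches, max_count: int):
    """Precompute per-(edge, branch) quadrature scheme and localized tables.

    Edge index m corresponds to edge value m - 0.5, m = 1..max_count+1.
    """
    n_edges = max_count + 2
    nbr = len(branches)
    nloc = 2 * _LOC_NODES
    edge_val = np.arange(n_edges) - 0.5
    scheme = np.full((n_edges, nbr), _kernels.SCHEME_PLAIN, dtype=np.int64)
    xi = np.full(n_edges, np.nan)
    wloc = np.zeros((n_edges, nbr))
    locA = np.zeros((n_edges, nbr, nloc))
    locHW = np.zeros((n_edges, nbr, nloc))

    v_nodes = np.concatenate([-_LOC_SPAN * (_gl_g[::-1] + 1) / 2, _LOC_SPAN * (_gl_g + 1) / 2])
    v_weights = np.concatenate([(_LOC_SPAN / 2) * _gl_w[::-1], (_LOC_SPAN / 2) * _gl_w])

    for mi in range(1, n_edges):
        e = edge_val[mi]
        above = e > nl.beta4
        if above:
            xi_e = float(softplus_inverse(nl, e))
            xi[mi] = xi_e
            fp = float(softplus_derivatives(nl, xi_e)[0])
        for j, (_, a, b) in enumerate(branches):
            s_e2 = a * e + b
            if s_e2 <= 0.0:
                # degenerate branch: CDF is an indicator in lam
                scheme[mi, j] = _kernels.SCHEME_EXACT
                continue
            if not above:
                scheme[mi, j] = _kernels.SCHEME_PLAIN
                continue
            w = math.sqrt(s_e2) / fp
            if su <= 0 or w >= _LOCAL_RATIO * su:
                scheme[mi, j] = _kernels.SCHEME_PLAIN
                continue
            scheme[mi, j] = _kernels.SCHEME_LOCAL
            wloc[mi, j] = w
            pos = xi_e + w * v_nodes
            lam = softplus_eval(nl, pos)
            s = np.sqrt(np.maximum(a * lam + b, 0.0))
            with np.errstate(divide="ignore"):
                z = np.where(s > 0, (e - lam) / np.where(s > 0, s, 1.0),
                             np.where(lam <= e, np.inf, -np.inf))
            H = ndtr(z) - (v_nodes < 0)
            locA[mi, j] = pos
            locHW[mi, j] = v_weights * H
    return edge_val, scheme, xi, wloc, locA, locHW


def _kernel_args(m: MultistageModel, max_count: int):
    nl = m.nonlinearity
    su = m.noise.sigma_up
    branches = _branches(m)
    nbr = len(branches)
    brw = np.array([br[0] for br in branches])
    a = np.array([br[1] for br in branches])
    b = np.array([br[2] for br in branches])
    tables = _edge_tables(nl, su, branches, max_count)
    return (su, nl.beta1, nl.beta2, nl.beta3, nl.beta4,
            brw, a, b, nbr, _gh_g, _gh_w) + tables


def _effective_inputs(m: MultistageModel, d: BinnedDataset) -> np.ndarray:
    """Nonlinearity inputs, augmented by the observed-response history term."""
    x = d.inputs
    if m.history_weight is None:
        return x
    prev = np.concatenate([[0], d.counts[:-1]]).astype(float)
    return x + m.history_weight * prev


# ---------------------------------------------------------------------------
# stage densities (change of variables / lambda-dependent smearing)
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """A one-dimensional density tabulated on strictly increasing points.

    ``atom`` holds (location, mass) for degenerate point-mass components
    (e.g. the sigma_up -> 0 limit of the nonlinearity-output distribution,
    or the absent-noise branch of the mixture downstream stage).
    """

    points: np.ndarray
    values: np.ndarray
    lo: float
    hi: float
    atom: Optional[tuple] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.points.size and np.any(np.diff(self.points) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")

    def integral(self) -> float:
        total = float(np.trapezoid(self.values, self.points)) if self.points.size > 1 else 0.0
        if self.atom is not None:
            total += self.atom[1]
        return total

    def mean(self) -> float:
        mu = float(np.trapezoid(self.points * self.values, self.points)) if self.points.size > 1 else 0.0
        if self.atom is not None:
            mu += self.atom[0] * self.atom[1]
        return mu


def _upstream_grid(m: MultistageModel, x: float, n: int = 2001):
    su = m.noise.sigma_up
    u = np.linspace(x - _SPAN_SD * su, x + _SPAN_SD * su, n)
    dens = np.exp(-0.5 * ((u - x) / su) ** 2) / (su * math.sqrt(2 * math.pi))
    return u, dens


def p_lambda(m: MultistageModel, x: float, n_grid: int = 16001) -> DensityGrid:
    """Density of lambda = f(x + n_up): the upstream noise law pushed through
    the nonlinearity, P_Lambda(lam) = P_up(f^-1(lam) - x) * d f^-1 / d lam.

    The density spreads where f' is large and compresses where f' is small.
    For sigma_up = 0 a point mass at f(x) is returned.
    """
    nl = m.nonlinearity
    if m.noise.sigma_up <= _SIGMA_UP_TINY:
        lam0 = float(softplus_eval(nl, x))
        return DensityGrid(np.empty(0), np.empty(0), lam0, lam0, atom=(lam0, 1.0))
    u, dens = _upstream_grid(m, x, n_grid)
    lam = softplus_eval(nl, u)
    fprime = softplus_derivatives(nl, u)[0]
    vals = dens / np.maximum(fprime, 1e-300)
    keep = np.concatenate([[True], np.diff(lam) > 0])
    return DensityGrid(lam[keep], vals[keep], float(lam[0]), float(lam[-1]))


def _mixture_density_at(m: MultistageModel, x: float, z: np.ndarray,
                        include_down: bool, n_u: int = 2001) -> np.ndarray:
    """Density of the (pre-quantization) output evaluated at points z,
    integrating the conditionally-Gaussian kernel over the upstream noise."""
    nl, ns = m.nonlinearity, m.noise
    a = ns.sigma_mult ** 2

    def kernel(zc, lam):
        # density matrix over (z, lam)
        var = a * lam + (ns.sigma_down ** 2 if include_down else 0.0)
        if include_down and ns.variant == "mixture" and ns.p_down < 1.0:
            var0 = a * lam
            return (ns.p_down * _gauss_pdf(zc[:, None], lam, var)
                    + (1 - ns.p_down) * _gauss_pdf(zc[:, None], lam, var0))
        return _gauss_pdf(zc[:, None], lam, var)

    if ns.sigma_up <= _SIGMA_UP_TINY:
        lam0 = np.array([float(softplus_eval(nl, x))])
        return kernel(np.asarray(z), lam0)[:, 0]
    u, dens = _upstream_grid(m, x, n_u)
    lam = np.asarray(softplus_eval(nl, u))
    out = np.empty(len(z))
    chunk = max(1, 10_000_000 // len(u))  # bound the (z, u) work matrix
    for i in range(0, len(z), chunk):
        zc = np.asarray(z[i:i + chunk])
        out[i:i + chunk] = np.trapezoid(kernel(zc, lam) * dens[None, :], u, axis=1)
    return out


def _gauss_pdf(z, mu, var):
    var = np.asarray(var, dtype=float)
    out = np.zeros(np.broadcast(z, mu, var).shape)
    pos = np.broadcast_to(var, out.shape) > 0
    sd = np.sqrt(np.where(pos, var, 1.0))
    zz = (np.broadcast_to(z, out.shape) - np.broadcast_to(mu, out.shape)) / sd
    out = np.where(pos, np.exp(-0.5 * zz ** 2) / (sd * math.sqrt(2 * math.pi)), 0.0)
    return out


def _output_grid(m: MultistageModel, x: float, include_down: bool, n: int = 20001):
    """Evaluation grid for the stage-2/3 densities: spans the full output
    range (each lambda spreads by 8.5 of its own kernel SD) and is refined
    near the softplus floor where the lambda-scaled kernel narrows."""
    nl, ns = m.nonlinearity, m.noise
    su = ns.sigma_up
    lam = np.asarray(softplus_eval(nl, np.linspace(x - _SPAN_SD * su, x + _SPAN_SD * su, 201)))
    a = ns.sigma_mult ** 2
    b = ns.sigma_down ** 2 if include_down else 0.0
    s = np.sqrt(a * lam + b)
    lo = float(np.min(lam - 8.5 * s)) - 1e-12
    hi = float(np.max(lam + 8.5 * s)) + 1e-9
    base = np.linspace(lo, hi, n)
    lam_lo, lam_hi = float(lam.min()), float(lam.max())
    # refine around the floor where the kernel can be much narrower than
    # the base spacing
    if a > 0 and lam_lo < 0.1 * (lam_hi - lam_lo + 1e-12):
        fine_hi = min(max(lam_lo, 1e-8) + 1.0, lam_hi)
        fine = nl.beta4 + np.geomspace(1e-9, fine_hi - nl.beta4, 600)
        mirror = nl.beta4 - np.geomspace(1e-9, min(1.0, nl.beta4 - lo + 1e-9), 200)
        mirror = mirror[mirror > lo]
        base = np.unique(np.concatenate([base, fine, mirror, [nl.beta4]]))
    return base


def p_y(m: MultistageModel, x: float) -> DensityGrid:
    """Density after the multiplicative stage:
    P_Y(y) = int P_Lambda(lam) N(y; lam, sigma_mult^2 lam) dlam.

    A lambda-dependent-kernel smoothing, similar to a convolution but with
    the kernel widening as lambda grows.  sigma_mult = 0 returns p_lambda.
    """
    if m.noise.sigma_mult == 0.0:
        return p_lambda(m, x)
    z = _output_grid(m, x, include_down=False)
    vals = _mixture_density_at(m, x, z, include_down=False)
    return DensityGrid(z, vals, float(z[0]), float(z[-1]))


def p_z(m: MultistageModel, x: float) -> DensityGrid:
    """Density after the downstream stage: the convolution of P_Y with the
    downstream noise law (Gaussian variant), or the p_down-weighted blend of
    the convolved and unconvolved densities (mixture variant)."""
    ns = m.noise
    if ns.sigma_down == 0.0 or ns.p_down == 0.0:
        return p_y(m, x)
    z = _output_grid(m, x, include_down=True)
    vals = _mixture_density_at(m, x, z, include_down=True)
    atom = None
    if ns.sigma_up <= _SIGMA_UP_TINY and ns.sigma_mult == 0.0 and ns.variant == "mixture" and ns.p_down < 1.0:
        lam0 = float(softplus_eval(m.nonlinearity, x))
        # absent-noise branch contributes a point mass
        vals = ns.p_down * _gauss_pdf(z, lam0, ns.sigma_down ** 2)
        atom = (lam0, 1.0 - ns.p_down)
    return DensityGrid(z, vals, float(z[0]), float(z[-1]), atom=atom)


# ---------------------------------------------------------------------------
# count pmf and likelihood
# ---------------------------------------------------------------------------

def _edge_cdf_quad(m: MultistageModel, x: float, e: float) -> float:
    """P(z <= e | x) by adaptive quadrature over the upstream noise, with an
    integration breakpoint at the CDF transition point f^-1(e) - x."""
    nl, ns = m.nonlinearity, m.noise
    branches = _branches(m)
    su = ns.sigma_up

    def branch_cdf(lam, a, b):
        var = a * lam + b
        if var <= 0:
            return 1.0 if lam <= e else 0.0
        return float(ndtr((e - lam) / math.sqrt(var)))

    if su <= _SIGMA_UP_TINY:
        lam0 = float(softplus_eval(nl, x))
        return sum(w * branch_cdf(lam0, a, b) for w, a, b in branches)

    def integrand(u):
        lam = float(softplus_eval(nl, x + u))
        dens = math.exp(-0.5 * (u / su) ** 2) / (su * math.sqrt(2 * math.pi))
        return dens * sum(w * branch_cdf(lam, a, b) for w, a, b in branches)

    lim = 10.0 * su
    pts = []
    if e > nl.beta4:
        ustar = float(softplus_inverse(nl, e)) - x
        if -lim < ustar < lim:
            pts.append(ustar)
    val, _ = quad(integrand, -lim, lim, points=pts or None, limit=400,
                  epsabs=1e-12, epsrel=1e-10)
    return val


def response_pmf(m: MultistageModel, x: float, r_max: Optional[int] = None,
                 tail_tol: float = 1e-8) -> CountPMF:
    """Probability mass over spike counts for a single input value.

    P(r=0) integrates the output density up to 0.5; P(r=k) integrates over
    (k-1/2, k+1/2].  ``r_max`` is extended until the mass beyond it falls
    below ``tail_tol``.
    """
    nl, ns = m.nonlinearity, m.noise
    # initial truncation guess: mean output + 8 total SDs
    lam_hi = float(softplus_eval(nl, x + _SPAN_SD * ns.sigma_up))
    fp = float(softplus_derivatives(nl, x)[0])
    total_sd = math.sqrt(ns.sigma_mult ** 2 * lam_hi + ns.sigma_down ** 2
                         + (fp * ns.sigma_up) ** 2)
    guess = max(2, int(math.ceil(lam_hi + 8 * total_sd)))
    target = r_max if r_max is not None else guess

    cdf_vals = [_edge_cdf_quad(m, x, k + 0.5) for k in range(target + 1)]
    while 1.0 - cdf_vals[-1] > tail_tol:
        if r_max is not None and len(cdf_vals) - 1 >= r_max + 200:
            raise RuntimeError("response_pmf truncation failed to converge")
        if len(cdf_vals) > 100000:
            raise RuntimeError("response_pmf truncation failed to converge")
        cdf_vals.append(_edge_cdf_quad(m, x, len(cdf_vals) - 0.5))
    cdf = np.asarray(cdf_vals)
    probs = np.diff(np.concatenate([[0.0], cdf]))
    probs = np.clip(probs, 0.0, None)
    tail = max(0.0, 1.0 - float(cdf[-1]))
    return CountPMF(probs=probs, r_max=len(probs) - 1, tail_mass=tail)


def _bin_probabilities(m: MultistageModel, x: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Vectorized P(r_t | x_t) via the compiled hybrid-quadrature kernel."""
    args = _kernel_args(m, int(r.max()))
    return _kernels.binprobs_kernel(
        np.ascontiguousarray(x, dtype=float), np.ascontiguousarray(r, dtype=np.int64),
        *args)


def log_likelihood(m: MultistageModel, d: BinnedDataset,
                   return_details: bool = False):
    """Dataset log-likelihood sum_t log P(r_t | x_t), bins independent.

    With ``history_weight`` set, the nonlinearity input of bin t is augmented
    by w * r_{t-1} using the observed previous count (r_0 = 0 for the first
    bin).  Per-bin probabilities are floored at 1e-300; the number of floored
    bins is reported in the details and via a warning.
    """
    x = _effective_inputs(m, d)
    args = _kernel_args(m, int(d.counts.max()))
    ll, n_floored = _kernels.loglik_kernel(
        np.ascontiguousarray(x, dtype=float),
        np.ascontiguousarray(d.counts, dtype=np.int64),
        *args, _PROB_FLOOR)
    if n_floored:
        warnings.warn(f"{n_floored} bins hit the probability floor", RuntimeWarning)
    if return_details:
        return float(ll), {"n_floored": int(n_floored)}
    return float(ll)


def log_likelihood_lnp(p: SoftplusParams, d: BinnedDataset,
                       history_weight: Optional[float] = None) -> float:
    """Poisson (LNP) log-likelihood: sum_t r_t log f(x_t) - f(x_t) - log r_t!."""
    x = d.inputs
    if history_weight is not None:
        prev = np.concatenate([[0], d.counts[:-1]]).astype(float)
        x = x + history_weight * prev
    rates = np.asarray(softplus_eval(p, x), dtype=float)
    if np.any(rates <= 0):
        return -1e290
    r = d.counts
    with np.errstate(divide="ignore"):
        logr = np.where(r > 0, np.log(rates), 0.0)
    return float(np.sum(r * logr - rates - gammaln(r + 1.0)))
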