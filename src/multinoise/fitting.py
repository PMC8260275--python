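"""Multi-start bounded Nelder-Mead maximum-likelihood estimation.

Both the multistage noise model and the LNP baseline are fit by maximizing
their exact log-likelihoods with derivative-free Nelder-Mead searches
started from several randomized initial conditions; the best converged
start is reported.  Parameter positivity and range constraints are imposed
by smooth reparameterization (log for scales, logit for p_down) rather than
clipping, so the simplex always moves through feasible models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.optimize import least_squares, minimize

from .likelihood import log_likelihood, log_likelihood_lnp
from .model import BinnedDataset, MultistageModel, NoiseParams, SoftplusParams, softplus_eval

__all__ = [
    "FitConfig",
    "FitResult",
    "StartRecord",
    "init_nonlinearity_ls",
    "random_starts",
    "fit_mle",
    "fit_lnp",
]

_LOG_FLOOR = -40.0  # lower clamp for log-transformed scale parameters


@dataclass
class FitConfig:
    """Optimizer settings for the multi-start search.

    n_starts       : number of randomized initial conditions (the reference
                     procedure used 5-10)
    perturb_frac   : multiplicative perturbation of the least-squares
                     nonlinearity estimate used to seed each start (+-40%)
    xatol, fatol   : Nelder-Mead simplex-size and function tolerances
                     (transformed units)
    maxfev         : maximum likelihood evaluations per start
    snr_anchor     : single-source SNR defining the upper scale of the
                     uniform noise initial conditions
    """

    n_starts: int = 8
    seed: Optional[int] = None
    perturb_frac: float = 0.40
    xatol: float = 1e-4
    fatol: float = 1e-6
    maxfev: int = 5000
    snr_anchor: float = 0.5
    anchor_n_stimuli: int = 1000
    anchor_n_reps: int = 100

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not (0 <= self.perturb_frac < 1):
            raise ValueError("perturb_frac must lie in [0, 1)")


@dataclass
class StartRecord:
    init_params: dict
    final_params: dict
    loglik: float
    converged: bool
    n_evals: int


@dataclass
class FitResult:
    """Outcome of a multi-start fit: the argmax model plus per-start diagnostics."""

    best_params: object  # MultistageModel or SoftplusParams
    best_loglik: float
    per_start: List[StartRecord] = field(default_factory=list)
    config: Optional[FitConfig] = None
    seed: Optional[int] = None
    variant: str = ""

    def to_dict(self) -> dict:
        best = (self.best_params.to_dict() if isinstance(self.best_params, MultistageModel)
                else vars(self.best_params).copy() if hasattr(self.best_params, "__dict__")
                else {"beta1": self.best_params.beta1, "beta2": self.best_params.beta2,
                      "beta3": self.best_params.beta3, "beta4": self.best_params.beta4})
        return {
            "best_params": best,
            "best_loglik": self.best_loglik,
            "variant": self.variant,
            "seed": self.seed,
            "per_start": [
                {"init": s.init_params, "final": s.final_params, "loglik": s.loglik,
                 "converged": s.converged, "n_evals": s.n_evals}
                for s in self.per_start
            ],
        }


# ---------------------------------------------------------------------------
# least-squares nonlinearity initializer
# ---------------------------------------------------------------------------

def init_nonlinearity_ls(d: BinnedDataset, n_bins: int = 20) -> SoftplusParams:
    """Least-squares softplus fit to quantile-binned mean spike counts.

    Inputs are grouped into ~``n_bins`` equal-count quantile bins; the
    softplus is fit to (mean input, mean count) pairs.  Degenerate data
    (constant counts) fall back to a near-flat softplus with a warning.
    """
    x, r = d.inputs, d.counts.astype(float)
    if len(d) < 20:
        raise ValueError("need at least 20 bins for the least-squares initializer")
    if np.all(r == r[0]):
        warnings.warn("all counts equal; returning a flat-softplus fallback", RuntimeWarning)
        return SoftplusParams(1e-3, 1.0, 0.0, max(float(r[0]), 0.0))
    if np.ptp(x) == 0:
        warnings.warn("constant inputs; returning a flat softplus at the mean count",
                      RuntimeWarning)
        return SoftplusParams(1e-3, 1.0, 0.0, max(float(r.mean()), 1e-3))

    n_bins = min(n_bins, max(len(d) // 5, 2))
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    xm = np.array([x[idx == b].mean() for b in range(n_bins) if np.any(idx == b)])
    rm = np.array([r[idx == b].mean() for b in range(n_bins) if np.any(idx == b)])

    sx = max(float(np.std(x)), 1e-6)
    span = max(float(rm.max() - rm.min()), 1e-3)
    theta0 = np.array([
        math.log(max(span / 2.0, 1e-3)),   # log beta1
        math.log(1.5 / sx),                 # log beta2
        0.0,                                # beta3
        math.log(max(float(rm.min()), 1e-3)),  # log beta4
    ])

    def resid(theta):
        p = SoftplusParams(math.exp(theta[0]), math.exp(theta[1]), theta[2], math.exp(theta[3]))
        return np.asarray(softplus_eval(p, xm)) - rm

    sol = least_squares(resid, theta0, method="lm", max_nfev=4000)
    t = sol.x
    return SoftplusParams(math.exp(t[0]), math.exp(t[1]), float(t[2]), math.exp(t[3]))


# ---------------------------------------------------------------------------
# randomized starts
# ---------------------------------------------------------------------------

def _noise_anchor_scales(d: BinnedDataset, nl: SoftplusParams, cfg: FitConfig, rng) -> dict:
    """Upper scales for uniform noise initial conditions: the level at which
    each source alone yields the anchor SNR under the initializer's
    nonlinearity.  Falls back to order-of-magnitude defaults if a source
    cannot reach the anchor (e.g. a nearly flat nonlinearity)."""
    from .metrics import noise_level_for_snr

    base = MultistageModel(nl, NoiseParams(0.0, 0.0, 0.0))
    anchor_seed = int(rng.integers(2 ** 31 - 1))
    scales = {}
    fallback = {"up": 1.0, "mult": 1.0, "down": max(1.0, float(d.counts.mean()))}
    for source in ("up", "mult", "down"):
        try:
            scales[source] = noise_level_for_snr(
                base, source, cfg.snr_anchor, seed=anchor_seed,
                n_stimuli=cfg.anchor_n_stimuli, n_reps=cfg.anchor_n_reps)
        except (RuntimeError, ZeroDivisionError):
            scales[source] = fallback[source]
    return scales


def random_starts(d: BinnedDataset, cfg: FitConfig, variant: str = "gaussian",
                  nl_ls: Optional[SoftplusParams] = None,
                  noise_scales: Optional[dict] = None) -> List[MultistageModel]:
    """Randomized initial models: the least-squares nonlinearity perturbed
    multiplicatively by +-perturb_frac per parameter, and noise levels drawn
    uniformly on [0, scale] with per-source SNR-anchored scales."""
    rng = np.random.default_rng(cfg.seed)
    if nl_ls is None:
        nl_ls = init_nonlinearity_ls(d)
    if noise_scales is None:
        noise_scales = _noise_anchor_scales(d, nl_ls, cfg, rng)

    starts = []
    base = nl_ls.as_array()
    for _ in range(cfg.n_starts):
        fac = rng.uniform(1 - cfg.perturb_frac, 1 + cfg.perturb_frac, size=4)
        b = base * fac
        nl = SoftplusParams(max(b[0], 1e-6), max(b[1], 1e-6), b[2], max(b[3], 0.0))
        s_up = rng.uniform(0, noise_scales["up"])
        s_mult = rng.uniform(0, noise_scales["mult"])
        s_down = rng.uniform(0, noise_scales["down"])
        if variant == "mixture":
            p_down = rng.uniform(0.05, 1.0)
            noise = NoiseParams(s_up, s_mult, s_down, p_down, "mixture")
        else:
            noise = NoiseParams(s_up, s_mult, s_down, 1.0, "gaussian")
        starts.append(MultistageModel(nl, noise))
    return starts


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _logit(p):
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def _expit(t):
    return 1.0 / (1.0 + math.exp(-t))


def _safe_log(v, floor=math.exp(_LOG_FLOOR)):
    return math.log(max(v, floor))


def _pack_ms(m: MultistageModel, variant: str) -> np.ndarray:
    nl, ns = m.nonlinearity, m.noise
    theta = [math.log(nl.beta1), math.log(nl.beta2), nl.beta3, _safe_log(nl.beta4),
             _safe_log(ns.sigma_up), _safe_log(ns.sigma_mult), _safe_log(ns.sigma_down)]
    if variant == "mixture":
        theta.append(_logit(ns.p_down))
    return np.array(theta)


def _unpack_ms(theta: np.ndarray, variant: str) -> MultistageModel:
    e = lambda t: math.exp(min(t, 60.0))
    nl = SoftplusParams(e(theta[0]), e(theta[1]), float(theta[2]), e(theta[3]))
    if variant == "mixture":
        ns = NoiseParams(e(theta[4]), e(theta[5]), e(theta[6]), _expit(theta[7]), "mixture")
    else:
        ns = NoiseParams(e(theta[4]), e(theta[5]), e(theta[6]), 1.0, "gaussian")
    return MultistageModel(nl, ns)


def _pack_nl(p: SoftplusParams) -> np.ndarray:
    return np.array([math.log(p.beta1), math.log(p.beta2), p.beta3, _safe_log(p.beta4)])


def _unpack_nl(theta: np.ndarray) -> SoftplusParams:
    e = lambda t: math.exp(min(t, 60.0))
    return SoftplusParams(e(theta[0]), e(theta[1]), float(theta[2]), e(theta[3]))


# ---------------------------------------------------------------------------
# multi-start drivers
# ---------------------------------------------------------------------------

def _run_starts(objective, thetas, cfg: FitConfig, unpack, describe):
    records = []
    best = None
    for theta0 in thetas:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(objective, theta0, method="Nelder-Mead",
                           options={"xatol": cfg.xatol, "fatol": cfg.fatol,
                                    "maxfev": cfg.maxfev, "maxiter": cfg.maxfev})
        rec = StartRecord(
            init_params=describe(unpack(theta0)),
            final_params=describe(unpack(res.x)),
            loglik=-float(res.fun),
            converged=bool(res.success),
            n_evals=int(res.nfev),
        )
        records.append(rec)
        if best is None or rec.loglik > best[0]:
            best = (rec.loglik, res.x, rec)
    return best, records


def fit_mle(d: BinnedDataset, variant: str = "gaussian",
            cfg: Optional[FitConfig] = None) -> FitResult:
    """Maximum-likelihood fit of the multistage noise model.

    Runs Nelder-Mead from each randomized start (log/logit-transformed
    parameters keep the search inside the feasible region) and returns the
    start achieving the highest exact log-likelihood.  The gaussian variant
    fixes p_down = 1.
    """
    if variant not in ("gaussian", "mixture"):
        raise ValueError(f"unknown variant {variant!r}")
    cfg = cfg or FitConfig()
    starts = random_starts(d, cfg, variant)
    thetas = [_pack_ms(s, variant) for s in starts]

    def objective(theta):
        m = _unpack_ms(theta, variant)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return -log_likelihood(m, d)

    best, records = _run_starts(objective, thetas, cfg,
                                lambda th: _unpack_ms(th, variant),
                                lambda m: m.to_dict())
    if best is None or not math.isfinite(best[0]):
        raise RuntimeError(f"all {cfg.n_starts} starts diverged; records: {records}")
    if not best[2].converged:
        warnings.warn("best start did not formally converge within maxfev", RuntimeWarning)
    return FitResult(best_params=_unpack_ms(best[1], variant), best_loglik=best[0],
                     per_start=records, config=cfg, seed=cfg.seed, variant=variant)


def fit_lnp(d: BinnedDataset, cfg: Optional[FitConfig] = None) -> FitResult:
    """Multi-start Nelder-Mead fit of the softplus LNP baseline (Poisson
    counts with rate f(x_t)), using the same start-generation procedure as
    the multistage fit for a fair comparison."""
    cfg = cfg or FitConfig()
    rng = np.random.default_rng(cfg.seed)
    nl_ls = init_nonlinearity_ls(d)
    base = nl_ls.as_array()
    thetas = []
    for _ in range(cfg.n_starts):
        fac = rng.uniform(1 - cfg.perturb_frac, 1 + cfg.perturb_frac, size=4)
        b = base * fac
        thetas.append(_pack_nl(SoftplusParams(max(b[0], 1e-6), max(b[1], 1e-6), b[2],
                                              max(b[3], 1e-9))))

    def objective(theta):
        return -log_likelihood_lnp(_unpack_nl(theta), d)

    best, records = _run_starts(objective, thetas, cfg, _unpack_nl,
                                lambda p: {"beta1": p.beta1, "beta2": p.beta2,
                                           "beta3": p.beta3, "beta4": p.beta4})
    if best is None or not math.isfinite(best[0]):
        raise RuntimeError("all LNP starts diverged")
    return FitResult(best_params=_unpack_nl(best[1]), best_loglik=best[0],
                     per_start=records, config=cfg, seed=cfg.seed, variant="lnp")
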