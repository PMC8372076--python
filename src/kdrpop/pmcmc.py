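"""Genotype-frequency hidden Markov model fitted by particle MCMC.

The HMM couples three layers:

* **Latent dynamics** — the resistance allele frequency p_t follows the
  deterministic selection-with-dominance recursion each monthly generation,
  then experiences genetic drift as binomial resampling of 2*Ne gametes.
* **Observation** — in a sampled month, the (n_RR, n_RS, n_SS) genotype
  counts are Dirichlet-multinomial around the Hardy-Weinberg proportions at
  p_t with concentration A; small A means heavy overdispersion relative to
  multinomial sampling (A -> infinity recovers the multinomial).
* **Parameters** — theta = (s, h, R0, A) with priors Beta(1, 1) on the unit
  interval parameters and Gamma(0.01, 0.01) on A; Ne is fixed (default 500,
  the midpoint of published estimates for this population).

Because the likelihood integrates over the latent frequency path it has no
closed form; a bootstrap particle filter provides an unbiased estimate,
which is embedded in an adaptive Metropolis-Hastings chain (particle
marginal Metropolis-Hastings).  Proposals are multivariate normal on the
transformed scale (logit s, logit h, logit R0, log A) with Haario-style
empirical covariance adaptation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logit

from ._filter import particle_filter
from .io import SampleSeries, month_index
from .selection import hwe_proportions, step_allele_freq

logger = logging.getLogger(__name__)

PARAM_NAMES = ("s", "h", "R0", "A")

#: Default priors: Beta(a, b) for unit-interval parameters, Gamma(shape,
#: rate) for the overdispersion concentration A.
DEFAULT_PRIORS = {
    "s": ("beta", 1.0, 1.0),
    "h": ("beta", 1.0, 1.0),
    "R0": ("beta", 1.0, 1.0),
    "A": ("gamma", 0.01, 0.01),
}

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class HMMParams:
    """State-space model parameters: selection s, dominance h, initial
    frequency R0, sampling overdispersion A (> 0) and effective size Ne."""

    s: float
    h: float
    R0: float
    A: float
    Ne: int = 500

    def __post_init__(self) -> None:
        for name in ("s", "h", "R0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")


@dataclass
class PMCMCConfig:
    """Particle MCMC settings.

    The defaults (1000 particles, 50,000 iterations with 10,000 burn-in)
    match a full production run; tests and quick looks should scale
    ``n_iterations`` and ``n_particles`` down.
    """

    n_particles: int = 1000
    n_iterations: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    adapt_start: int = 500
    seed: int = 0
    Ne: int = 500
    init: HMMParams | None = None
    ml_init: bool = True
    ml_maxfev: int = 150
    store_paths: bool = True

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")


@dataclass
class PosteriorDraws:
    """Retained post-burn-in draws over (s, h, R0, A)."""

    draws: np.ndarray                       # (n_kept, 4)
    logliks: np.ndarray                     # (n_kept,)
    acceptance_rate: float
    param_names: tuple[str, ...] = PARAM_NAMES
    latent_paths: np.ndarray | None = None  # (n_kept, n_months)
    start: tuple[int, int] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(self.param_names))
        df["loglik"] = self.logliks
        return df


def dirichlet_multinomial_logpmf(counts, probs, A: float) -> float:
    """Compound multinomial log-pmf with concentration vector A * probs.

    ``probs`` is epsilon-floored and renormalized so the pmf stays finite
    when the latent frequency sits at fixation.
    """
    if A <= 0:
        raise ValueError("A must be positive")
    counts = np.asarray(counts)
    probs = np.maximum(np.asarray(probs, dtype=float), _PROB_FLOOR)
    probs = probs / probs.sum()
    n = int(counts.sum())
    return float(stats.dirichlet_multinomial(A * probs, n).logpmf(counts))


def simulate_hmm(
    params: HMMParams,
    sample_sizes,
    seed: int,
    start: tuple[int, int] = (2002, 10),
) -> tuple[np.ndarray, SampleSeries]:
    """Simulate the HMM forward: latent drift trajectory + observed counts.

    ``sample_sizes`` gives the number of individuals genotyped in each
    calendar month (0 = no observation that month).  Returns the latent
    monthly allele-frequency trajectory and the observed
    :class:`SampleSeries` (months with n = 0 emit nothing).
    """
    sample_sizes = np.asarray(sample_sizes, dtype=np.int64)
    if (sample_sizes < 0).any():
        raise ValueError("sample sizes must be non-negative")
    rng = np.random.default_rng(seed)
    n_months = len(sample_sizes)
    latent = np.empty(n_months)
    p = params.R0
    two_ne = 2 * params.Ne
    months, obs = [], []
    base = month_index(*start)
    for t in range(n_months):
        latent[t] = p
        n_t = int(sample_sizes[t])
        if n_t > 0:
            probs = np.maximum(hwe_proportions(p), _PROB_FLOOR)
            probs /= probs.sum()
            g = rng.dirichlet(params.A * probs)
            counts = rng.multinomial(n_t, g)
            y, m0 = divmod(base + t, 12)
            months.append((y, m0 + 1))
            obs.append(counts)
        p_det = step_allele_freq(p, params.s, params.h)
        p = rng.binomial(two_ne, p_det) / two_ne
    series = SampleSeries(months=months, counts=np.stack(obs))
    return latent, series


def particle_loglik(
    series: SampleSeries,
    params: HMMParams,
    n_particles: int = 1000,
    seed: int = 0,
    return_path: bool = False,
):
    """Particle-filter estimate of the marginal log-likelihood.

    Unbiased on the likelihood scale; at fixed seed it is a deterministic
    function of its inputs.  Returns the log-likelihood, or
    ``(loglik, latent_path)`` when ``return_path`` is True.  Complete
    particle degeneracy yields -inf with a warning.
    """
    obs_t = series.t.astype(np.int64)
    counts = series.counts.astype(np.float64)
    ll, path = particle_filter(obs_t, counts, float(params.s), float(params.h),
                               float(params.R0), float(params.A),
                               2 * int(params.Ne), int(n_particles),
                               int(seed) & 0x7FFFFFFF, return_path)
    if not np.isfinite(ll):
        warnings.warn("particle filter degenerated: all weights zero",
                      RuntimeWarning, stacklevel=2)
    if return_path:
        return ll, path
    return ll


# ---------------------------------------------------------------------------
# transformed-scale helpers

def _to_theta(x: np.ndarray) -> np.ndarray:
    return np.array([logit(x[0]), logit(x[1]), logit(x[2]), np.log(x[3])])


def _from_theta(theta: np.ndarray) -> np.ndarray:
    return np.array([expit(theta[0]), expit(theta[1]), expit(theta[2]),
                     np.exp(theta[3])])


def _log_prior_theta(theta: np.ndarray, priors: dict) -> float:
    """Log prior density on the transformed scale (includes Jacobians)."""
    x = _from_theta(theta)
    lp = 0.0
    for name, val in zip(PARAM_NAMES, x):
        kind, a, b = priors[name]
        if kind == "beta":
            if not 0 < val < 1:
                return -np.inf
            lp += stats.beta.logpdf(val, a, b) + np.log(val) + np.log(1 - val)
        elif kind == "gamma":
            if val <= 0:
                return -np.inf
            lp += stats.gamma.logpdf(val, a, scale=1.0 / b) + np.log(val)
        else:
            raise ValueError(f"unknown prior kind {kind!r}")
    return float(lp)


def _ml_initialize(series: SampleSeries, config: PMCMCConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Derivative-free ML fit of the particle-filter likelihood, used to
    start the chain near the mode (common random numbers across evals)."""
    p0 = float(series.resistance_freq()[0])
    x0 = np.array([0.1, 0.5, min(max(p0, 0.02), 0.98), 10.0])
    pf_seed = int(rng.integers(2**31))

    def neg_ll(theta):
        x = _from_theta(theta)
        params = HMMParams(s=x[0], h=x[1], R0=x[2], A=x[3], Ne=config.Ne)
        ll = particle_loglik(series, params, config.n_particles, pf_seed)
        return -ll if np.isfinite(ll) else 1e12

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(neg_ll, _to_theta(x0), method="Nelder-Mead",
                       options={"maxfev": config.ml_maxfev, "xatol": 1e-3,
                                "fatol": 0.5})
    return np.asarray(res.x)


def run_pmcmc(
    series: SampleSeries | None,
    config: PMCMCConfig,
    priors: dict | None = None,
) -> PosteriorDraws:
    """Particle marginal Metropolis-Hastings over (s, h, R0, A).

    ``series=None`` runs the chain against a flat (empty) likelihood and
    therefore samples the prior — useful as a correctness check.  The
    proposal is multivariate normal on (logit s, logit h, logit R0, log A);
    after ``adapt_start`` iterations its covariance tracks the running
    empirical covariance of the chain scaled by 2.38^2 / d (Haario-style
    adaptive Metropolis).
    """
    priors = dict(DEFAULT_PRIORS, **(priors or {}))
    rng = np.random.default_rng(config.seed)
    d = len(PARAM_NAMES)

    def loglik(theta: np.ndarray) -> float:
        if series is None:
            return 0.0
        x = _from_theta(theta)
        params = HMMParams(s=x[0], h=x[1], R0=x[2], A=x[3], Ne=config.Ne)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return particle_loglik(series, params, config.n_particles,
                                   int(rng.integers(2**31)))

    if config.init is not None:
        theta = _to_theta(np.array([config.init.s, config.init.h,
                                    config.init.R0, config.init.A]))
    elif series is not None and config.ml_init:
        theta = _ml_initialize(series, config, rng)
    else:
        theta = _to_theta(np.array([0.5, 0.5, 0.5, 1.0]))

    ll_cur = loglik(theta)
    lp_cur = _log_prior_theta(theta, priors)
    if not np.isfinite(ll_cur + lp_cur):
        raise RuntimeError(
            "initial state has non-finite posterior density; supply an "
            "explicit init or widen the priors")

    base_cov = np.diag(np.full(d, 0.01))
    scale = 2.38**2 / d
    run_mean = theta.copy()
    run_m2 = np.zeros((d, d))
    n_seen = 1

    draws = np.empty((config.n_iterations, d))
    lls = np.empty(config.n_iterations)
    n_accept = 0
    for it in range(config.n_iterations):
        if it >= config.adapt_start and n_seen > d:
            cov = scale * (run_m2 / (n_seen - 1)) + 1e-9 * np.eye(d)
        else:
            cov = base_cov
        prop = rng.multivariate_normal(theta, cov)
        lp_prop = _log_prior_theta(prop, priors)
        if np.isfinite(lp_prop):
            ll_prop = loglik(prop)
            log_alpha = (ll_prop + lp_prop) - (ll_cur + lp_cur)
            if np.log(rng.random()) < log_alpha:
                theta, ll_cur, lp_cur = prop, ll_prop, lp_prop
                n_accept += 1
        draws[it] = _from_theta(theta)
        lls[it] = ll_cur
        # running mean / scatter for adaptation
        n_seen += 1
        delta = theta - run_mean
        run_mean += delta / n_seen
        run_m2 += np.outer(delta, theta - run_mean)

    keep = slice(config.burn_in, None, config.thin)
    kept = draws[keep].copy()
    kept_ll = lls[keep].copy()
    acceptance = n_accept / config.n_iterations
    logger.info("pMCMC finished: %d kept draws, acceptance %.3f",
                len(kept), acceptance)

    paths = None
    start = None
    if series is not None and config.store_paths:
        start = tuple(series.months[0])
        n_months = int(series.t[-1]) + 1
        paths = np.empty((len(kept), n_months))
        for i, x in enumerate(kept):
            params = HMMParams(s=x[0], h=x[1], R0=x[2], A=x[3], Ne=config.Ne)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                _, path = particle_loglik(series, params, config.n_particles,
                                          int(rng.integers(2**31)),
                                          return_path=True)
            paths[i] = path
    return PosteriorDraws(draws=kept, logliks=kept_ll,
                          acceptance_rate=acceptance, latent_paths=paths,
                          start=start)


def summarize_posterior(draws: PosteriorDraws, level: float = 0.95):
    """Posterior means and equal-tailed credible intervals.

    Returns ``(param_summary, genotype_bands)``: the second element maps
    the retained latent allele-frequency paths through Hardy-Weinberg
    proportions to per-month credible bands for the three genotype
    frequencies (None when no paths were stored).
    """
    if len(draws.draws) == 0:
        raise ValueError("no posterior draws to summarize")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    summary = pd.DataFrame({
        "param": list(draws.param_names),
        "mean": draws.draws.mean(axis=0),
        "median": np.median(draws.draws, axis=0),
        "ci_low": np.quantile(draws.draws, lo_q, axis=0),
        "ci_high": np.quantile(draws.draws, hi_q, axis=0),
    })

    bands = None
    if draws.latent_paths is not None:
        p = draws.latent_paths                       # (n_draws, n_months)
        geno = np.stack([p * p, 2 * p * (1 - p), (1 - p) ** 2], axis=-1)
        base = month_index(*draws.start) if draws.start else 0
        rows = []
        for t in range(p.shape[1]):
            y, m0 = divmod(base + t, 12)
            row = {"year": y, "month": m0 + 1,
                   "p_mean": p[:, t].mean(),
                   "p_low": np.quantile(p[:, t], lo_q),
                   "p_high": np.quantile(p[:, t], hi_q)}
            for k, cls in enumerate(("RR", "RS", "SS")):
                row[f"{cls}_mean"] = geno[:, t, k].mean()
                row[f"{cls}_low"] = np.quantile(geno[:, t, k], lo_q)
                row[f"{cls}_high"] = np.quantile(geno[:, t, k], hi_q)
            rows.append(row)
        bands = pd.DataFrame(rows)
    return summary, bands
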