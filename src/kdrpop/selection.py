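"""Deterministic single-locus selection dynamics with dominance.

The model tracks the resistance allele frequency p through discrete,
non-overlapping monthly generations under random mating.  Fitness is
parameterized as a cost to the susceptible allele:

    w_RR = 1,   w_RS = 1 - h*s,   w_SS = 1 - s

with selection coefficient s in [0, 1] and dominance h in [0, 1] of the
cost in heterozygotes.  h = 0 makes the heterozygote behave like the
resistant homozygote (resistance dominant); h = 1 makes it behave like the
susceptible homozygote (resistance recessive).  One generation of
selection plus random mating gives the classical recursion

    p' = [p^2 + p(1-p)(1 - h*s)] / w_bar,
    w_bar = p^2 + 2 p (1-p)(1 - h*s) + (1-p)^2 (1 - s).

``ml_s_given_h`` implements the profile-likelihood fit used to draw
deterministic trajectories through observed monthly genotype counts: for a
fixed dominance h and initial frequency R0, the selection coefficient
maximizing the product of multinomial likelihoods of the observed
(n_RR, n_RS, n_SS) under Hardy-Weinberg proportions at the model's p_t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .io import SampleSeries, month_index


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SelectionParams:
    """Cost to the susceptible allele (s), its dominance (h), and the
    initial resistance allele frequency (R0)."""

    s: float
    h: float
    R0: float

    def __post_init__(self) -> None:
        _check_unit("s", self.s)
        _check_unit("h", self.h)
        _check_unit("R0", self.R0)


@dataclass
class FrequencyTrajectory:
    """Per-generation resistance allele frequencies from a start month."""

    start: tuple[int, int]
    freqs: np.ndarray

    @property
    def months(self) -> list[tuple[int, int]]:
        base = month_index(*self.start)
        return [divmod(base + t, 12)[0:1] + (divmod(base + t, 12)[1] + 1,)
                for t in range(len(self.freqs))]


def genotype_fitnesses(s: float, h: float) -> tuple[float, float, float]:
    """Relative fitnesses (w_RR, w_RS, w_SS) = (1, 1 - h*s, 1 - s)."""
    _check_unit("s", s)
    _check_unit("h", h)
    return (1.0, 1.0 - h * s, 1.0 - s)


def step_allele_freq(p: float, s: float, h: float) -> float:
    """One generation of viability selection plus random mating."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    w_rr, w_rs, w_ss = genotype_fitnesses(s, h)
    q = 1.0 - p
    num = p * p * w_rr + p * q * w_rs
    w_bar = p * p * w_rr + 2.0 * p * q * w_rs + q * q * w_ss
    if w_bar == 0.0:
        return p  # degenerate: everyone dead; frequency undefined, keep p
    return min(1.0, max(0.0, num / w_bar))


def simulate_deterministic(
    params: SelectionParams,
    generations: int,
    start: tuple[int, int] = (2002, 10),
) -> FrequencyTrajectory:
    """Iterate the recursion for ``generations`` monthly steps from R0."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    freqs = np.empty(generations + 1)
    freqs[0] = params.R0
    for t in range(generations):
        freqs[t + 1] = step_allele_freq(freqs[t], params.s, params.h)
    return FrequencyTrajectory(start=tuple(start), freqs=freqs)


def hwe_proportions(p: float) -> np.ndarray:
    """Hardy-Weinberg genotype proportions (RR, RS, SS) at frequency p."""
    return np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])


def _series_loglik(series: SampleSeries, s: float, h: float, R0: float,
                   start: tuple[int, int], floor: float = 1e-12) -> float:
    """Multinomial log-likelihood of observed monthly genotype counts under
    HWE proportions at the deterministic trajectory (pre-selection census)."""
    base = month_index(*start)
    offsets = [month_index(y, m) - base for y, m in series.months]
    if min(offsets) < 0:
        raise ValueError("series begins before the trajectory start month")
    traj = simulate_deterministic(SelectionParams(s=s, h=h, R0=R0),
                                  generations=max(offsets), start=start)
    ll = 0.0
    for t_off, counts in zip(offsets, series.counts):
        probs = np.maximum(hwe_proportions(traj.freqs[t_off]), floor)
        probs = probs / probs.sum()
        n = counts.sum()
        ll += (gammaln(n + 1) - gammaln(counts + 1).sum()
               + float(counts @ np.log(probs)))
    return ll


@dataclass
class MLFit:
    s_hat: float
    loglik: float
    boundary: bool


def ml_s_given_h(
    series: SampleSeries,
    h: float,
    R0: float,
    start: tuple[int, int] | None = None,
    tol: float = 1e-4,
) -> MLFit:
    """Maximum-likelihood selection coefficient for fixed h and R0.

    A coarse grid scan over s in [0, 1] brackets the optimum, which is then
    refined by bounded scalar minimization to ``tol``.  Estimates within
    ``tol`` of 0 or 1 are flagged as boundary solutions.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    if start is None:
        start = series.months[0]

    def nll(s: float) -> float:
        return -_series_loglik(series, s, h, R0, start)

    grid = np.linspace(0.0, 1.0, 101)
    values = np.array([nll(s) for s in grid])
    k = int(np.argmin(values))
    lo, hi = grid[max(0, k - 1)], grid[min(len(grid) - 1, k + 1)]
    if lo == hi:
        s_hat, fval = grid[k], values[k]
    else:
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                              options={"xatol": tol})
        s_hat, fval = float(res.x), float(res.fun)
        if values[k] < fval:  # guard: grid point better than refinement
            s_hat, fval = float(grid[k]), float(values[k])
    boundary = s_hat < tol or s_hat > 1 - tol
    return MLFit(s_hat=s_hat, loglik=-fval, boundary=boundary)
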