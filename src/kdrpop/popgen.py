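"""Population-genetic statistics: LD via EM haplotype frequencies, HWE
chi-square tests, monthly allele-frequency confidence intervals, and
spray-vs-buffer zone contrasts.

Linkage disequilibrium between two biallelic loci is computed from
maximum-likelihood haplotype frequencies estimated by EM under random
mating (phase of double heterozygotes is the only latent quantity).  The
chi-square test of D = 0 uses the identity ``chi2 = 2 n R^2`` with one
degree of freedom, where n is the number of individuals (2n haplotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit
from statsmodels.stats.proportion import proportion_confint

from .io import ONE_LOCUS_CLASSES, TWO_LOCUS_CLASSES, GenotypeCountTable, SampleSeries

logger = logging.getLogger(__name__)

# Haplotype order (VF, VC, IC, IF); allele A = Ile1016, allele B = Cys1534.
_H_VF, _H_VC, _H_IC, _H_IF = 0, 1, 2, 3


def _genotype_class_probs(f: np.ndarray) -> np.ndarray:
    """HWE (random-union) probabilities of the 9 two-locus genotype classes."""
    vf, vc, ic, if_ = f
    return np.array([
        vf * vf,                      # VV/FF
        2 * vf * vc,                  # VV/FC
        vc * vc,                      # VV/CC
        2 * vf * if_,                 # VI/FF
        2 * vf * ic + 2 * vc * if_,   # VI/FC  (both phasings)
        2 * vc * ic,                  # VI/CC
        if_ * if_,                    # II/FF
        2 * ic * if_,                 # II/FC
        ic * ic,                      # II/CC
    ])


def _em_loglik(counts: np.ndarray, f: np.ndarray) -> float:
    probs = _genotype_class_probs(f)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        lp = np.log(probs[mask])
    if np.any(np.isneginf(lp)):
        return -np.inf
    return float(counts[mask] @ lp)


def _em_once(counts: np.ndarray, f: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, float]:
    n2 = 2.0 * counts.sum()
    ll = _em_loglik(counts, f)
    for _ in range(max_iter):
        vf, vc, ic, if_ = f
        # E-step: expected haplotype counts; only VI/FC is phase-ambiguous.
        cis = vf * ic
        trans = vc * if_
        w = 0.5 if cis + trans == 0 else cis / (cis + trans)
        c = counts
        n_vf = 2 * c[0] + c[1] + c[3] + w * c[4]
        n_vc = 2 * c[2] + c[1] + c[5] + (1 - w) * c[4]
        n_ic = 2 * c[8] + c[5] + c[7] + w * c[4]
        n_if = 2 * c[6] + c[3] + c[7] + (1 - w) * c[4]
        f = np.array([n_vf, n_vc, n_ic, n_if]) / n2
        new_ll = _em_loglik(counts, f)
        if new_ll - ll < tol:
            ll = new_ll
            break
        ll = new_ll
    return f, ll


def em_haplotype_freqs(
    table: GenotypeCountTable,
    tol: float = 1e-10,
    max_iter: int = 10000,
    init: np.ndarray | None = None,
    multi_start: bool = True,
) -> np.ndarray:
    """Maximum-likelihood haplotype frequencies (VF, VC, IC, IF) by EM.

    The log-likelihood is non-decreasing across iterations; convergence is
    declared when it improves by less than ``tol``.  Because the
    flat-margin likelihood has a symmetric saddle at D = 0 (e.g. a table
    of only double heterozygotes), the default multi-start runs EM from a
    uniform initialization plus two corner initializations favouring each
    phasing and returns the highest-likelihood solution.
    """
    if table.classes != TWO_LOCUS_CLASSES:
        raise ValueError("em_haplotype_freqs requires a two-locus table")
    counts = table.counts.astype(float)
    if counts.sum() == 0:
        raise ValueError("all genotype counts are zero")

    if init is not None:
        starts = [np.asarray(init, dtype=float)]
    elif multi_start:
        starts = [
            np.full(4, 0.25),
            np.array([0.4, 0.1, 0.4, 0.1]),   # coupling-phase corner
            np.array([0.1, 0.4, 0.1, 0.4]),   # repulsion-phase corner
        ]
    else:
        starts = [np.full(4, 0.25)]

    best_f, best_ll = None, -np.inf
    for f0 in starts:
        f, ll = _em_once(counts, f0 / f0.sum(), tol, max_iter)
        if ll > best_ll:
            best_f, best_ll = f, ll
    return best_f


@dataclass
class LDResult:
    """Linkage disequilibrium between two biallelic loci."""

    D: float
    Dprime: float
    R2: float
    chi2: float
    p: float
    n: int


def ld_chi2(r2: float, n: int) -> float:
    """Chi-square statistic for D = 0 from R^2 and n individuals (1 df)."""
    return 2.0 * n * r2


def ld_stats(hapfreqs: np.ndarray, n: int) -> LDResult:
    """LD statistics from a haplotype frequency 4-vector (VF, VC, IC, IF).

    The focal alleles are the resistance alleles: A = Ile1016
    (p_A = f_IC + f_IF) and B = Cys1534 (p_B = f_VC + f_IC);
    D = f_IC - p_A p_B.
    """
    f = np.asarray(hapfreqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("haplotype frequencies must sum to 1")
    if n <= 0:
        raise ValueError("n must be positive")
    p_a = f[_H_IC] + f[_H_IF]
    p_b = f[_H_VC] + f[_H_IC]
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("LD undefined for a monomorphic locus")
    d = f[_H_IC] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = 0.0 if d_max == 0 else d / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    chi2 = ld_chi2(r2, n)
    p = float(stats.chi2.sf(chi2, df=1))
    return LDResult(D=float(d), Dprime=float(dprime), R2=float(r2),
                    chi2=float(chi2), p=p, n=int(n))


@dataclass
class HWEResult:
    chi2: float
    p_raw: float
    p_bonferroni: float
    n: int
    allele_freq: float


def hwe_chi2(counts, family_size: int = 1) -> HWEResult:
    """Chi-square test (1 df) of Hardy-Weinberg proportions.

    ``counts`` is (n_RR, n_RS, n_SS); the expected counts come from the
    estimated allele frequency; ``family_size`` is the Bonferroni family
    (number of monthly tests), applied as ``min(1, m * p_raw)``.
    """
    n_rr, n_rs, n_ss = (int(c) for c in counts)
    n = n_rr + n_rs + n_ss
    if n == 0:
        raise ValueError("empty sample")
    p_hat = (2 * n_rr + n_rs) / (2 * n)
    if p_hat in (0.0, 1.0):
        raise ValueError("HWE test undefined for a monomorphic sample")
    expected = n * np.array([p_hat ** 2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2])
    observed = np.array([n_rr, n_rs, n_ss], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_raw = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(chi2=chi2, p_raw=p_raw,
                     p_bonferroni=min(1.0, family_size * p_raw),
                     n=n, allele_freq=p_hat)


def monthly_allele_freq_ci(series: SampleSeries, level: float = 0.95):
    """Per-month resistance allele frequency with binomial-logit Wald CIs.

    Each month gets its own intercept (a saturated binomial logit model on
    allele counts out of 2n trials), so the point estimate is the raw
    allele frequency and the CI is the Wald interval on the logit scale
    back-transformed.  Months at frequency 0 or 1, where the logit interval
    degenerates, fall back to the Wilson score interval and are flagged.

    Returns a pandas DataFrame (year, month, n, freq, ci_low, ci_high,
    boundary).
    """
    import pandas as pd

    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    k_arr = series.resistance_allele_counts()
    for (ym, k, n_ind) in zip(series.months, k_arr, series.n):
        trials = 2 * int(n_ind)
        k = int(k)
        freq = k / trials
        boundary = k == 0 or k == trials
        if boundary:
            lo, hi = proportion_confint(k, trials, alpha=1 - level, method="wilson")
        else:
            se = np.sqrt(1 / k + 1 / (trials - k))
            lo, hi = expit(logit(freq) + np.array([-z, z]) * se)
        rows.append({"year": ym[0], "month": ym[1], "n": int(n_ind),
                     "freq": freq, "ci_low": float(lo), "ci_high": float(hi),
                     "boundary": boundary})
    return pd.DataFrame(rows)


@dataclass
class ZoneContrast:
    """Ratio of spray-zone to buffer-zone resistance allele frequencies."""

    month: tuple[int, int]
    ratio: float
    ci_low: float
    ci_high: float
    p: float
    flagged: bool = False


def zone_contrast(spray: SampleSeries, buffer: SampleSeries,
                  month: tuple[int, int], level: float = 0.95) -> ZoneContrast:
    """Spray/buffer frequency ratio for one month with delta-method CI.

    The ratio is on the response (frequency) scale; its CI comes from the
    delta method on the log-ratio.  The p-value is the two-sided Wald test
    of equal frequencies on the logit scale.  A zero allele count in the
    buffer zone leaves the ratio undefined and returns a flagged result.
    """

    def _extract(series: SampleSeries):
        for ym, row in zip(series.months, series.counts):
            if tuple(ym) == tuple(month):
                k = int(2 * row[0] + row[1])
                return k, int(2 * row.sum())
        raise ValueError(f"month {month} not sampled in series")

    k1, n1 = _extract(spray)
    k2, n2 = _extract(buffer)
    if k2 == 0:
        return ZoneContrast(month=month, ratio=np.nan, ci_low=np.nan,
                            ci_high=np.nan, p=np.nan, flagged=True)
    p1, p2 = k1 / n1, k2 / n2
    ratio = p1 / p2
    flagged = k1 == 0 or k1 == n1 or k2 == n2
    z = stats.norm.ppf(0.5 + level / 2)
    if not flagged:
        # delta method: var(log p_hat) = (1 - p) / k
        se_log = np.sqrt((1 - p1) / k1 + (1 - p2) / k2)
        lo, hi = ratio * np.exp(np.array([-z, z]) * se_log)
        se_logit = np.sqrt(1 / k1 + 1 / (n1 - k1) + 1 / k2 + 1 / (n2 - k2))
        z_stat = (logit(p1) - logit(p2)) / se_logit
        p_val = float(2 * stats.norm.sf(abs(z_stat)))
    else:
        lo = hi = np.nan
        p_val = np.nan
    return ZoneContrast(month=tuple(month), ratio=float(ratio),
                        ci_low=float(lo), ci_high=float(hi), p=p_val,
                        flagged=flagged)
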