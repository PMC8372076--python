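"""Two-locus kdr haplotype imputation from unphased genotype counts.

The two resistance loci V1016I and F1534C sit in the single-copy
voltage-gated sodium channel gene, so each mosquito carries two of the four
possible haplotypes VF, VC, IC, IF (first letter = 1016 allele, second =
1534 allele).  Phase is unobserved, but in American *Aedes aegypti*
populations the Ile1016/Phe1534 (IF) haplotype is essentially absent:
Cys1534 reached fixation before Ile1016 appeared.  Under that exclusion
constraint every genotype class resolves to a unique haplotype pair — in
particular the double heterozygote VI/FC must be VF + IC — except for three
classes (VI/FF, II/FF, II/FC) that cannot be formed without an IF haplotype
and are flagged infeasible.

Haplotype counts are obtained by multiplying the 9-class genotype count
vector by a 9x4 haplotype probability matrix and doubling (two haplotypes
per individual); 95% confidence intervals use the Wilson score interval,
which stays well-behaved at the frequency boundaries where these data
spend most of their time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .io import TWO_LOCUS_CLASSES, GenotypeCountTable, two_locus_class

logger = logging.getLogger(__name__)

HAPLOTYPES = ("VF", "VC", "IC", "IF")

#: Genotype classes that require at least one IF haplotype.
IF_IMPLYING_CLASSES = ("VI/FF", "II/FF", "II/FC")

# Haplotype-pair content of each unambiguous genotype class.
_PAIRS = {
    "VV/FF": ("VF", "VF"),
    "VV/FC": ("VF", "VC"),
    "VV/CC": ("VC", "VC"),
    "VI/FF": ("VF", "IF"),
    "VI/CC": ("VC", "IC"),
    "II/FF": ("IF", "IF"),
    "II/FC": ("IC", "IF"),
    "II/CC": ("IC", "IC"),
}


@dataclass
class HaplotypeProbabilityMatrix:
    """Rows = the 9 two-locus genotype classes, columns = (VF, VC, IC, IF).

    Entry [g, k] is the expected fraction of genotype g's two haplotypes
    that are haplotype k; feasible rows sum to 1, infeasible rows are zero.
    """

    probs: np.ndarray
    feasible: np.ndarray
    exclude_IF: bool

    @property
    def infeasible_classes(self) -> tuple[str, ...]:
        return tuple(c for c, ok in zip(TWO_LOCUS_CLASSES, self.feasible) if not ok)


def haplotype_probability_matrix(
    exclude_IF: bool = True,
    hap_freqs: np.ndarray | None = None,
) -> HaplotypeProbabilityMatrix:
    """Build the genotype-class -> haplotype probability matrix.

    With ``exclude_IF=True`` the IF column is identically zero, the double
    heterozygote VI/FC resolves deterministically to 1/2 VF + 1/2 IC, and
    the three IF-implying classes are flagged infeasible.

    With ``exclude_IF=False`` the double heterozygote has two possible
    phasings (VF+IC vs VC+IF); their relative weight is taken from
    ``hap_freqs`` (population haplotype frequencies, e.g. an EM estimate)
    when given, otherwise split 50/50.
    """
    probs = np.zeros((9, 4))
    feasible = np.ones(9, dtype=bool)
    hap_idx = {h: k for k, h in enumerate(HAPLOTYPES)}
    for g, cls in enumerate(TWO_LOCUS_CLASSES):
        if cls == "VI/FC":
            if exclude_IF:
                probs[g, hap_idx["VF"]] = 0.5
                probs[g, hap_idx["IC"]] = 0.5
            else:
                if hap_freqs is None:
                    w_cis = 0.5
                else:
                    f = np.asarray(hap_freqs, dtype=float)
                    a = f[hap_idx["VF"]] * f[hap_idx["IC"]]
                    b = f[hap_idx["VC"]] * f[hap_idx["IF"]]
                    w_cis = 0.5 if a + b == 0 else a / (a + b)
                probs[g, hap_idx["VF"]] = w_cis / 2
                probs[g, hap_idx["IC"]] = w_cis / 2
                probs[g, hap_idx["VC"]] = (1 - w_cis) / 2
                probs[g, hap_idx["IF"]] = (1 - w_cis) / 2
            continue
        pair = _PAIRS[cls]
        if exclude_IF and "IF" in pair:
            feasible[g] = False
            continue
        for h in pair:
            probs[g, hap_idx[h]] += 0.5
    return HaplotypeProbabilityMatrix(probs=probs, feasible=feasible,
                                      exclude_IF=exclude_IF)


@dataclass
class HaplotypeFreqs:
    """Imputed haplotype frequencies with Wilson confidence intervals."""

    freqs: np.ndarray            # length 4, sums to 1 over retained haplotypes
    hap_counts: np.ndarray       # expected haplotype counts (may be fractional)
    total_haplotypes: int        # 2 x individuals retained
    ci: np.ndarray               # (4, 2) lower/upper bounds
    n_individuals: int
    n_dropped: int
    level: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(HAPLOTYPES, self.freqs.tolist()))


def haplotype_freq_ci(count: float, total: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a haplotype proportion count/total."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0 or count > total:
        raise ValueError("count must lie in [0, total]")
    lo, hi = proportion_confint(count, total, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def impute_haplotype_freqs(
    table: GenotypeCountTable,
    exclude_IF: bool = True,
    infeasible_policy: str = "drop",
    level: float = 0.95,
    hap_freqs_for_phasing: np.ndarray | None = None,
) -> HaplotypeFreqs:
    """Impute haplotype frequencies from a two-locus genotype count table.

    Haplotype count for haplotype k is ``sum_g 2 * count(g) * P[g, k]``
    over feasible genotype classes.  Individuals in infeasible classes
    (those requiring an IF haplotype when ``exclude_IF=True``) are dropped
    with a logged warning, or raise if ``infeasible_policy="error"``.

    With ``exclude_IF=False`` and no explicit ``hap_freqs_for_phasing``,
    the double-heterozygote phasing weights are taken from the EM haplotype
    frequency estimate of the same table (a 50/50 split is biased whenever
    the loci are in linkage disequilibrium).
    """
    if table.classes != TWO_LOCUS_CLASSES:
        raise ValueError("impute_haplotype_freqs requires a two-locus table")
    if infeasible_policy not in ("drop", "error"):
        raise ValueError("infeasible_policy must be 'drop' or 'error'")

    if not exclude_IF and hap_freqs_for_phasing is None:
        from .popgen import em_haplotype_freqs
        hap_freqs_for_phasing = em_haplotype_freqs(table)
    mat = haplotype_probability_matrix(exclude_IF=exclude_IF,
                                       hap_freqs=hap_freqs_for_phasing)

    counts = table.counts.astype(float)
    dropped = counts[~mat.feasible]
    n_dropped = int(dropped.sum())
    if n_dropped and infeasible_policy == "error":
        detail = {c: table.count(c) for c in mat.infeasible_classes if table.count(c)}
        raise ValueError(f"infeasible genotype classes present: {detail}")
    if n_dropped:
        logger.warning("dropped %d individuals in IF-implying genotype classes %s",
                       n_dropped, mat.infeasible_classes)

    kept = counts * mat.feasible
    hap_counts = 2.0 * kept @ mat.probs
    total = int(round(2 * kept.sum()))
    if total == 0:
        raise ValueError("no individuals retained for haplotype imputation")
    freqs = hap_counts / total
    ci = np.array([haplotype_freq_ci(c, total, level) for c in hap_counts])
    return HaplotypeFreqs(
        freqs=freqs, hap_counts=hap_counts, total_haplotypes=total, ci=ci,
        n_individuals=table.total, n_dropped=n_dropped, level=level,
    )


def count_IF_implying(records) -> int:
    """Number of individuals whose genotype class requires >=1 IF haplotype.

    These are II/FF, II/FC and VI/FF — each is impossible without at least
    one Ile1016/Phe1534 chromosome.  In the Iquitos study such individuals
    were a 0.03% anomaly, consistent with the haplotype's low fitness.
    """
    n = 0
    for rec in records:
        cls = rec if isinstance(rec, str) else two_locus_class(rec)
        if cls in IF_IMPLYING_CLASSES:
            n += 1
    return n
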