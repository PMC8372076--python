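"""Synthetic genotype datasets with the structure of long-term kdr
surveillance collections.

The generators emulate ~18 years of monthly samples of genotyped
mosquitoes from a single panmictic population: allele-frequency dynamics
follow the selection/drift HMM (selection coefficient s, dominance h,
initial frequency R0, effective size Ne), and per-month genotype counts
are Dirichlet-multinomial overdispersed around Hardy-Weinberg proportions
(concentration A).  A two-zone variant reproduces the spray/buffer
suppression-experiment design: independent zones (no migration), with
elevated selection in the spray zone only during the spray window.

Default sample sizes follow the annual totals of the Iquitos repository
(hundreds of mosquitoes most years, with sparse early-2000s years and a
3000-strong 2014), spread evenly over 10 sampled months per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeRecord, SampleSeries, month_index
from .pmcmc import HMMParams, simulate_hmm
from .selection import hwe_proportions, step_allele_freq

#: Annual totals of genotyped males in the surveillance repository,
#: 2000-2017 (individuals genotyped at both 1016 and 1534).
DEFAULT_ANNUAL_TOTALS = {
    2000: 628, 2001: 779, 2002: 70, 2003: 389, 2004: 198, 2005: 268,
    2006: 796, 2007: 150, 2008: 216, 2009: 433, 2010: 414, 2011: 250,
    2012: 400, 2013: 331, 2014: 3080, 2015: 149, 2016: 809, 2017: 522,
}

#: Genotype code per one-locus class, per locus.
_CLASS_TO_CODE = {
    1016: {"RR": "II", "RS": "VI", "SS": "VV"},
    1534: {"RR": "CC", "RS": "FC", "SS": "FF"},
    410: {"RR": "LL", "RS": "VL", "SS": "VV"},
}

HAPLOTYPE_ORDER = ("VF", "VC", "IC", "IF")


def monthly_schedule(
    annual_totals: dict[int, int] | None = None,
    months_per_year: int = 10,
    start: tuple[int, int] | None = None,
    end: tuple[int, int] | None = None,
) -> tuple[tuple[int, int], np.ndarray]:
    """Spread annual totals evenly over the first ``months_per_year``
    months of each year; remaining months get n = 0.

    Returns ``(start_month, sizes)`` where ``sizes[t]`` is the sample size
    t months after ``start_month``.
    """
    totals = dict(DEFAULT_ANNUAL_TOTALS if annual_totals is None
                  else annual_totals)
    years = sorted(totals)
    if start is None:
        start = (years[0], 1)
    if end is None:
        end = (years[-1], 12)
    lo, hi = month_index(*start), month_index(*end)
    sizes = np.zeros(hi - lo + 1, dtype=np.int64)
    for year in years:
        per_month, extra = divmod(totals[year], months_per_year)
        for m in range(1, months_per_year + 1):
            t = month_index(year, m) - lo
            if 0 <= t < len(sizes):
                sizes[t] = per_month + (1 if m <= extra else 0)
    return start, sizes


@dataclass
class ScenarioSpec:
    """Everything needed to generate one synthetic temporal dataset."""

    params: HMMParams = field(
        default_factory=lambda: HMMParams(s=0.2, h=0.2, R0=0.25, A=5.0, Ne=500))
    locus: int = 1534
    start: tuple[int, int] = (2002, 10)
    sample_sizes: np.ndarray | None = None   # per-month n; default schedule
    seed: int = 0
    # spray/buffer sub-experiment
    s_spray: float = 0.3
    spray_window: tuple[int, int] = (6, 8)   # month offsets [from, to)

    def resolved_sizes(self) -> np.ndarray:
        if self.sample_sizes is not None:
            return np.asarray(self.sample_sizes, dtype=np.int64)
        _, sizes = monthly_schedule(start=self.start)
        return sizes


def _counts_to_records(months, counts, locus: int, zone: str,
                       prefix: str) -> list[GenotypeRecord]:
    code = _CLASS_TO_CODE[locus]
    col = {1016: "g1016", 1534: "g1534", 410: "g410"}[locus]
    records = []
    i = 0
    for (year, month), row in zip(months, counts):
        for cls, k in zip(("RR", "RS", "SS"), row):
            for _ in range(int(k)):
                records.append(GenotypeRecord(
                    sample_id=f"{prefix}{i:06d}", year=year, month=month,
                    zone=zone, **{col: code[cls]}))
                i += 1
    return records


def generate_temporal_dataset(spec: ScenarioSpec) -> list[GenotypeRecord]:
    """Individual records whose monthly one-locus genotype counts are one
    draw of the selection/drift HMM under ``spec.params``."""
    sizes = spec.resolved_sizes()
    _, series = simulate_hmm(spec.params, sizes, seed=spec.seed,
                             start=spec.start)
    return _counts_to_records(series.months, series.counts, spec.locus,
                              "citywide", "syn")


def generate_two_locus_dataset(
    hap_freqs,
    n: int,
    seed: int,
    year: int = 2014,
    month: int = 1,
    zone: str = "citywide",
) -> list[GenotypeRecord]:
    """``n`` individuals formed by random union of two haplotypes drawn
    i.i.d. from ``hap_freqs`` (order VF, VC, IC, IF); genotypes are
    reported unphased.  The default specs put zero mass on IF, matching
    the empirical absence of the Ile1016/Phe1534 haplotype.
    """
    f = np.asarray(hap_freqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    pairs = rng.choice(4, size=(n, 2), p=f)
    records = []
    for i, (a, b) in enumerate(pairs):
        h1, h2 = HAPLOTYPE_ORDER[a], HAPLOTYPE_ORDER[b]
        n_i = (h1[0] == "I") + (h2[0] == "I")
        n_c = (h1[1] == "C") + (h2[1] == "C")
        g1016 = ("VV", "VI", "II")[n_i]
        g1534 = ("FF", "FC", "CC")[n_c]
        records.append(GenotypeRecord(
            sample_id=f"2loc{i:06d}", year=year, month=month, zone=zone,
            g1016=g1016, g1534=g1534))
    return records


def _simulate_zone(params: HMMParams, s_by_month: np.ndarray,
                   sizes: np.ndarray, start, rng) -> tuple[list, np.ndarray]:
    """Forward simulation with a time-varying selection coefficient."""
    p = params.R0
    two_ne = 2 * params.Ne
    base = month_index(*start)
    months, obs = [], []
    floor = 1e-12
    for t, n_t in enumerate(sizes):
        if n_t > 0:
            probs = np.maximum(hwe_proportions(p), floor)
            probs /= probs.sum()
            g = rng.dirichlet(params.A * probs)
            counts = rng.multinomial(int(n_t), g)
            y, m0 = divmod(base + t, 12)
            months.append((y, m0 + 1))
            obs.append(counts)
        p_det = step_allele_freq(p, float(s_by_month[t]), params.h)
        p = rng.binomial(two_ne, p_det) / two_ne
    return months, np.stack(obs)


def generate_spray_buffer_dataset(
    spec: ScenarioSpec,
) -> tuple[list[GenotypeRecord], list[GenotypeRecord]]:
    """Two independent zone-labelled collections (spray, buffer).

    The spray zone experiences ``spec.s_spray`` only inside
    ``spec.spray_window`` (month offsets, half-open) and s = 0 outside it;
    the buffer zone has s = 0 throughout.  There is no migration between
    zones, mirroring the isolation assumption of the temporal model.
    """
    sizes = spec.resolved_sizes()
    lo, hi = spec.spray_window
    if not 0 <= lo < hi <= len(sizes):
        raise ValueError("spray window must lie inside the simulated horizon")
    rng = np.random.default_rng(spec.seed)
    s_spray = np.zeros(len(sizes))
    s_spray[lo:hi] = spec.s_spray
    s_buffer = np.zeros(len(sizes))

    out = []
    for zone, s_sched in (("spray", s_spray), ("buffer", s_buffer)):
        months, counts = _simulate_zone(spec.params, s_sched, sizes,
                                        spec.start, rng)
        out.append(_counts_to_records(months, counts, spec.locus, zone,
                                      f"{zone[:2]}"))
    return out[0], out[1]
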