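# Methods

`kdrpop` analyses temporal and spatial samples of *Aedes aegypti*
genotyped at the knockdown-resistance (kdr) loci of the voltage-gated
sodium channel gene: V1016I, F1534C and (as an LD proxy for 1016) V410L.
This note records the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Data model

One mosquito is one record: collection year and month, a zone label
(`spray`, `buffer`, `citywide`, `unassigned`), and unphased genotype
codes per locus. All models operate on monthly generations, so days are
discarded. Records missing either of the 1016/1534 genotypes are excluded
from two-locus analyses but retained for single-locus analyses at the
locus they do carry, which is why the same collection can have different
denominators across analyses. Counts are tabulated over the 9 ordered
two-locus genotype classes (VV/FF ... II/CC) or the 3 one-locus classes
(RR, RS, SS with R the resistance allele: Ile1016, Cys1534 or Leu410).

## Haplotype imputation under the IF-exclusion constraint

Both loci sit in one gene, so each chromosome carries one of four
haplotypes VF, VC, IC, IF. Phase is unobserved only in the double
heterozygote VI/FC. In American populations the IF (Ile1016/Phe1534)
haplotype is essentially absent — Cys1534 fixed before Ile1016 appeared —
and imposing `exclude_IF` resolves VI/FC deterministically to VF + IC.
Three genotype classes (VI/FF, II/FF, II/FC) cannot exist without an IF
haplotype; by default individuals in these classes are dropped with a
logged count (`infeasible_policy="drop"`), since in the field data they
are rare anomalies consistent with genotyping error or a low-fitness
haplotype. `count_IF_implying` reports them.

Haplotype counts are `2 * counts @ P` with `P` the 9x4 class-to-haplotype
probability matrix. Without the constraint, the VI/FC row is weighted by
the relative probabilities of the two phasings computed from EM haplotype
frequency estimates — a fixed 50/50 split is biased whenever D != 0.

Confidence intervals are Wilson score intervals. The interval method is a
package choice: haplotype frequencies in these data spend most of their
time near 0 or 1, where Wald intervals degenerate and Wilson intervals
remain well-behaved.

## LD, HWE and frequency statistics

Two-locus haplotype frequencies from unphased counts are maximum
likelihood via EM under random mating. The likelihood in the flat-margin
case (all double heterozygotes) has a symmetric saddle at D = 0 where EM
started from uniform frequencies stalls; the default therefore multi-starts
from the uniform point plus one corner initialization per phasing and
returns the highest-likelihood solution. Defaults: tolerance 1e-10 on the
log-likelihood, 10,000 iterations, three starts.

LD statistics use the classical definitions: `D = f_IC - pA*pB` for the
resistance alleles A = Ile1016, B = Cys1534, `D' = D / Dmax` with the
sign-dependent bound, `R2 = D^2 / (pA qA pB qB)` and `chi2 = 2 n R2` with
one degree of freedom (n = individuals, 2n haplotypes). Composite LD
without the random-mating assumption is deliberately not implemented: the
`chi2 = 2 n R2` identity is what the published per-year table obeys.

HWE is the 1-df chi-square test against expected proportions at the
estimated allele frequency, with Bonferroni correction over a
caller-supplied family of monthly tests.

Monthly allele frequencies get a per-month-intercept binomial logit
treatment: the point estimate is the raw allele frequency and the CI is
the Wald interval on the logit scale, back-transformed. At frequency 0 or
1 the logit interval degenerates; such months fall back to the Wilson
interval and are flagged. Zone contrasts are ratios of response-scale
frequencies (spray / buffer) with a delta-method CI on the log ratio and
a two-sided Wald p-value on the logit scale. Reporting frequency ratios
(not odds ratios) is a package decision: statements like "higher by 31%"
read naturally as frequency ratios of 1.31; the logit-scale test statistic
is exposed through the p-value for users who prefer that scale.

## Deterministic selection with dominance

Fitness is a cost to the susceptible allele: `(w_RR, w_RS, w_SS) =
(1, 1-h*s, 1-s)` with s, h in [0, 1]. h = 0 means the heterozygote
behaves like the resistant homozygote (resistance dominant); h = 1 the
reverse. One calendar month is one non-overlapping generation; the
recursion is the standard one-locus viability-selection step under random
mating. This produces the known asymmetry: low h speeds the rise of a
rare resistance allele, high h speeds the final elimination of the
susceptible allele (which then hides in heterozygotes when h is low).

`ml_s_given_h` fits s for fixed h and R0 by maximizing the product of
multinomial likelihoods of observed monthly (RR, RS, SS) counts under HWE
proportions at the deterministic trajectory — a pre-selection census,
since field collections happened irrespective of spray timing. Months
without samples are stepped through silently. The optimizer is a 101-point
grid scan bracketing a bounded scalar refinement to 1e-4; estimates within
tolerance of 0 or 1 are flagged as boundary solutions.

## The genotype-frequency HMM and particle MCMC

The latent state is the monthly resistance allele frequency p_t.
Transition: the deterministic selection step followed by binomial
Wright-Fisher resampling of 2*Ne gametes (Ne fixed, default 500 — the
centre of published estimates for this population; it is not estimated
because no neutral loci were genotyped). Observation: in a sampled month,
genotype counts are Dirichlet-multinomial with concentration `A * HWE(p_t)`;
A is the overdispersion parameter (A -> infinity recovers multinomial
sampling; the benchmark value A = 5 is heavily overdispersed, as monthly
field collections clustered on a few city blocks are). Genotype
probabilities are floored at 1e-12 so the compound pmf stays finite at
fixation. A enters the observation layer only; placing overdispersion in
the process (drift) layer instead would be a different model with no
available oracle, and is a known limitation rather than an option.
Sampling reflects pre-selection HWE proportions, consistent with the
deterministic fit.

The marginal likelihood is estimated by a bootstrap particle filter
(numba-compiled). Weights are carried between observations and
multinomial resampling triggers when the effective sample size falls
below half the particle count; the estimator stays unbiased, and on a
small instance (Ne = 25, so the latent state lives exactly on a 51-point
grid) it agrees with an exact forward-algorithm computation. Resampling
uses the exponential-spacings construction of sorted uniforms, making the
whole filter O(particles) per step. At fixed seed the estimate is a
deterministic function of its inputs.

Inference is particle marginal Metropolis-Hastings over (s, h, R0, A)
with priors Beta(1,1) on the unit-interval parameters and Gamma(0.01,
0.01) on A. Proposals are multivariate normal on (logit s, logit h,
logit R0, log A); after 500 iterations the proposal covariance tracks the
chain's running empirical covariance scaled by 2.38^2/4 (Haario-style
adaptation). The chain initializes at an approximate ML point found by
Nelder-Mead on the particle-filter likelihood with common random numbers.
Production defaults are 1000 particles, 50,000 iterations, 10,000
burn-in, thinning 10. Latent genotype-frequency credible bands are built
by re-running the filter at thinned posterior draws and keeping one
ancestral particle path per draw — a filter-based approximation to the
smoothing distribution that is adequate for plotting bands but slightly
degenerate at early time points when particle diversity is low.

## Wright-Fisher ABC

The ABC estimator targets the same selection process through summary
statistics. The focal allele is the susceptible allele with genotype
fitnesses `(1+s, 1+h*s, 1)` for (SS, SR, RR) and s in [-1, 0]; this is
algebraically identical to the cost parameterization under `s = -cost`
with the same h, so the two estimators' results are directly comparable
via |s|. Simulations run a 2Ne = 1000 chromosome Wright-Fisher population
on the observed sampling schedule; each simulation draws its initial
frequency from Beta(x1+1, n1-x1+1), the posterior given the first
observed sample under a uniform prior.

Each series is summarized by (Fsd', Fsi'): the temporal F statistic
`Fs = (x-y)^2 / (z(1-z))`, `z = (x+y)/2`, for consecutive sample pairs,
with the Jorde-Ryman sample-size correction

    Fs' = [Fs (1 - 1/(2*n_h)) - 2/n_h] / [(1 + Fs/4)(1 - 1/n_y)] / gap

(n_h the harmonic mean of the two sample sizes in chromosomes, n_y the
second sample size, gap the generation distance), averaged separately
over frequency-decreasing and frequency-increasing pairs. Pairs whose
mean frequency is 0 or 1 carry no information and are skipped; an empty
group contributes 0. Under neutrality the two averages estimate the same
quantity — a symmetry the test suite checks by simulation, since the
correction algebra has no closed-form oracle here.

Rejection ABC draws (s, h) uniformly from the prior box, keeps the 1% of
100,000 simulations closest to the observed (Fsd', Fsi') in
variance-standardized Euclidean distance, and reports posterior means and
equal-tailed intervals of |s| and h. Posterior *means* are reported (modes
are available from the accepted draws); with weakly informative summaries
the posterior mean of |s| is pulled toward the prior mean 0.5, which is
visible in the benchmark recovery spread.

## Synthetic data

The generators produce datasets with the statistical structure the
analyses assume: per-month individual records whose one-locus counts are
a draw of the selection/drift HMM; two-locus panels formed by random
union of gametes from a specified haplotype frequency vector (zero IF
mass by default); and a two-zone spray/buffer design in which the spray
zone experiences elevated s only inside a spray window and the zones are
otherwise independent (no migration, mirroring the temporal model's
isolation assumption).

Default sample sizes follow the surveillance repository's annual totals
(9882 genotyped males over 2000-2017, from 70 in the sparsest year to
3080 in the densest), spread evenly over the first ten months of each
year because per-month totals are not published. What the generators do
*not* emulate: spatial structure within a zone, migration, relatedness of
mosquitoes collected from the same house, time-varying insecticide
pressure within the temporal model, and genotyping error. Passing
recovery tests on these benchmarks therefore demonstrates correctness of
the estimators under the models' own assumptions, not robustness to the
violations known to exist in field data (the real collections are
spatially clumped, which inflates LD variance and produces heterozygote
deficits).

## Benchmark problem sizes

The regression benchmarks use reduced problem sizes chosen to exercise
every code path at useful statistical power: the pMCMC benchmark is
s=0.2, h=0.2, R0=0.25, A=5, Ne=500 over 90 months of ~40 mosquitoes,
fitted with 200 particles and 10,000 iterations (2,000 burn-in), with
20-replicate coverage checks for s; the ABC benchmark uses the full
surveillance-scale schedule with 100,000 simulations. Production analyses
should use the full defaults (1000 particles, 50,000 iterations).

## Known limitations

- Ne is fixed, not estimated; s and drift intensity are partially
  confounded at this series length.
- (s, h, R0) are strongly correlated in the posterior (low initial
  frequency + strong selection mimics higher initial frequency + weaker
  selection); credible intervals for h are wide.
- Each locus is modelled marginally; the physical linkage between 1016
  and 1534 is exploited only for imputation, never in the dynamics.
- The latent-path bands are filter (not smoother) paths.
- Selection is constant within the analysis window, although spraying
  was episodic.
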