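# kdrpop

Population genetics of knockdown-resistance (kdr) haplotype evolution in
*Aedes aegypti*.

Pyrethroid insecticides target the voltage-gated sodium channel (VGSC),
and point mutations in its gene — V1016I, F1534C, V410L — confer
knockdown resistance. Because the gene is single-copy, the loci are
physically linked and evolve as haplotypes (VF, VC, IC, IF, writing the
1016 allele first). Long-term surveillance collections of genotyped
mosquitoes let us ask how strongly spraying selected for resistance and
how dominant the resistance alleles are. `kdrpop` provides the full
analysis chain for such data:

- **I/O and tabulation** — per-mosquito CSV records (year, month, zone,
  genotypes) tabulated into genotype count tables and monthly sample
  series.
- **Haplotype imputation** — two-locus haplotype frequencies from
  unphased genotypes under the constraint that the Ile1016/Phe1534 (IF)
  haplotype is absent, which resolves the double heterozygote
  deterministically; Wilson 95% CIs.
- **Popgen statistics** — EM haplotype frequencies, linkage
  disequilibrium (D, D', R², χ² = 2nR²), Hardy-Weinberg χ² tests with
  Bonferroni correction, monthly allele-frequency CIs from a binomial
  logit model, and spray-vs-buffer frequency-ratio contrasts.
- **Deterministic selection model** — monthly generations with genotype
  fitnesses (1, 1−hs, 1−s) for (RR, RS, SS): selection coefficient s is
  the cost to the susceptible allele, dominance h interpolates between
  resistance-dominant (h=0) and resistance-recessive (h=1); plus
  maximum-likelihood fitting of s for fixed h.
- **Genotype-frequency HMM + particle MCMC** — latent allele frequency
  follows selection plus Wright-Fisher drift (2Ne gametes); observed
  monthly genotype counts are Dirichlet-multinomial overdispersed
  (concentration A) around Hardy-Weinberg proportions; (s, h, R₀, A)
  estimated by particle marginal Metropolis-Hastings with adaptive
  multivariate-normal proposals and a numba-compiled bootstrap particle
  filter.
- **Wright-Fisher ABC** — rejection ABC for temporally sampled allele
  counts using the sample-size-corrected temporal statistics (Fsd′, Fsi′),
  reporting |s| and h.
- **Synthetic data** — generators reproducing the statistical structure
  of an 18-year surveillance archive (annual totals 70–3080 mosquitoes)
  and of two-zone spray/buffer suppression experiments.

## Worked example

Simulate a benchmark dataset (s=0.2, h=0.2, R₀=0.25, A=5, Ne=500; 90
months of 40 mosquitoes) and re-estimate the parameters:

```python
import numpy as np
import kdrpop as k

truth = k.HMMParams(s=0.2, h=0.2, R0=0.25, A=5.0, Ne=500)
_, series = k.simulate_hmm(truth, np.full(90, 40), seed=11)

cfg = k.PMCMCConfig(n_particles=200, n_iterations=10_000, burn_in=2_000,
                    thin=10, seed=5, store_paths=False)
draws = k.run_pmcmc(series, cfg)
summary, _ = k.summarize_posterior(draws)
print(summary.round(3))
```

```
  param   mean  median  ci_low  ci_high
0     s  0.235   0.233   0.146    0.335
1     h  0.103   0.081   0.004    0.336
2    R0  0.267   0.265   0.160    0.382
3     A  5.463   5.408   3.746    7.463
```

Each 95% credible interval covers its generating value: the selection
cost to the susceptible allele is ~0.2 per monthly generation, the cost
is nearly recessive in heterozygotes (h ≈ 0.1–0.2, i.e. resistance is
partially dominant), the initial resistance frequency is ~0.25, and the
genotype counts are far noisier than multinomial (A ≈ 5).

The same machinery runs from the shell:

```bash
kdrpop simulate --seed 3 --outdir out/
kdrpop freqs  --input out/genotypes.csv --locus 1534 --outdir out/
kdrpop pmcmc  --input out/genotypes.csv --locus 1534 --seed 4 --outdir out/
```

Every subcommand writes tidy CSVs plus a `manifest.json` recording
inputs, settings and seed; reruns with identical configuration are
byte-identical.

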