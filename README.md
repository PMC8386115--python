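# fatmap

Discovery pipeline for carcass and abdominal-fat trait loci in meat-type
chickens: genotype quality control, Bayesian window-based GWAS, LD-aware
triage of predicted-deleterious SNPs, and single-SNP mixed-model
association — plus a synthetic-population generator so the whole chain runs
and can be validated without access to proprietary breeding data.

## The problem

Commercial broiler populations segregate variants that change carcass
composition (breast, thigh, drumstick and abdominal-fat weight and their
percentages of 42-day body weight).  Mapping them proceeds in two stages:

1. **Window GWAS.**  Whole-genome regression on ~hundreds of thousands of
   array SNPs with a spike-slab (Bayes-alphabet) prior,

   `y = X b + Σ_j a_j β_j δ_j + e`,

   where `a_j` is the alt-allele dosage at marker `j`, `δ_j ~ Bernoulli(1−π)`
   with π = 0.9970 (so a few hundred markers are in the model at a time),
   and `β_j | δ_j = 1 ~ N(0, σ²_βj)`.  A BayesC chain (common marker
   variance) estimates the genetic and residual variances; a BayesB chain
   (per-locus variances) maps effects.  Markers are grouped into
   non-overlapping 1-Mb windows; for every 100th retained MCMC draw the
   percent of genetic variance attributable to each window is computed from
   the sampled effects, and a window is declared significant when its
   posterior mean share exceeds five times the infinitesimal expectation
   (100%/n_windows — 0.53% for a 947-window genome).  The posterior
   probability of association (PPA) is the fraction of draws in which the
   window beats that expectation.

2. **Candidate-SNP association.**  Within significant windows,
   missense SNPs predicted deleterious by SIFT (score ≤ 0.05) are pruned to
   one tag per correlated set (composite r² > 0.7) and tested jointly per
   trait in a linear mixed model,

   `y = X β + W a + Z u + e`,

   with fixed sex and hatch (plus the BW42 covariate for weight traits),
   additive (0/1/2) or genotypic (3-level factor) SNP coding, and a random
   dam-family effect `u ~ N(0, σ²_u I)` fitted by REML with Satterthwaite
   denominator degrees of freedom.  Candidates with no alt-homozygotes
   despite an expected count ≥ 1 under Hardy–Weinberg are additionally
   flagged as possible recessive lethals.

## Worked example

```python
from fatmap.sim import SimConfig, simulate_population
from fatmap.assoc import SnpMixedLM, trait_design
from fatmap.bayes import BayesB, BayesC, GwasConfig
from fatmap.windows import assign_windows, summarize_windows, window_variance_draws

geno, mmap, pheno, annotation, truth = simulate_population(
    SimConfig(seed=1, n_markers=1000, n_chromosomes=4, offspring_per_dam=8))

y, X, fam, used = trait_design(pheno, "ABFW")
cfg = GwasConfig(n_iter=6000, burn_in=1000, seed=1)
priors = BayesC(y, X.to_numpy(float), geno, cfg).fit()
print(priors.summary())
res = BayesB(y, X.to_numpy(float), geno, cfg, priors=priors.variances,
             marker_ids=mmap.marker_ids).fit()
wf = assign_windows(mmap)
shares = window_variance_draws(res.chain.thinned_draws, res.centered_dosage,
                               wf["window_idx"].to_numpy())
print(summarize_windows(shares, wf).query("significant"))

fit = SnpMixedLM.from_tables(pheno, geno, mmap, "ABFW", [truth.focal_marker_id]).fit()
print(fit.summary())
```

Output (736 simulated offspring of 20 sires × 92 dams, 1,000 markers; the
generator plants a focal deleterious SNP with a −3.43 g additive effect on
abdominal-fat weight at alt-allele frequency 0.236):

```
BayesC variance estimation
  genetic variance        58.3772
  residual variance      135.6888
  h2 (marker-based)        0.3008

chromosome  window_mb  ...  pct_genetic_variance  ppa  significant
         1          0  ...             14.868936  1.0         True
         3          0  ...             30.412663  1.0         True
         3          7  ...             34.171378  1.0         True

Mixed-model SNP association (REML, Satterthwaite df)
  n = 736, families = 92
  sigma2_family = 32.1975   sigma2_resid = 158.7335
  ...
  snp_4_4730821            -2.2296    1.0072   540.0    0.0273
```

The BayesC heritability (~0.30) reflects the configured QTL (25%) plus the
planted focal effect; the windows holding the large simulated QTL carry
essentially all posterior variance with PPA 1.0; and the mixed model
recovers the planted negative fat effect (−2.23 ± 1.01 g, within 1.2 SE of
−3.43) at comparison-wise p < 0.05.

The same chain is available from a shell:

```sh
fatmap run-all --seed 1 --out-dir run/   # simulate → qc → gwas → windows → prune → assoc → screen
```

with per-stage subcommands (`fatmap simulate|qc|gwas|windows|prune|assoc|screen`)
that read and write PLINK-style text genotypes, tab-separated tables and a
minimal VCF for sequenced variants.

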