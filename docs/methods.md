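# Methods

This note documents the statistical models, priors, numerical choices and
design decisions in fatmap, and what the synthetic-data validation does and
does not demonstrate.

## Spike-slab whole-genome regression (bayes module)

Model: `y = X b + Σ_j a_j β_j δ_j + e`, with flat priors on the fixed
effects `b` (sex, hatch dummies, and the BW42 covariate for weight traits),
`δ_j ~ Bernoulli(1−π)`, `β_j | δ_j=1 ~ N(0, σ²_βj)`, scaled inverse
chi-square priors on marker and residual variances.  Dosages are mean
imputed and column centered; a marker with zero variance after centering is
permanently excluded (`δ_j = 0`).

* **BayesC** (common σ²_β) is run first to estimate the genetic variance —
  the across-animal variance of `Σ_j a_j β_j δ_j`, averaged over post
  burn-in draws — and the residual variance.  Its chain starts from a
  weakly informative 50/50 split of the phenotypic variance; the posterior
  is data-driven.  The same π is used as in BayesB (overridable).
* **BayesB** (per-locus σ²_βj) uses those estimates as prior scales.  The
  slab scale is the standard conversion from trait-level to per-marker
  variance under the mixture prior:
  `S²_β = Vg (ν−2)/ν / ((1−π) Σ_j 2 p_j (1−p_j))`, with ν = 4 prior df.
  The residual prior scale is `Ve (ν_e−2)/ν_e` so the prior mean matches
  the BayesC estimate.

Sampling is single-site Gibbs in marker-map order, one long chain:
`δ_j` is drawn with `β_j` integrated out (marginal likelihood of the
adjusted right-hand side under inclusion vs exclusion), then `β_j` from its
normal full conditional; per-locus variances from their conditional scaled
inverse chi-square (from the prior when the marker is excluded); the
residual variance last.  Residual and genomic-value vectors are updated
incrementally, making one iteration O(n·k).  The kernel is numba-compiled;
chains are bit-reproducible for a fixed seed.  Defaults mirror the study
design this package models: π = 0.9970, 41,000 iterations, 1,000 burn-in,
marker-effect vectors retained every 100th post-burn-in iteration.
For the top-model-frequency marker the reported effect is the posterior
mean of `β_j` conditional on inclusion (`beta_mean / model_frequency`), a
convention choice since several are defensible.

Setting π = 0 with both variances pinned reduces the sampler to Bayesian
ridge regression; the test suite exploits this closed form as an oracle.

## 1-Mb windows, variance shares and PPA (windows module)

Markers are binned per chromosome by `floor((pos−1)/1e6)` on 1-based
positions, so positions 1..1,000,000 share bin 0; only bins containing a
marker are instantiated, and no window spans a chromosome boundary.  For
each retained draw, the window share is the across-animal variance of the
window's genomic values, normalized over windows to sum to exactly 100%.
(Dividing by the variance of total genomic values instead differs only
through between-window LD covariance and does not yield an exact
decomposition; the normalized form is used so shares always sum to 100%.)
A draw with zero total genetic variance yields uniform shares with a
warning.

Significance: a window is called when its posterior mean share reaches
`fold × 100/n_windows` (fold = 5 by default; 0.53% for 947 windows — the
expectation 100/947 = 0.1056% is computed at full precision, never from a
rounded intermediate).  PPA is the fraction of retained draws whose share
exceeds the infinitesimal expectation; an alternative definition — the
fraction of draws with at least one included marker in the window — is
available via `ppa_mode="inclusion"`.

Trait-level summaries deduplicate significant windows across traits on
(chromosome, window) and sum a trait's significant shares (cumulative
variance).

## Quality control (qc module)

Array QC runs samples → marker call rate → MAF → HWE → chromosome, with
defaults: sample call rate ≥ 0.90, marker call rate ≥ 0.98, MAF ≥ 0.02
(computed on non-missing calls), HWE exact p ≥ 1e−6, and removal of
Z/W/unplaced markers.  The order means a monomorphic marker leaves at the
MAF step and never reaches the HWE test.  Sequenced-variant filters keep
biallelic SNPs with MAF ≥ 0.05, call rate ≥ 0.7, site depth ≥ 15 and
quality ≥ 40 — all inclusive thresholds — attributing each removal to the
first failing predicate in that order.

The HWE exact test is the standard conditional test: given the allele
counts, the p-value sums the probabilities of all heterozygote counts whose
conditional probability does not exceed the observed table's.  It is
computed by an outward ratio recurrence from the observed table
(numerically stable for n in the thousands); the chi-square test (1 df) is
provided as a secondary check and returns missing for monomorphic sites.
Bonferroni correction flags `p < α/m` with m the number of tests in the
table at hand (the candidate-SNP panel, not the genome-wide marker count);
both raw and corrected flags are reported.

## LD pruning and deleterious triage (ld_prune module)

r² is the squared Pearson correlation of dosage vectors over animals
non-missing at both markers (composite-genotype LD; founder phase is not
available in this pipeline's inputs, so no haplotype-EM r²).  Pruning is
greedy with a deterministic visit order — MAF descending, position
ascending — each visited marker tags and removes all others with r² above
the threshold (0.7 default), so the kept set is mutually below threshold.
Deleterious triage keeps annotated markers with SIFT ≤ 0.05 (the standard
deleteriousness convention) whose position falls in a significant window.

## Mixed-model association (assoc module)

For each trait, all candidate SNPs enter one joint model
`y = X β + W a + Z u + e` on complete cases (trait, covariates and all
tested genotypes observed).  With a single family random effect,
`V = σ²_e I + σ²_u Z Z'` is block diagonal and
`(I + λ J_m)⁻¹ = I − λ/(1+λm) J_m` per family, so REML evaluations are
closed form and O(n·p).  The variance ratio `λ = σ²_u/σ²_e` is profiled by
bounded scalar minimization on the log scale over [1e−6, 1e3]; if the
profile is flat down to the lower bound the fit is reported at the λ = 0
boundary with a warning (OLS-equivalent), not as an error.

Per-coefficient t-tests use Satterthwaite denominator df:
`df = 2 f² / (g' I⁻¹ g)` where `f = Var(β̂_i)` as a function of
(σ²_u, σ²_e), `g` its gradient and `I` the observed REML information, both
by central finite differences (relative step 1e−4; cheap and accurate at
these problem sizes).  df is clamped to [1, n−p]; at the boundary the OLS
residual df is used.  Genotypic coding contrasts heterozygote and
alt-homozygote classes against the reference homozygote, omitting an absent
class; it errors when no reference homozygote exists.  Significance is
comparison-wise at p < 0.05, matching the two-stage design in which the
genome-wide multiplicity was already handled by the window GWAS.

The recessive-lethal screen computes the expected alt-homozygote count
`q²·n` with q rounded to 3 decimals by default — the precision at which
such frequencies are reported, and the mode that reproduces published
expectations exactly (full precision differs in the second decimal, e.g.
4.45 vs 4.46 for q = 0.137, n = 237) — plus `(1−q²)^n`, the probability of
observing zero alt-homozygotes under HWE.  A marker is flagged when none
were observed but at least one was expected, optionally requiring a
significant HWE departure.

## Synthetic populations (sim module)

The generator emulates a broiler reference population: 20 sires × 92 dams
(defaults) in full-/half-sib families, five hatches assigned round-robin,
1:1 sexes.  Founder haplotypes are drawn per LD block (default 250 kb) from
a pool of 8 block haplotypes, giving within-block r² of roughly 1/8 on
average and essentially zero between blocks; offspring inherit whole blocks
from each parent with free recombination at block boundaries, so
transmissions are exactly Mendelian.  Block length is a free parameter (no
published LD map for this line); the pool model is sufficient to exercise
window assignment and r² pruning, not a coalescent-realistic LD profile.

Traits: BW42 is simulated first (mean 2,220 g, SD ~260 g with sex and hatch
effects); each weight trait adds its baseline, an allometric regression on
BW42, scaled sex/hatch effects, a shared-QTL genetic value, a dam-family
deviate and residual noise.  Trait means/SDs default to values typical of a
42-day meat-type population (e.g. ABFW 47 g ± 14 g).  The QTL architecture
is spike-slab: `n_qtl` markers share standard-normal raw effects rescaled
per trait so the genetic variance equals `qtl_h2` × trait variance; the
family and residual fractions complete the budget (validated to not exceed
1).  The focal deleterious SNP (alt frequency 0.236) carries a −3.43 g
additive effect on abdominal-fat weight; its effect on ABF% follows
implicitly because percent traits are computed as 100 × weight / BW42.
With `lethal_recessive` set, alt-homozygous offspring at the focal locus
are re-drawn before phenotyping, producing the homozygote deficit the
screen targets.  An annotation table marks the focal SNP missense with
SIFT 0.04 plus configurable decoy deleterious SNPs.

What passing tests on these data show: the sampler finds large planted
signals, window decomposition and PPA behave as designed, REML matches GLS
oracles and is calibrated under the null at study dimensions (n = 237,
41 families).  What they do not show: behavior under real LD (long-range,
heterogeneous), selection-induced disequilibrium, genotyping error,
pedigree errors or genuinely polygenic architectures — none of which the
generator models.

## Problem sizes used in validation

Simulation studies are scaled down from the source population: the window
GWAS power check uses n = 800 animals × 2,000 markers over 40 windows with
a single QTL at 30% of phenotypic variance, 5,000-iteration chains, 20
replicates; effect-size recovery and type-I calibration use the published
association-stage dimensions (n = 237, 41 dam families, alt frequency
0.236) with 100 and 500 replicates.  With only ~40 instantiated windows the
five-fold significance threshold is 12.5% rather than the 0.53% of a
947-window genome, so scaled-down runs call only large planted QTL
significant — the thresholding rule, not its genome-wide operating point,
is what these runs validate.
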