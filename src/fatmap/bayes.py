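"""Bayesian whole-genome regression for window-based GWAS.

Two models from the Bayes-alphabet family are provided as fit-and-summarize
model objects:

``BayesC``
    spike-slab model with a *common* marker-effect variance; used to
    estimate the genetic and residual variances of a trait, which become
    the priors for marker mapping.

``BayesB``
    spike-slab model with a *per-locus* marker-effect variance (scaled
    inverse chi-square prior); its chain summary feeds the 1-Mb window
    variance decomposition.

Both assume y = X b + sum_j a_j beta_j delta_j + e, where a_j is the
centered alt-allele dosage at marker j, delta_j ~ Bernoulli(1 - pi) with pi
the prior exclusion probability (0.9970 by default), and flat priors on the
fixed effects b.  The per-locus slab variance prior scale is derived from
the total genetic variance as

    S2_beta = Vg (nu-2)/nu / ((1 - pi) * sum_j 2 p_j (1 - p_j)),

the usual conversion from trait-level variance to per-marker variance under
the mixture prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._gibbs import run_chain
from .datatypes import FatmapError, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GwasConfig:
    """MCMC settings for the Bayes-alphabet models.

    Defaults follow the study design this pipeline reproduces: pi=0.9970,
    41,000 iterations with 1,000 burn-in, per-marker effect draws retained
    every 100th post-burn-in iteration for the window decomposition, and
    4 prior degrees of freedom on the marker-effect and residual variances.
    """

    pi: float = 0.9970
    n_iter: int = 41_000
    burn_in: int = 1_000
    thin_for_windows: int = 100
    nu_beta: float = 4.0
    nu_e: float = 4.0
    seed: int = 0
    update_marker_var: bool = True
    update_resid_var: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi < 1.0):
            raise FatmapError("pi must lie in [0, 1)")
        if self.burn_in >= self.n_iter:
            raise FatmapError("burn_in must be < n_iter")
        if self.thin_for_windows < 1:
            raise FatmapError("thin_for_windows must be >= 1")


@dataclass(frozen=True)
class VarianceEstimates:
    genetic_variance: float
    residual_variance: float

    def __post_init__(self) -> None:
        if not (self.genetic_variance > 0 and self.residual_variance > 0):
            raise FatmapError("variance estimates must be positive")


@dataclass
class ChainSummary:
    """Posterior summaries from one chain plus thinned effect draws."""

    marker_ids: np.ndarray
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    model_frequency: np.ndarray
    fixed_effects: np.ndarray
    genetic_var_draws: np.ndarray
    residual_var_draws: np.ndarray
    thinned_draws: np.ndarray  # n_thin x k
    config: GwasConfig = field(repr=False, default=None)

    @property
    def n_thinned(self) -> int:
        return self.thinned_draws.shape[0]

    def top_marker(self) -> int:
        """Index of the marker with the highest model frequency."""
        return int(np.argmax(self.model_frequency))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_ids,
            "beta_mean": self.beta_mean,
            "beta_sd": self.beta_sd,
            "model_frequency": self.model_frequency,
        })


def prepare_genotypes(geno) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages and center columns.

    Returns the centered (Fortran-ordered) matrix and per-marker alt-allele
    frequencies p_j (column mean / 2 over non-missing calls).
    """
    dose = geno.dosage if isinstance(geno, GenotypeMatrix) else np.asarray(geno, dtype=float)
    dose = dose.astype(float, copy=True)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(dose, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.nonzero(np.isnan(dose))
    dose[nan_r, nan_c] = col_mean[nan_c]
    centered = dose - dose.mean(axis=0)
    return np.asfortranarray(centered), col_mean / 2.0


def marker_variance_scale(
    genetic_variance: float, p_alt: np.ndarray, pi: float, nu_beta: float
) -> float:
    """Per-locus slab-variance prior scale S2_beta from total genetic variance."""
    het = float(np.sum(2.0 * p_alt * (1.0 - p_alt)))
    if het <= 0:
        raise FatmapError("all markers monomorphic: cannot scale marker variance")
    return genetic_variance * (nu_beta - 2.0) / nu_beta / ((1.0 - pi) * het)


class _BayesAlphabet:
    """Shared preparation for the spike-slab models."""

    per_locus: bool

    def __init__(self, y, fixed_design, genotypes, config: GwasConfig | None = None,
                 marker_ids=None):
        y = np.asarray(y, dtype=float)
        if not np.isfinite(y).all():
            raise FatmapError("non-finite phenotype values; drop missing rows upstream")
        X = np.asarray(fixed_design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.y = y
        self.X = np.ascontiguousarray(X)
        self.A, self.p_alt = prepare_genotypes(genotypes)
        if not (len(y) == self.X.shape[0] == self.A.shape[0]):
            raise FatmapError("y, fixed design and genotypes disagree on n")
        self.config = config or GwasConfig()
        if marker_ids is None and isinstance(genotypes, GenotypeMatrix):
            marker_ids = np.array([f"m{j}" for j in range(genotypes.n_markers)], dtype=object)
        self.marker_ids = (
            np.asarray(marker_ids, dtype=object)
            if marker_ids is not None
            else np.array([f"m{j}" for j in range(self.A.shape[1])], dtype=object)
        )

    def _run(self, s2_b: float, s2_e: float, seed: int | None = None) -> ChainSummary:
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        out = run_chain(
            self.y, self.X, self.A, cfg.pi, self.per_locus,
            cfg.n_iter, cfg.burn_in, cfg.thin_for_windows,
            cfg.nu_beta, s2_b, cfg.nu_e, s2_e,
            cfg.update_marker_var, cfg.update_resid_var, int(seed) % (2**31),
        )
        beta_sum, beta_sumsq, delta_sum, b_sum, genvar, resvar, thinned = out
        n_keep = cfg.n_iter - cfg.burn_in
        mean = beta_sum / n_keep
        var = np.maximum(beta_sumsq / n_keep - mean**2, 0.0)
        return ChainSummary(
            marker_ids=self.marker_ids,
            beta_mean=mean,
            beta_sd=np.sqrt(var),
            model_frequency=delta_sum / n_keep,
            fixed_effects=b_sum / n_keep,
            genetic_var_draws=genvar,
            residual_var_draws=resvar,
            thinned_draws=thinned,
            config=cfg,
        )


class BayesC(_BayesAlphabet):
    """Common-marker-variance spike-slab model; estimates Vg and Ve."""

    per_locus = False

    def fit(self, h2_start: float = 0.5, seed: int | None = None) -> "BayesCResults":
        """Run the chain from a weakly informative split of var(y).

        ``h2_start`` apportions the phenotypic variance between the genetic
        and residual prior scales; the posterior is driven by the data.
        """
        vy = float(np.var(self.y))
        if vy <= 0:
            raise FatmapError("zero-variance phenotype")
        cfg = self.config
        s2_b = marker_variance_scale(h2_start * vy, self.p_alt, cfg.pi, cfg.nu_beta)
        s2_e = (1.0 - h2_start) * vy * (cfg.nu_e - 2.0) / cfg.nu_e
        chain = self._run(s2_b, s2_e, seed)
        est = VarianceEstimates(
            genetic_variance=float(chain.genetic_var_draws.mean()),
            residual_variance=float(chain.residual_var_draws.mean()),
        )
        return BayesCResults(variances=est, chain=chain)


@dataclass
class BayesCResults:
    variances: VarianceEstimates
    chain: ChainSummary

    @property
    def heritability(self) -> float:
        v = self.variances
        return v.genetic_variance / (v.genetic_variance + v.residual_variance)

    def summary(self) -> str:
        v = self.variances
        return (
            "BayesC variance estimation\n"
            f"  genetic variance   {v.genetic_variance:12.4f}\n"
            f"  residual variance  {v.residual_variance:12.4f}\n"
            f"  h2 (marker-based)  {self.heritability:12.4f}\n"
        )


class BayesB(_BayesAlphabet):
    """Per-locus-variance spike-slab model for marker mapping.

    ``priors`` carries the genetic and residual variances (typically the
    BayesC posterior means) that set the scaled-inverse-chi-square prior
    scales.
    """

    per_locus = True

    def __init__(self, y, fixed_design, genotypes, config=None, *,
                 priors: VarianceEstimates, marker_ids=None):
        super().__init__(y, fixed_design, genotypes, config, marker_ids)
        self.priors = priors

    def fit(self, seed: int | None = None) -> "BayesBResults":
        cfg = self.config
        s2_b = marker_variance_scale(
            self.priors.genetic_variance, self.p_alt, cfg.pi, cfg.nu_beta
        )
        s2_e = self.priors.residual_variance * (cfg.nu_e - 2.0) / cfg.nu_e
        chain = self._run(s2_b, s2_e, seed)
        return BayesBResults(chain=chain, centered_dosage=self.A)


@dataclass
class BayesBResults:
    chain: ChainSummary
    centered_dosage: np.ndarray

    def genomic_values(self, draw: np.ndarray | None = None) -> np.ndarray:
        effects = self.chain.beta_mean if draw is None else draw
        return genetic_values(self.centered_dosage, effects, centered=True)

    def summary(self) -> str:
        c = self.chain
        top = c.top_marker()
        return (
            "BayesB marker mapping\n"
            f"  markers                 {len(c.marker_ids):8d}\n"
            f"  thinned window draws    {c.n_thinned:8d}\n"
            f"  mean model frequency    {c.model_frequency.mean():8.4f}\n"
            f"  top marker              {c.marker_ids[top]} "
            f"(model freq {c.model_frequency[top]:.3f}, "
            f"beta|in {self.effect_given_inclusion(top):+.4f})\n"
        )

    def effect_given_inclusion(self, j: int) -> float:
        """Posterior mean of beta_j conditional on delta_j = 1."""
        mf = self.chain.model_frequency[j]
        return float(self.chain.beta_mean[j] / mf) if mf > 0 else 0.0


# -- functional surface -----------------------------------------------------

def fit_bayes_c(y, fixed_design, genotypes, config=None) -> VarianceEstimates:
    """Estimate genetic and residual variances (common-variance model)."""
    return BayesC(y, fixed_design, genotypes, config).fit().variances


def fit_bayes_b(y, fixed_design, genotypes, config=None, priors=None) -> ChainSummary:
    """Map marker effects with per-locus variances; priors from BayesC."""
    if priors is None:
        raise FatmapError("BayesB requires variance priors (run BayesC first)")
    return BayesB(y, fixed_design, genotypes, config, priors=priors).fit().chain


def genetic_values(genotypes, effects, centered: bool = False) -> np.ndarray:
    """Per-animal genomic values: centered dosage matrix times effect vector."""
    effects = np.asarray(effects, dtype=float)
    if centered:
        A = np.asarray(genotypes, dtype=float)
    else:
        A, _ = prepare_genotypes(genotypes)
    if A.shape[1] != effects.shape[0]:
        raise FatmapError("effect vector length does not match marker count")
    return A @ effects
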