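"""Single-SNP mixed-model association and the recessive-lethal screen.

The association model is y = X beta + W a + Z u + e with fixed sex and
hatch effects (plus the BW42 covariate for the weight traits), the
candidate SNPs for a trait fitted jointly in W (additive 0/1/2 dosage or a
genotype factor), and a single random dam-family effect
u ~ N(0, sigma2_u I).  Fitting is by REML with the variance ratio
lambda = sigma2_u / sigma2_e profiled out in a one-dimensional bounded
search; the family-incidence structure of Z makes V-inverse available in
closed form per family, so every REML evaluation is O(n p).  Per-coefficient
t-tests use Satterthwaite denominator degrees of freedom computed from the
REML information matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import FatmapError, WEIGHT_TRAITS
from .qc import allele_frequency, hwe_exact_test

log = logging.getLogger(__name__)

_LAMBDA_BOUNDS = (1e-6, 1e3)


# ---------------------------------------------------------------------------
# REML machinery for a single grouping factor
# ---------------------------------------------------------------------------

class _FamilyStructure:
    """Precomputed group indices for closed-form V-inverse products.

    With Z the family incidence matrix, V = I + lambda Z Z' is block
    diagonal; (I + lambda J_m)^-1 = I - (lambda / (1 + lambda m)) J_m per
    family of size m, and log|V| = sum_f log(1 + lambda m_f).
    """

    def __init__(self, family_labels):
        fam = pd.Categorical(family_labels)
        self.codes = fam.codes.astype(np.int64)
        self.n_families = len(fam.categories)
        self.sizes = np.bincount(self.codes, minlength=self.n_families).astype(float)

    def vinv_dot(self, lam: float, M: np.ndarray) -> np.ndarray:
        """(I + lam ZZ')^-1 @ M for a vector or matrix M."""
        M2 = M[:, None] if M.ndim == 1 else M
        group_sums = np.zeros((self.n_families, M2.shape[1]))
        np.add.at(group_sums, self.codes, M2)
        shrink = lam / (1.0 + lam * self.sizes)
        out = M2 - shrink[self.codes, None] * group_sums[self.codes]
        return out[:, 0] if M.ndim == 1 else out

    def logdet(self, lam: float) -> float:
        return float(np.sum(np.log1p(lam * self.sizes)))


def _reml_profile(lam, y, X, fs):
    """Profiled REML: residual variance concentrated out at fixed lambda.

    Returns (loglik, beta_hat, sigma2_e_hat, XtVinvX).
    """
    n, p = X.shape
    ViX = fs.vinv_dot(lam, X)
    Viy = fs.vinv_dot(lam, y)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    beta = np.linalg.solve(XtViX, XtViy)
    quad = float(y @ Viy - XtViy @ beta)
    sigma2_e = quad / (n - p)
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf, beta, sigma2_e, XtViX
    ll = -0.5 * ((n - p) * np.log(sigma2_e) + fs.logdet(lam) + logdet_xvx + (n - p))
    return ll, beta, sigma2_e, XtViX


def _reml_loglik_full(sigma2_u, sigma2_e, y, X, fs):
    """REML log-likelihood in the absolute (sigma2_u, sigma2_e) parametrization."""
    n, p = X.shape
    if sigma2_e <= 0 or sigma2_u < 0:
        return -np.inf
    lam = sigma2_u / sigma2_e
    ViX = fs.vinv_dot(lam, X)
    Viy = fs.vinv_dot(lam, y)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    beta = np.linalg.solve(XtViX, XtViy)
    quad = float(y @ Viy - XtViy @ beta) / sigma2_e
    sign, logdet_xvx = np.linalg.slogdet(XtViX / sigma2_e)
    if sign <= 0:
        return -np.inf
    logdet_v = n * np.log(sigma2_e) + fs.logdet(lam)
    return -0.5 * (logdet_v + logdet_xvx + quad)


def _coef_variance(sigma2_u, sigma2_e, X, fs):
    """Diagonal of (X' V^-1 X)^-1 with V = sigma2_e I + sigma2_u ZZ'."""
    lam = sigma2_u / sigma2_e
    XtViX = X.T @ fs.vinv_dot(lam, X) / sigma2_e
    return np.diag(np.linalg.inv(XtViX))


def _satterthwaite_df(sigma2_u, sigma2_e, y, X, fs, n_coef):
    """Satterthwaite denominator df per coefficient.

    df_i = 2 f_i^2 / (g_i' H^-1 g_i) with f_i = Var(beta_i_hat) as a
    function of the variance components, g_i its gradient and H the
    observed REML information (numeric derivatives; cheap at these sizes).
    """
    theta = np.array([sigma2_u, sigma2_e])
    h = np.maximum(np.abs(theta), 1e-8) * 1e-4

    def f(th):
        return _coef_variance(max(th[0], 0.0), th[1], X, fs)

    grads = np.empty((n_coef, 2))
    for a in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[a] += h[a]
        tm[a] = max(tm[a] - h[a], 0.0 if a == 0 else 1e-12)
        grads[:, a] = (f(tp) - f(tm)) / (tp[a] - tm[a])

    def ll(th):
        return _reml_loglik_full(th[0], th[1], y, X, fs)

    H = np.empty((2, 2))
    for a in range(2):
        for b_ in range(a, 2):
            ta = theta.copy(); tb = theta.copy(); tab = theta.copy()
            ta[a] += h[a]; tb[b_] += h[b_]; tab[a] += h[a]; tab[b_] += h[b_]
            H[a, b_] = H[b_, a] = (
                ll(tab) - ll(ta) - ll(tb) + ll(theta)
            ) / (h[a] * h[b_])
    info = -H
    fvals = f(theta)
    df = np.empty(n_coef)
    resid_df = X.shape[0] - X.shape[1]
    try:
        info_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        info_inv = None
    for i in range(n_coef):
        denom = float(grads[i] @ info_inv @ grads[i]) if info_inv is not None else 0.0
        if denom <= 0 or not np.isfinite(denom):
            df[i] = resid_df
        else:
            df[i] = 2.0 * fvals[i] ** 2 / denom
    return np.clip(df, 1.0, resid_df)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify aliased columns from the QR diagonal
        _, rmat = np.linalg.qr(arr)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [X.columns[i] for i, d in enumerate(diag) if d < tol]
        raise FatmapError(f"singular fixed design; aliased columns: {aliased}")


class SnpMixedLM:
    """Mixed linear model for joint single-SNP association within a trait.

    Parameters
    ----------
    y : phenotype vector (complete cases).
    fixed : DataFrame of fixed covariates (intercept included).
    snps : DataFrame of SNP columns (dosages or genotype contrasts); these
        are fixed effects too, but reported as the association terms.
    family : dam-family labels (the single random effect).
    """

    def __init__(self, y, fixed: pd.DataFrame, snps: pd.DataFrame, family):
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            raise FatmapError("zero-variance trait")
        if len(pd.unique(pd.Series(list(family)))) < 2:
            raise FatmapError("need at least 2 family levels")
        X = pd.concat([fixed.reset_index(drop=True), snps.reset_index(drop=True)], axis=1)
        if len(y) != len(X) or len(y) != len(list(family)):
            raise FatmapError("y, design and family lengths differ")
        _check_full_rank(X)
        self.y = y
        self.exog = X
        self.snp_names = list(snps.columns)
        self.fs = _FamilyStructure(list(family))

    @classmethod
    def from_tables(cls, pheno: pd.DataFrame, geno, mmap, trait: str,
                    snp_ids, coding: str = "additive"):
        """Build the model from phenotype table + genotypes for one trait.

        Fixed effects: intercept, sex, hatch (and BW42 for weight traits);
        all ``snp_ids`` enter jointly; rows with any missing value among
        the trait, covariates or tested genotypes are dropped
        (complete-case, matching the joint fit).
        """
        y, fixed, fam, used = trait_design(pheno, trait)
        cols = mmap.index_of(snp_ids)
        dose = pd.DataFrame(
            geno.dosage[:, cols],
            columns=list(snp_ids),
            index=pd.Index(geno.animal_ids, name="animal_id"),
        )
        dose = dose.reindex(pheno.loc[used, "animal_id"]).reset_index(drop=True)
        keep = ~dose.isna().any(axis=1).to_numpy()
        y = y[keep]
        fixed = fixed.loc[keep].reset_index(drop=True)
        fam = np.asarray(fam)[keep]
        dose = dose.loc[keep].reset_index(drop=True)
        if coding == "additive":
            snps = dose
        elif coding == "genotypic":
            parts = [genotypic_coding(dose[c].to_numpy(), prefix=str(c)) for c in dose.columns]
            snps = pd.concat(parts, axis=1)
        else:
            raise FatmapError(f"unknown coding {coding!r}")
        return cls(y, fixed, snps, fam)

    def fit(self, ratio: float | None = None) -> "SnpMixedLMResults":
        """REML fit; ``ratio`` pins lambda = sigma2_u/sigma2_e (skips the
        variance search — used for oracle comparisons and boundary checks)."""
        y, X = self.y, self.exog.to_numpy(dtype=float)
        fs = self.fs
        lo, hi = np.log(_LAMBDA_BOUNDS[0]), np.log(_LAMBDA_BOUNDS[1])

        boundary = False
        if ratio is not None:
            lam = float(ratio)
            boundary = lam == 0.0
        else:
            def neg(loglam):
                return -_reml_profile(np.exp(loglam), y, X, fs)[0]

            res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                           options={"xatol": 1e-8})
            lam = float(np.exp(res.x))
            ll0 = -neg(lo)
            if -res.fun <= ll0 + 1e-8:  # flat down to the lower bound: no family variance
                lam = 0.0
                boundary = True
                log.warning("family variance ratio at boundary (~0); OLS-equivalent fit")
        ll, beta, sigma2_e, XtViX = _reml_profile(max(lam, 0.0), y, X, fs)
        sigma2_u = lam * sigma2_e
        cov = sigma2_e * np.linalg.inv(XtViX)
        bse = np.sqrt(np.diag(cov))
        n, p = X.shape
        if boundary or sigma2_u <= 0:
            df = np.full(p, float(n - p))
        else:
            df = _satterthwaite_df(sigma2_u, sigma2_e, y, X, fs, p)
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        return SnpMixedLMResults(
            model=self,
            params=pd.Series(beta, index=self.exog.columns),
            bse=pd.Series(bse, index=self.exog.columns),
            df=pd.Series(df, index=self.exog.columns),
            pvalues=pd.Series(pvals, index=self.exog.columns),
            sigma2_u=float(sigma2_u),
            sigma2_e=float(sigma2_e),
            reml_loglik=float(ll),
            boundary=boundary,
            n_used=n,
        )


@dataclass
class SnpMixedLMResults:
    model: SnpMixedLM
    params: pd.Series
    bse: pd.Series
    df: pd.Series
    pvalues: pd.Series
    sigma2_u: float
    sigma2_e: float
    reml_loglik: float
    boundary: bool
    n_used: int

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    def snp_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Association terms only, with comparison-wise significance flags."""
        names = self.model.snp_names
        return pd.DataFrame({
            "term": names,
            "effect": self.params[names].to_numpy(),
            "se": self.bse[names].to_numpy(),
            "df": self.df[names].to_numpy(),
            "p_value": self.pvalues[names].to_numpy(),
            "significant": self.pvalues[names].to_numpy() < alpha,
            "n_used": self.n_used,
        })

    def summary(self) -> str:
        lines = [
            "Mixed-model SNP association (REML, Satterthwaite df)",
            f"  n = {self.n_used}, families = {self.model.fs.n_families}",
            f"  sigma2_family = {self.sigma2_u:.4f}   sigma2_resid = {self.sigma2_e:.4f}"
            + ("   [boundary]" if self.boundary else ""),
            f"  REML loglik = {self.reml_loglik:.3f}",
            f"  {'term':<22}{'effect':>10}{'se':>10}{'df':>8}{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {str(name):<22}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.df[name]:>8.1f}{self.pvalues[name]:>10.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Design helpers
# ---------------------------------------------------------------------------

def trait_design(pheno: pd.DataFrame, trait: str):
    """Complete-case response + fixed design for one trait.

    Fixed effects: intercept, sex and hatch (dummy-coded, first level
    reference) and, for the weight traits, the BW42 covariate.  Returns
    (y, design frame, family labels, boolean row mask into ``pheno``).
    """
    if trait not in pheno.columns:
        raise FatmapError(f"trait {trait!r} not in phenotype table")
    cols = ["sex", "hatch", "dam_family", trait]
    use_bw42 = trait in WEIGHT_TRAITS
    if use_bw42:
        cols.append("bw42_g")
    used = pheno[cols].notna().all(axis=1)
    sub = pheno.loc[used]
    fixed = pd.DataFrame({"intercept": np.ones(len(sub))}, index=sub.index)
    sex_d = pd.get_dummies(sub["sex"].astype(str), prefix="sex", drop_first=True, dtype=float)
    hatch_d = pd.get_dummies(sub["hatch"].astype(str), prefix="hatch", drop_first=True, dtype=float)
    fixed = pd.concat([fixed, sex_d, hatch_d], axis=1)
    if use_bw42:
        fixed["bw42_g"] = sub["bw42_g"].to_numpy()
    return (
        sub[trait].to_numpy(dtype=float),
        fixed.reset_index(drop=True),
        sub["dam_family"].astype(str).to_numpy(),
        used,
    )


def genotypic_coding(dosage, prefix: str = "GE") -> pd.DataFrame:
    """Genotype-as-factor design: contrasts vs the reference homozygote.

    Returns indicator columns for the heterozygote (``GE1``) and the
    alternative homozygote (``GE2``); an absent genotype class simply
    yields no column for it.  Raises when no reference homozygotes exist
    (no reference level to contrast against).
    """
    d = np.asarray(dosage, dtype=float)
    levels = set(np.unique(d[~np.isnan(d)]).tolist())
    if 0.0 not in levels:
        raise FatmapError("no reference homozygotes: genotypic coding undefined")
    out = {}
    if 1.0 in levels:
        out[f"{prefix}_GE1"] = (d == 1.0).astype(float)
    if 2.0 in levels:
        out[f"{prefix}_GE2"] = (d == 2.0).astype(float)
    if not out:
        raise FatmapError("monomorphic marker: no contrasts to estimate")
    return pd.DataFrame(out)


def fit_lmm(y, fixed: pd.DataFrame, snps: pd.DataFrame, family) -> pd.DataFrame:
    """Functional wrapper: fit the joint mixed model, return the SNP table."""
    return SnpMixedLM(y, fixed, snps, family).fit().snp_table()


# ---------------------------------------------------------------------------
# Recessive-lethal homozygote-deficit screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LethalScreenResult:
    marker_id: str
    observed_hom_alt: int
    expected_hom_alt: float
    prob_zero_given_hwe: float
    flagged: bool


def lethal_recessive_screen(
    counts,
    marker_id: str = "",
    require_hwe_deviation: bool = False,
    hwe_alpha: float = 0.05,
    round_freq: bool = True,
) -> LethalScreenResult:
    """Homozygote-deficit screen for recessive-lethal candidates.

    Expected alt-homozygotes under HWE = q^2 * n with q the alt-allele
    frequency (rounded to 3 dp by default, the precision at which such
    frequencies are reported; ``round_freq=False`` uses full precision).
    ``prob_zero_given_hwe`` = (1 - q^2)^n, the chance of seeing no
    alt-homozygote if HWE held.  A marker is flagged when no alt-homozygote
    was observed yet at least one was expected — optionally also requiring
    a significant HWE departure.
    """
    _, q = allele_frequency(counts)
    if round_freq:
        q = round(q, 3)
    n = counts.n
    expected = q * q * n
    prob_zero = (1.0 - q * q) ** n
    flagged = counts.n_hom_alt == 0 and expected >= 1.0
    if flagged and require_hwe_deviation:
        flagged = hwe_exact_test(counts) < hwe_alpha
    return LethalScreenResult(
        marker_id=marker_id,
        observed_hom_alt=counts.n_hom_alt,
        expected_hom_alt=expected,
        prob_zero_given_hwe=prob_zero,
        flagged=flagged,
    )
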