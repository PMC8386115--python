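"""Mixed-model SNP association: GLS/OLS oracles, REML behaviour,
genotype-factor coding and the homozygote-deficit screen."""

import numpy as np
import pandas as pd
import pytest

from fatmap.assoc import (
    SnpMixedLM,
    _reml_profile,
    _FamilyStructure,
    fit_lmm,
    genotypic_coding,
    lethal_recessive_screen,
    trait_design,
)
from fatmap.datatypes import FatmapError, GenotypeCounts


def _toy_mixed(rng, n_fam=3, per_fam=4, sigma_u=np.sqrt(2.0), sigma_e=1.0, snp_effect=1.5):
    n = n_fam * per_fam
    fam = np.repeat([f"f{i}" for i in range(n_fam)], per_fam)
    dose = rng.binomial(2, 0.4, n).astype(float)
    u = rng.normal(0, sigma_u, n_fam)
    y = 3.0 + snp_effect * dose + u[np.repeat(np.arange(n_fam), per_fam)] \
        + rng.normal(0, sigma_e, n)
    fixed = pd.DataFrame({"intercept": np.ones(n)})
    snps = pd.DataFrame({"snp": dose})
    return y, fixed, snps, fam


def _gls(y, X, V):
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    return np.linalg.solve(XtViX, X.T @ Vi @ y)


class TestOracles:
    def test_estimates_equal_gls_at_true_variance_ratio(self, rng):
        y, fixed, snps, fam = _toy_mixed(rng)
        model = SnpMixedLM(y, fixed, snps, fam)
        res = model.fit(ratio=2.0)  # true sigma2_u / sigma2_e
        X = model.exog.to_numpy(float)
        Z = pd.get_dummies(pd.Series(fam), dtype=float).to_numpy()
        V = np.eye(len(y)) + 2.0 * Z @ Z.T
        oracle = _gls(y, X, V)
        np.testing.assert_allclose(res.params.to_numpy(), oracle, rtol=1e-6)

    def test_zero_family_variance_equals_ols(self, rng):
        # construct y with family means removed from the noise so REML
        # lands on the sigma2_u = 0 boundary
        n_fam, per_fam = 8, 6
        n = n_fam * per_fam
        fam = np.repeat([f"f{i}" for i in range(n_fam)], per_fam)
        dose = rng.binomial(2, 0.4, n).astype(float)
        e = rng.normal(0, 1, n)
        e -= pd.Series(e).groupby(fam).transform("mean").to_numpy()
        y = 2.0 + 0.8 * dose + e
        fixed = pd.DataFrame({"intercept": np.ones(n)})
        model = SnpMixedLM(y, fixed, pd.DataFrame({"snp": dose}), fam)
        res = model.fit()
        assert res.boundary
        X = model.exog.to_numpy(float)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(res.params.to_numpy(), ols, rtol=1e-6)
        # with sigma2_u = 0 the t-test df is the OLS residual df
        assert res.df.iloc[0] == pytest.approx(n - X.shape[1])

    def test_pinned_zero_ratio_is_exact_ols(self, rng):
        y, fixed, snps, fam = _toy_mixed(rng)
        model = SnpMixedLM(y, fixed, snps, fam)
        res = model.fit(ratio=0.0)
        X = model.exog.to_numpy(float)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(res.params.to_numpy(), ols, rtol=1e-10)

    def test_cross_check_against_statsmodels_mixedlm(self, rng):
        import statsmodels.formula.api as smf
        n_fam, per_fam = 20, 8
        n = n_fam * per_fam
        fam = np.repeat([f"f{i}" for i in range(n_fam)], per_fam)
        dose = rng.binomial(2, 0.3, n).astype(float)
        u = rng.normal(0, 1.2, n_fam)
        y = 1.0 - 0.7 * dose + u[np.repeat(np.arange(n_fam), per_fam)] + rng.normal(0, 1, n)
        df = pd.DataFrame({"y": y, "dose": dose, "fam": fam})
        sm_fit = smf.mixedlm("y ~ dose", df, groups="fam").fit(reml=True)
        model = SnpMixedLM(y, pd.DataFrame({"intercept": np.ones(n)}),
                           pd.DataFrame({"dose": dose}), fam)
        res = model.fit()
        assert res.params["dose"] == pytest.approx(sm_fit.params["dose"], rel=1e-4)
        assert res.bse["dose"] == pytest.approx(sm_fit.bse["dose"], rel=1e-3)
        assert res.sigma2_u == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert res.sigma2_e == pytest.approx(sm_fit.scale, rel=1e-3)


class TestRemlBehaviour:
    def test_returned_ratio_beats_grid(self, rng):
        y, fixed, snps, fam = _toy_mixed(rng, n_fam=10, per_fam=5)
        model = SnpMixedLM(y, fixed, snps, fam)
        res = model.fit()
        X = model.exog.to_numpy(float)
        fs = _FamilyStructure(fam)
        lam_hat = res.sigma2_u / res.sigma2_e if res.sigma2_e > 0 else 0.0
        ll_hat = _reml_profile(lam_hat, y, X, fs)[0]
        for lam in np.geomspace(1e-6, 1e3, 50):
            assert ll_hat >= _reml_profile(lam, y, X, fs)[0] - 1e-6

    def test_additive_effect_antisymmetric_under_allele_flip(self, rng):
        y, fixed, snps, fam = _toy_mixed(rng, n_fam=10, per_fam=6)
        res1 = SnpMixedLM(y, fixed, snps, fam).fit(ratio=1.0)
        flipped = pd.DataFrame({"snp": 2.0 - snps["snp"]})
        res2 = SnpMixedLM(y, fixed, flipped, fam).fit(ratio=1.0)
        assert res1.params["snp"] == pytest.approx(-res2.params["snp"], rel=1e-10)
        assert res1.bse["snp"] == pytest.approx(res2.bse["snp"], rel=1e-10)

    def test_satterthwaite_df_bounded_by_ols_residual_df(self, rng):
        y, fixed, snps, fam = _toy_mixed(rng, n_fam=15, per_fam=5)
        model = SnpMixedLM(y, fixed, snps, fam)
        res = model.fit()
        n, p = model.exog.shape
        assert (res.df <= n - p + 1e-9).all()
        assert (res.df >= 1.0).all()

    def test_singular_design_names_aliased_columns(self, rng):
        y, fixed, snps, fam = _toy_mixed(rng)
        snps = snps.assign(dup=snps["snp"])
        with pytest.raises(FatmapError, match="aliased"):
            SnpMixedLM(y, fixed, snps, fam)

    def test_zero_variance_trait_rejected(self, rng):
        _, fixed, snps, fam = _toy_mixed(rng)
        with pytest.raises(FatmapError, match="variance"):
            SnpMixedLM(np.ones(len(fam)), fixed, snps, fam)

    def test_single_family_rejected(self, rng):
        y, fixed, snps, _ = _toy_mixed(rng)
        with pytest.raises(FatmapError, match="family"):
            SnpMixedLM(y, fixed, snps, ["f0"] * len(y))


class TestGenotypicCoding:
    def test_three_levels_two_contrasts(self):
        X = genotypic_coding(np.array([0.0, 1.0, 2.0, 1.0, 0.0]))
        assert list(X.columns) == ["GE_GE1", "GE_GE2"]
        np.testing.assert_array_equal(X["GE_GE1"], [0, 1, 0, 1, 0])
        np.testing.assert_array_equal(X["GE_GE2"], [0, 0, 1, 0, 0])

    def test_missing_alt_homozygote_class_gives_single_contrast(self):
        X = genotypic_coding(np.array([0.0, 1.0, 0.0, 1.0]))
        assert list(X.columns) == ["GE_GE1"]

    def test_all_het_input_no_reference_level(self):
        with pytest.raises(FatmapError, match="reference"):
            genotypic_coding(np.array([1.0, 1.0, 1.0]))


class TestFromTables:
    def test_joint_fit_recovers_planted_effect_direction(self, small_population):
        geno, mmap, pheno, _, truth = small_population
        res = SnpMixedLM.from_tables(
            pheno, geno, mmap, "ABFW", [truth.focal_marker_id], coding="additive"
        ).fit()
        tab = res.snp_table()
        assert tab.loc[0, "effect"] < 0  # planted -3.43 g
        assert tab.loc[0, "n_used"] == geno.n_animals

    def test_bw42_covariate_only_for_weight_traits(self, small_population):
        _, _, pheno, _, _ = small_population
        _, fixed_w, _, _ = trait_design(pheno, "ABFW")
        _, fixed_p, _, _ = trait_design(pheno, "ABF%")
        assert "bw42_g" in fixed_w.columns
        assert "bw42_g" not in fixed_p.columns

    def test_genotypic_coding_through_from_tables(self, small_population):
        geno, mmap, pheno, _, truth = small_population
        res = SnpMixedLM.from_tables(
            pheno, geno, mmap, "ABF%", [truth.focal_marker_id], coding="genotypic"
        ).fit()
        ge_terms = [t for t in res.model.snp_names if "GE" in t]
        assert 1 <= len(ge_terms) <= 2

    def test_functional_wrapper_returns_snp_table(self, rng):
        y, fixed, snps, fam = _toy_mixed(rng, n_fam=12, per_fam=5)
        tab = fit_lmm(y, fixed, snps, fam)
        assert set(["term", "effect", "se", "df", "p_value"]).issubset(tab.columns)


class TestLethalScreen:
    def test_homozygote_deficit_expectation(self):
        res = lethal_recessive_screen(GenotypeCounts(172, 65, 0), marker_id="x")
        assert round(res.expected_hom_alt, 2) == 4.45  # q = 0.137 at 3 dp
        assert res.flagged

    def test_full_precision_mode(self):
        res = lethal_recessive_screen(GenotypeCounts(172, 65, 0), round_freq=False)
        assert round(res.expected_hom_alt, 2) == 4.46

    def test_observed_homozygotes_not_flagged(self):
        res = lethal_recessive_screen(GenotypeCounts(100, 50, 6))
        assert not res.flagged

    def test_monomorphic_reference(self):
        res = lethal_recessive_screen(GenotypeCounts(100, 0, 0))
        assert res.expected_hom_alt == 0.0
        assert res.prob_zero_given_hwe == 1.0
        assert not res.flagged

    def test_hwe_requirement_gates_flag(self):
        # deficit present and HWE departure significant -> still flagged
        res = lethal_recessive_screen(GenotypeCounts(172, 65, 0),
                                      require_hwe_deviation=True)
        assert res.flagged == (res.expected_hom_alt >= 1)
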