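"""Allele frequencies, Hardy-Weinberg tests and the filtering chains.

The exact-test authority here is a brute-force enumeration oracle built
directly from log-gamma multinomial probabilities, independent of the
package's recurrence-based implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from fatmap.datatypes import FatmapError, GenotypeCounts, MarkerMap, SeqVariant
from fatmap.qc import (
    ArrayQcThresholds,
    allele_frequency,
    array_qc,
    bonferroni,
    filter_sequenced_variants,
    genotype_counts_from_dosage,
    hwe_chi2_test,
    hwe_exact_test,
    hwe_table,
)

from conftest import make_genotypes


def hwe_exact_enumeration(counts: GenotypeCounts) -> float:
    """Independent oracle: enumerate every feasible heterozygote count and
    sum the conditional probabilities of tables no more probable than the
    observed one (probabilities from log-gamma factorials)."""
    n = counts.n
    na = counts.n_alt_alleles
    nr = 2 * n - na

    def logp(h):
        hom_alt = (na - h) // 2
        hom_ref = (nr - h) // 2
        return (
            gammaln(n + 1) - gammaln(hom_ref + 1) - gammaln(h + 1) - gammaln(hom_alt + 1)
            + h * math.log(2)
            + gammaln(na + 1) + gammaln(nr + 1) - gammaln(2 * n + 1)
        )

    hets = range(na % 2, min(na, nr) + 1, 2)
    probs = {h: math.exp(logp(h)) for h in hets}
    total = sum(probs.values())
    p_obs = probs[counts.n_het] / total
    return min(sum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-9)), 1.0)


class TestAlleleFrequency:
    @pytest.mark.parametrize("counts, ref3, alt3", [
        ((146, 70, 21), 0.764, 0.236),   # a missense candidate's genotype table
        ((1, 38, 198), 0.084, 0.916),
        ((10, 0, 0), 1.0, 0.0),
    ])
    def test_published_style_tables(self, counts, ref3, alt3):
        ref, alt = allele_frequency(GenotypeCounts(*counts))
        assert round(ref, 3) == ref3
        assert round(alt, 3) == alt3

    def test_frequencies_sum_to_one_exactly(self, rng):
        for _ in range(50):
            c = GenotypeCounts(*(int(x) for x in rng.integers(0, 100, 3) + [1, 0, 0]))
            ref, alt = allele_frequency(c)
            assert ref + alt == 1.0


class TestHweExact:
    def test_modal_table_has_p_one(self):
        assert hwe_exact_test(GenotypeCounts(25, 50, 25)) == 1.0

    def test_monomorphic_p_one(self):
        assert hwe_exact_test(GenotypeCounts(40, 0, 0)) == 1.0

    @pytest.mark.parametrize("counts", [(209, 28, 0), (146, 70, 21), (172, 65, 0)])
    def test_matches_enumeration_oracle(self, counts):
        c = GenotypeCounts(*counts)
        assert hwe_exact_test(c) == pytest.approx(hwe_exact_enumeration(c), rel=1e-10)

    def test_extreme_excess_het_is_tiny(self):
        # strong heterozygote excess, the signature of the most extreme
        # departures seen among sequenced candidates
        assert hwe_exact_test(GenotypeCounts(71, 154, 12)) < 1e-6

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    def test_enumeration_property(self, a, b, c):
        if a + b + c == 0 or a + b + c > 200:
            return
        gc = GenotypeCounts(a, b, c)
        assert hwe_exact_test(gc) == pytest.approx(hwe_exact_enumeration(gc), rel=1e-9)


class TestHweChi2:
    def test_perfect_hwe_p_one(self):
        assert hwe_chi2_test(GenotypeCounts(25, 50, 25)) == pytest.approx(1.0)

    def test_matches_hand_arithmetic(self):
        c = GenotypeCounts(146, 70, 21)
        p_ref = (2 * 146 + 70) / 474
        n = 237
        exp = np.array([p_ref**2, 2 * p_ref * (1 - p_ref), (1 - p_ref) ** 2]) * n
        chi2 = ((146 - exp[0]) ** 2 / exp[0] + (70 - exp[1]) ** 2 / exp[1]
                + (21 - exp[2]) ** 2 / exp[2])
        from scipy.stats import chi2 as chi2_dist
        assert hwe_chi2_test(c) == pytest.approx(chi2_dist.sf(chi2, 1), rel=1e-12)

    def test_monomorphic_is_missing(self):
        assert math.isnan(hwe_chi2_test(GenotypeCounts(30, 0, 0)))


class TestBonferroni:
    def test_small_m_arithmetic(self):
        flags = bonferroni(np.array([0.0027] + [0.5] * 17), alpha=0.05)
        assert flags[0] and not flags[1:].any()  # 0.0027 < 0.05/18

    def test_single_test_reduces_to_alpha(self):
        assert bonferroni([0.04]).tolist() == [True]
        assert bonferroni([0.06]).tolist() == [False]

    def test_all_ones_none_flagged(self):
        assert not bonferroni(np.ones(10)).any()


class TestArrayQc:
    def _map(self, k, chroms=None):
        return MarkerMap(pd.DataFrame({
            "marker_id": [f"m{j}" for j in range(k)],
            "chromosome": chroms if chroms is not None else ["1"] * k,
            "position_bp": np.arange(1, k + 1) * 1000,
            "ref_allele": ["A"] * k,
            "alt_allele": ["G"] * k,
        }))

    def test_low_call_rate_marker_removed(self, rng):
        geno = make_genotypes(rng, 100, 50)
        dose = geno.dosage.copy()
        dose[:3, 2] = np.nan  # 3% missing < 98% call rate; animals stay above 90%
        geno = type(geno)(geno.animal_ids, dose)
        _, mmap_f, report = array_qc(geno, self._map(50))
        assert "m2" not in mmap_f.marker_ids
        assert report.to_frame().set_index("step").loc["marker_call_rate", "removed"] == 1

    def test_low_maf_marker_removed_at_maf_step(self, rng):
        geno = make_genotypes(rng, 200, 6, freqs=np.array([0.5] * 5 + [0.01]))
        _, mmap_f, report = array_qc(geno, self._map(6))
        assert "m5" not in mmap_f.marker_ids
        steps = report.to_frame().set_index("step")
        assert steps.loc["maf", "removed"] >= 1

    def test_monomorphic_removed_at_maf_never_reaches_hwe(self, rng):
        geno = make_genotypes(rng, 150, 4, freqs=np.array([0.5, 0.5, 0.5, 0.0]))
        _, mmap_f, report = array_qc(geno, self._map(4))
        steps = report.to_frame().set_index("step")
        assert steps.loc["maf", "removed"] == 1
        assert steps.loc["hwe", "removed"] == 0

    def test_sex_chromosome_markers_dropped(self, rng):
        geno = make_genotypes(rng, 120, 4)
        _, mmap_f, _ = array_qc(geno, self._map(4, chroms=["1", "Z", "W", "2"]))
        assert set(mmap_f.table["chromosome"]) == {"1", "2"}

    def test_idempotent(self, rng):
        geno = make_genotypes(rng, 150, 40, missing_rate=0.002)
        g1, m1, _ = array_qc(geno, self._map(40))
        g2, m2, _ = array_qc(g1, m1)
        np.testing.assert_array_equal(g1.dosage, g2.dosage)
        pd.testing.assert_frame_equal(m1.table, m2.table)

    def test_all_removed_raises(self, rng):
        geno = make_genotypes(rng, 100, 3, freqs=np.array([0.0, 0.0, 1.0]))
        with pytest.raises(FatmapError, match="every marker"):
            array_qc(geno, self._map(3))


def _seq_variant(vid, ref="C", alts=("T",), genos=None, depth=20.0, qual=50.0):
    genos = genos if genos is not None else np.array([0.0, 1.0, 1.0, 2.0, 1.0, 0.0] * 20)
    return SeqVariant(vid, "26", 1, ref, tuple(alts), np.asarray(genos, float), depth, qual)


class TestSequencedVariantFilters:
    def test_six_variant_fixture_one_survivor(self):
        variants = [
            _seq_variant("indel", ref="CA"),
            _seq_variant("triallelic", alts=("T", "G")),
            _seq_variant("rare", genos=np.array([0.0] * 97 + [1.0] * 3 + [0.0] * 20)),
            _seq_variant("shallow", depth=10.0),
            _seq_variant("lowqual", qual=30.0),
            _seq_variant("pass"),
        ]
        kept, report = filter_sequenced_variants(variants)
        assert [v.marker_id for v in kept] == ["pass"]
        removed = {s["step"]: s["removed"] for s in report.steps}
        assert removed == {"indel": 1, "maf": 1, "call_rate": 0,
                           "biallelic": 1, "depth": 1, "qual": 1}

    def test_empty_input(self):
        kept, _ = filter_sequenced_variants([])
        assert kept == []

    def test_thresholds_are_inclusive(self):
        # exactly MAF 0.05 (10 het of 100), depth 15, qual 40 -> kept
        genos = np.array([1.0] * 10 + [0.0] * 90)
        v = _seq_variant("edge", genos=genos, depth=15.0, qual=40.0)
        kept, _ = filter_sequenced_variants([v])
        assert len(kept) == 1


class TestHweTable:
    def test_flags_raw_and_corrected(self):
        counts = [GenotypeCounts(71, 154, 12), GenotypeCounts(25, 50, 25),
                  GenotypeCounts(105, 93, 39)]
        tab = hwe_table(counts, marker_ids=["x", "y", "z"])
        assert bool(tab.loc[0, "significant_raw"]) and bool(tab.loc[0, "significant_bonferroni"])
        assert not tab.loc[1, "significant_raw"]
        assert tab["hwe_exact_p"].between(0, 1).all()

    def test_counts_from_dosage(self):
        gc = genotype_counts_from_dosage(np.array([0, 0, 1, 2, np.nan, 1.0]))
        assert (gc.n_hom_ref, gc.n_het, gc.n_hom_alt) == (2, 2, 1)
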