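"""Genotype quality control: allele frequencies, Hardy-Weinberg testing and
the array / sequenced-variant filtering rules.

Array filters run in the order samples -> marker call rate -> MAF -> HWE ->
chromosome; MAF is computed on non-missing calls only.  The HWE exact test
is the standard conditional test: summing, over all heterozygote counts
compatible with the observed allele counts, the probabilities of tables no
more probable than the observed one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FatmapError, GenotypeCounts, GenotypeMatrix, MarkerMap, QcReport, SeqVariant

log = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"Z", "W", "z", "w"})
UNPLACED_LABELS = frozenset({"0", "Un", "un", "unplaced", "NA"})


def allele_frequency(counts: GenotypeCounts) -> tuple[float, float]:
    """Reference and alternative allele frequencies from genotype counts."""
    two_n = 2 * counts.n
    ref = (2 * counts.n_hom_ref + counts.n_het) / two_n
    return ref, 1.0 - ref


def _het_probabilities(n_het_obs: int, n_alt: int, n: int):
    """Conditional probabilities of all feasible heterozygote counts.

    Given ``n`` diploids and ``n_alt`` copies of the rarer-or-not allele,
    the heterozygote count has the same parity as ``n_alt``.  Uses the
    stable ratio recurrence outward from the observed table.
    """
    n_ref = 2 * n - n_alt
    het_min = n_alt % 2
    het_max = min(n_alt, n_ref)
    hets = list(range(het_min, het_max + 1, 2))
    # unnormalized probability ratios via the recurrence
    #   P(h+2)/P(h) = (n_alt-h)(n_ref-h) / ((h+2)(h+1))  ... up to the
    # hom-count factorials, folded in below.
    probs = {}
    h0 = hets[len(hets) // 2]
    probs[h0] = 1.0
    for h in range(h0, het_max - 1, 2):
        hom_alt = (n_alt - h) // 2
        hom_ref = (n_ref - h) // 2
        probs[h + 2] = probs[h] * 4.0 * hom_alt * hom_ref / ((h + 2.0) * (h + 1.0))
    for h in range(h0, het_min + 1, -2):
        hom_alt = (n_alt - h) // 2
        hom_ref = (n_ref - h) // 2
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (hom_alt + 1.0) * (hom_ref + 1.0))
    total = math.fsum(probs.values())
    return {h: p / total for h, p in probs.items()}


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact Hardy-Weinberg test p-value.

    p = sum of conditional probabilities (given allele counts) of all
    heterozygote counts whose probability does not exceed the observed
    table's, the standard exact-test definition.
    """
    n_alt = counts.n_alt_alleles
    if n_alt == 0 or n_alt == 2 * counts.n:
        return 1.0  # monomorphic: the observed table is the only table
    probs = _het_probabilities(counts.n_het, n_alt, counts.n)
    p_obs = probs[counts.n_het]
    # small tolerance so ties are counted despite floating rounding
    p = math.fsum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))
    return min(p, 1.0)


def hwe_chi2_test(counts: GenotypeCounts) -> float:
    """1-df chi-square test against HWE-expected genotype counts.

    Returns NaN (with a warning) when any expected cell is zero, i.e. for
    monomorphic sites.
    """
    p_ref, p_alt = allele_frequency(counts)
    n = counts.n
    expected = np.array([p_ref**2, 2 * p_ref * p_alt, p_alt**2]) * n
    if np.any(expected == 0):
        log.warning("HWE chi-square undefined: zero expected genotype count")
        return float("nan")
    observed = np.array([counts.n_hom_ref, counts.n_het, counts.n_hom_alt], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Flag p-values significant under Bonferroni correction (p < alpha/m)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    return p < alpha / m


def genotype_counts_from_dosage(dosage_column: np.ndarray) -> GenotypeCounts:
    d = np.asarray(dosage_column, dtype=float)
    d = d[~np.isnan(d)]
    return GenotypeCounts(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


@dataclass(frozen=True)
class ArrayQcThresholds:
    """Defaults mirror a 600K-array pipeline: sample call rate >= 0.90,
    marker call rate >= 0.98, MAF >= 0.02, HWE exact p >= 1e-6, and removal
    of sex-chromosome / unplaced markers."""

    sample_call_rate: float = 0.90
    marker_call_rate: float = 0.98
    maf: float = 0.02
    hwe_p: float = 1e-6
    drop_chromosomes: frozenset = frozenset(SEX_CHROMOSOMES | UNPLACED_LABELS)


def array_qc(
    geno: GenotypeMatrix,
    mmap: MarkerMap,
    thresholds: ArrayQcThresholds | None = None,
) -> tuple[GenotypeMatrix, MarkerMap, QcReport]:
    """Apply the array QC chain: samples, marker call rate, MAF, HWE, chromosome.

    Each step records kept/removed counts; raising if no marker survives.
    """
    th = thresholds or ArrayQcThresholds()
    report = QcReport(thresholds={
        "sample_call_rate": th.sample_call_rate,
        "marker_call_rate": th.marker_call_rate,
        "maf": th.maf,
        "hwe_p": th.hwe_p,
    })

    # samples
    called = ~np.isnan(geno.dosage)
    rate = called.mean(axis=1) if geno.n_markers else np.ones(geno.n_animals)
    keep_animals = rate >= th.sample_call_rate
    report.record("sample_call_rate", "samples", int(keep_animals.sum()), int((~keep_animals).sum()))
    geno = geno.subset_animals(np.flatnonzero(keep_animals))

    keep = np.ones(geno.n_markers, dtype=bool)

    # marker call rate
    called = ~np.isnan(geno.dosage)
    m_rate = called.mean(axis=0) if geno.n_animals else np.zeros(geno.n_markers)
    step = keep & (m_rate >= th.marker_call_rate)
    report.record("marker_call_rate", "markers", int(step.sum()), int((keep & ~step).sum()))
    keep = step

    # MAF on non-missing calls
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(geno.dosage, axis=0) / 2.0
    maf = np.fmin(p_alt, 1.0 - p_alt)
    maf = np.where(np.isnan(maf), 0.0, maf)
    step = keep & (maf >= th.maf)
    report.record("maf", "markers", int(step.sum()), int((keep & ~step).sum()))
    keep = step

    # HWE exact test — only on markers still in play (monomorphics are gone)
    hwe_keep = keep.copy()
    for j in np.flatnonzero(keep):
        counts = genotype_counts_from_dosage(geno.dosage[:, j])
        if hwe_exact_test(counts) < th.hwe_p:
            hwe_keep[j] = False
    report.record("hwe", "markers", int(hwe_keep.sum()), int((keep & ~hwe_keep).sum()))
    keep = hwe_keep

    # chromosome
    chrom = mmap.table["chromosome"].astype(str).to_numpy()
    step = keep & ~np.isin(chrom, list(th.drop_chromosomes))
    report.record("chromosome", "markers", int(step.sum()), int((keep & ~step).sum()))
    keep = step

    if not keep.any():
        raise FatmapError("array QC removed every marker")

    idx = np.flatnonzero(keep)
    out_map = MarkerMap(mmap.table.iloc[idx].reset_index(drop=True))
    return geno.subset_markers(idx), out_map, report


#: sequenced-variant predicates, applied in order; the first failing one
#: is the attributed removal reason.
SEQ_FILTER_ORDER = ("indel", "maf", "call_rate", "biallelic", "depth", "qual")


@dataclass(frozen=True)
class SeqVariantThresholds:
    maf: float = 0.05
    call_rate: float = 0.7
    depth: float = 15.0
    qual: float = 40.0


def filter_sequenced_variants(
    variants: list[SeqVariant],
    thresholds: SeqVariantThresholds | None = None,
) -> tuple[list[SeqVariant], QcReport]:
    """Post-calling filters for sequenced variants.

    Keeps biallelic SNPs (no indels) with MAF >= 0.05, call rate >= 0.7,
    site depth >= 15 and site quality >= 40 (all thresholds inclusive).
    """
    th = thresholds or SeqVariantThresholds()
    report = QcReport(thresholds={
        "maf": th.maf, "call_rate": th.call_rate, "depth": th.depth, "qual": th.qual,
    })
    kept: list[SeqVariant] = []
    removed = dict.fromkeys(SEQ_FILTER_ORDER, 0)
    for v in variants:
        if v.is_indel:
            removed["indel"] += 1
        elif v.maf < th.maf:
            removed["maf"] += 1
        elif v.call_rate < th.call_rate:
            removed["call_rate"] += 1
        elif not v.is_biallelic:
            removed["biallelic"] += 1
        elif not (v.depth >= th.depth):
            removed["depth"] += 1
        elif not (v.qual >= th.qual):
            removed["qual"] += 1
        else:
            kept.append(v)
    running = len(variants)
    for step in SEQ_FILTER_ORDER:
        report.record(step, "variants", running - removed[step], removed[step])
        running -= removed[step]
    return kept, report


def hwe_table(
    counts_list: list[GenotypeCounts],
    marker_ids=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Allele/genotype frequencies plus exact HWE p per site, with both raw
    (p < alpha) and Bonferroni-corrected significance flags."""
    rows = []
    for c in counts_list:
        ref, alt = allele_frequency(c)
        rows.append({
            "n_hom_ref": c.n_hom_ref, "n_het": c.n_het, "n_hom_alt": c.n_hom_alt,
            "ref_freq": ref, "alt_freq": alt, "hwe_exact_p": hwe_exact_test(c),
        })
    out = pd.DataFrame(rows)
    if marker_ids is not None:
        out.insert(0, "marker_id", list(marker_ids))
    out["significant_raw"] = out["hwe_exact_p"] < alpha
    out["significant_bonferroni"] = bonferroni(out["hwe_exact_p"].to_numpy(), alpha)
    return out
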