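"""Synthetic populations with the structure the analysis chain assumes.

The generator emulates a broiler reference population: ~20 sires mated to
~92 dams producing full-/half-sib families over five hatches, biallelic
SNPs with blockwise LD (founder haplotypes are drawn from a small pool per
block, offspring inherit whole blocks from each parent), a spike-slab trait
architecture in which most markers are null, a focal predicted-deleterious
SNP with a negative additive effect on abdominal-fat weight, and a
dam-family random effect.  Every run returns a truth record so downstream
stages can be scored against a known generative model.

Trait construction: body weight at 42 days (BW42) is simulated first; each
carcass weight trait is its own baseline plus an allometric regression on
BW42, sex and hatch effects, the shared-QTL genetic value scaled to the
trait's variance budget, a dam-family deviate and residual noise.  Percent
traits are 100 x weight / BW42, so the focal SNP's effect on abdominal-fat
percentage is implied by its effect in grams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ALL_TRAITS,
    FatmapError,
    GenotypeMatrix,
    MarkerMap,
    PERCENT_TRAITS,
    WEIGHT_TRAITS,
    validate_phenotypes,
)
from .windows import assign_windows, window_variance_draws

#: baseline trait means (g) and phenotypic SDs (g) typical of a 42-day
#: meat-type population; BW42 in grams.
TRAIT_MEANS = {"BTW": 499.0, "THW": 310.0, "DRW": 205.0, "ABFW": 47.1}
TRAIT_SDS = {"BTW": 65.0, "THW": 46.0, "DRW": 31.0, "ABFW": 14.0}
BW42_MEAN = 2220.0
BW42_SD = 210.0


@dataclass(frozen=True)
class FocalDeleterious:
    """The planted candidate-causal SNP (abdominal-fat effect)."""

    allele_freq: float = 0.236
    additive_effect_g: float = -3.43  # grams of ABFW per alt-allele copy
    additive_effect_pct: float = -0.17  # implied ABF% effect (for the record)
    lethal_recessive: bool = False


@dataclass(frozen=True)
class SimConfig:
    n_sires: int = 20
    n_dams: int = 92
    offspring_per_dam: int = 15
    n_hatches: int = 5
    n_chromosomes: int = 5
    chromosome_length_bp: int = 10_000_000
    n_markers: int = 2_000
    ld_block_len_bp: int = 250_000
    haplotypes_per_block: int = 8
    n_qtl: int = 10
    qtl_h2: float = 0.25  # fraction of trait variance from the shared QTL
    family_variance_fraction: float = 0.10
    focal_deleterious: FocalDeleterious = field(default_factory=FocalDeleterious)
    sex_effect_g: float = 120.0  # male-minus-female BW42 difference, grams
    hatch_effects_g: tuple = (0.0, 15.0, -10.0, 25.0, -30.0)  # BW42 scale
    residual_sd: float | None = None  # overrides the per-trait residual budget
    n_decoy_deleterious: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.qtl_h2 <= 1 and 0 <= self.family_variance_fraction <= 1):
            raise FatmapError("variance fractions must lie in [0, 1]")
        if self.qtl_h2 + self.family_variance_fraction > 1:
            raise FatmapError("variance budget exceeds 1: infeasible")
        if self.n_markers < self.n_qtl + 1:
            raise FatmapError("need n_markers >= n_qtl + 1")
        if len(self.hatch_effects_g) < self.n_hatches:
            raise FatmapError("hatch_effects_g shorter than n_hatches")


@dataclass
class SimTruth:
    """Generative ground truth for scoring downstream stages."""

    qtl_marker_ids: np.ndarray
    effects: dict  # trait -> length-k effect vector (beta_j delta_j)
    window_shares: dict  # trait -> per-window true percent shares
    window_frame: pd.DataFrame
    family_effects: dict  # trait -> {family: u}
    variance_components: dict  # trait -> {"qtl", "family", "residual"}
    focal_marker_id: str
    focal_effect_g: float
    sire_dosage: np.ndarray = None  # n_sires x k founder dosages
    dam_dosage: np.ndarray = None  # n_dams x k
    pedigree: np.ndarray = None  # n_offspring x 2 (sire index, dam index)


def _draw_marker_map(cfg: SimConfig, rng) -> MarkerMap:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_markers // cfg.n_chromosomes)
    per_chrom[: cfg.n_markers % cfg.n_chromosomes] += 1
    rows = []
    for c in range(cfg.n_chromosomes):
        pos = np.sort(rng.choice(np.arange(1, cfg.chromosome_length_bp + 1),
                                 size=per_chrom[c], replace=False))
        for p in pos:
            rows.append((f"snp_{c + 1}_{p}", str(c + 1), int(p)))
    ref = rng.choice(list("ACGT"), size=len(rows))
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    return MarkerMap(pd.DataFrame({
        "marker_id": [r[0] for r in rows],
        "chromosome": [r[1] for r in rows],
        "position_bp": [r[2] for r in rows],
        "ref_allele": ref,
        "alt_allele": alt,
    }))


def _block_ids(mmap: MarkerMap, block_len: int) -> np.ndarray:
    """Dense block index per marker; blocks never span chromosomes."""
    t = mmap.table
    keys = list(zip(t["chromosome"], (t["position_bp"].to_numpy() - 1) // block_len))
    uniq = {k: i for i, k in enumerate(dict.fromkeys(keys))}
    return np.array([uniq[k] for k in keys])


def _founder_haplotypes(cfg, k, blocks, focal_idx, rng):
    """Two haplotypes per founder, block-copied from per-block pools."""
    n_founders = cfg.n_sires + cfg.n_dams
    n_blocks = blocks.max() + 1
    H = cfg.haplotypes_per_block
    freq = rng.uniform(0.1, 0.9, size=k)
    pools = []  # per block: H x markers_in_block 0/1 array
    block_cols = [np.flatnonzero(blocks == b) for b in range(n_blocks)]
    for cols in block_cols:
        pools.append((rng.random((H, cols.size)) < freq[cols]).astype(np.int8))
    haps = np.empty((n_founders, 2, k), dtype=np.int8)
    for b, cols in enumerate(block_cols):
        pick = rng.integers(0, H, size=(n_founders, 2))
        haps[:, :, cols] = pools[b][pick]
    # focal marker: allele drawn independently at the configured frequency
    q = cfg.focal_deleterious.allele_freq
    haps[:, :, focal_idx] = (rng.random((n_founders, 2)) < q).astype(np.int8)
    return haps, block_cols


def _gamete(parent_haps, block_cols, rng):
    """One gamete: whole-block inheritance, free recombination between blocks."""
    k = parent_haps.shape[1]
    gam = np.empty(k, dtype=np.int8)
    choice = rng.integers(0, 2, size=len(block_cols))
    for b, cols in enumerate(block_cols):
        gam[cols] = parent_haps[choice[b]][cols]
    return gam


def simulate_population(config: SimConfig | None = None):
    """Generate (GenotypeMatrix, MarkerMap, PhenotypeTable, annotation, SimTruth).

    Seed-fixed runs are bit-reproducible.  With ``lethal_recessive`` set,
    offspring homozygous for the focal alternative allele are re-drawn
    (censored before phenotyping), producing the homozygote deficit the
    lethal screen looks for.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    mmap = _draw_marker_map(cfg, rng)
    k = mmap.n_markers
    blocks = _block_ids(mmap, cfg.ld_block_len_bp)

    # focal SNP: middle of the first window of the last chromosome
    last_chrom = mmap.table["chromosome"].iloc[-1]
    on_last = mmap.table["chromosome"] == last_chrom
    focal_idx = int(np.flatnonzero(on_last)[on_last.sum() // 2])
    focal_id = mmap.table["marker_id"].iloc[focal_idx]

    haps, block_cols = _founder_haplotypes(cfg, k, blocks, focal_idx, rng)
    sire_haps = haps[: cfg.n_sires]
    dam_haps = haps[cfg.n_sires:]

    # matings: dams assigned to sires round-robin; full sibs within dam
    dam_sire = np.arange(cfg.n_dams) % cfg.n_sires
    n_off = cfg.n_dams * cfg.offspring_per_dam
    lethal = cfg.focal_deleterious.lethal_recessive
    off_dose = np.empty((n_off, k), dtype=np.int8)
    dam_of = np.empty(n_off, dtype=np.int64)
    row = 0
    for d in range(cfg.n_dams):
        s = dam_sire[d]
        for _ in range(cfg.offspring_per_dam):
            for _attempt in range(200):
                g1 = _gamete(sire_haps[s], block_cols, rng)
                g2 = _gamete(dam_haps[d], block_cols, rng)
                dose = g1 + g2
                if not (lethal and dose[focal_idx] == 2):
                    break
            off_dose[row] = dose
            dam_of[row] = d
            row += 1

    animal_ids = np.array([f"an{i + 1:05d}" for i in range(n_off)], dtype=object)
    geno = GenotypeMatrix(animal_ids, off_dose.astype(float))

    # --- trait architecture -------------------------------------------------
    qtl_pool = [j for j in range(k) if j != focal_idx]
    qtl_idx = np.sort(rng.choice(qtl_pool, size=cfg.n_qtl, replace=False)) if cfg.n_qtl else np.array([], dtype=int)
    centered = off_dose - off_dose.mean(axis=0)

    sex = np.tile([0, 1], n_off // 2 + 1)[:n_off]  # 0=F, 1=M, 1:1
    hatch = np.arange(n_off) % cfg.n_hatches
    hatch_eff = np.asarray(cfg.hatch_effects_g[: cfg.n_hatches])

    bw42 = (BW42_MEAN + cfg.sex_effect_g * (sex - 0.5) + hatch_eff[hatch]
            + rng.normal(0.0, BW42_SD, n_off))

    raw_beta = rng.normal(0.0, 1.0, size=cfg.n_qtl)
    effects: dict[str, np.ndarray] = {}
    family_effects: dict[str, dict] = {}
    varcomp: dict[str, dict] = {}
    weights = {}
    fam_labels = np.array([f"fam{d + 1:03d}" for d in dam_of], dtype=object)
    for trait in WEIGHT_TRAITS:
        sd_t = TRAIT_SDS[trait]
        beta = np.zeros(k)
        if cfg.n_qtl:
            g_raw = centered[:, qtl_idx] @ raw_beta
            sd_raw = g_raw.std()
            scale = (np.sqrt(cfg.qtl_h2) * sd_t / sd_raw) if sd_raw > 0 else 0.0
            beta[qtl_idx] = raw_beta * scale
        if trait == "ABFW":
            beta[focal_idx] = cfg.focal_deleterious.additive_effect_g
        g_val = centered @ beta
        fam_sd = np.sqrt(cfg.family_variance_fraction) * sd_t
        u = rng.normal(0.0, fam_sd, size=cfg.n_dams)
        res_sd = (cfg.residual_sd if cfg.residual_sd is not None
                  else np.sqrt(max(1.0 - cfg.qtl_h2 - cfg.family_variance_fraction, 0.0)) * sd_t)
        e = rng.normal(0.0, res_sd, n_off)
        slope = TRAIT_MEANS[trait] / BW42_MEAN  # allometric tie to body weight
        sex_t = cfg.sex_effect_g * slope * (sex - 0.5)
        w = (TRAIT_MEANS[trait] + slope * (bw42 - BW42_MEAN) + sex_t
             + hatch_eff[hatch] * slope + g_val + u[dam_of] + e)
        weights[trait] = np.clip(w, 0.0, None)
        effects[trait] = beta
        family_effects[trait] = {f"fam{d + 1:03d}": float(u[d]) for d in range(cfg.n_dams)}
        varcomp[trait] = {"qtl": float(g_val.var()), "family": float(fam_sd**2),
                          "residual": float(res_sd**2)}

    pheno = pd.DataFrame({
        "animal_id": animal_ids,
        "sex": np.where(sex == 1, "M", "F"),
        "hatch": hatch + 1,
        "dam_family": fam_labels,
        "bw42_g": bw42,
    })
    for trait in WEIGHT_TRAITS:
        pheno[trait] = weights[trait]
    for wt, pt in zip(WEIGHT_TRAITS, PERCENT_TRAITS):
        pheno[pt] = np.clip(100.0 * weights[wt] / bw42, 0.0, 100.0)
    pheno = validate_phenotypes(pheno)

    # --- annotation ---------------------------------------------------------
    ids = mmap.marker_ids
    consequence = np.full(k, "synonymous_variant", dtype=object)
    sift = np.full(k, np.nan)
    consequence[focal_idx] = "missense_variant"
    sift[focal_idx] = 0.04
    decoy_pool = [j for j in range(k) if j != focal_idx]
    decoys = rng.choice(decoy_pool, size=min(cfg.n_decoy_deleterious, len(decoy_pool)),
                        replace=False)
    for j in decoys:
        consequence[j] = "missense_variant"
        sift[j] = float(np.round(rng.uniform(0.0, 0.05), 3))
    annotation = pd.DataFrame({
        "marker_id": ids,
        "gene_symbol": [f"GENE{j // 10}" for j in range(k)],
        "ensembl_gene_id": [f"ENSGALG{j // 10:011d}" for j in range(k)],
        "consequence": consequence,
        "sift_score": sift,
    })

    # --- truth --------------------------------------------------------------
    wframe = assign_windows(mmap)
    window_shares = {}
    for trait in WEIGHT_TRAITS:
        beta = effects[trait]
        if np.any(beta != 0):
            shares = window_variance_draws(beta[None, :], centered.astype(float),
                                           wframe["window_idx"].to_numpy())[0]
        else:
            shares = np.zeros(wframe["window_idx"].max() + 1)
        window_shares[trait] = shares
    truth = SimTruth(
        qtl_marker_ids=ids[qtl_idx],
        effects=effects,
        window_shares=window_shares,
        window_frame=wframe,
        family_effects=family_effects,
        variance_components=varcomp,
        focal_marker_id=focal_id,
        focal_effect_g=cfg.focal_deleterious.additive_effect_g,
        sire_dosage=sire_haps.sum(axis=1),
        dam_dosage=dam_haps.sum(axis=1),
        pedigree=np.column_stack([dam_sire[dam_of], dam_of]),
    )
    return geno, mmap, pheno, annotation, truth
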