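"""Core in-memory containers shared by every pipeline stage.

The pipeline's stages exchange only these types: a marker map, an
allele-dosage genotype matrix aligned to it, a phenotype/covariate table,
variant annotations (VEP-style, with SIFT scores) and per-site genotype
counts.  Dosages count copies of the alternative ("B") allele; missing
genotypes are ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

#: traits measured in grams (BW42-adjusted in association models)
WEIGHT_TRAITS = ("BTW", "THW", "DRW", "ABFW")
#: traits expressed as percent of body weight at 42 days
PERCENT_TRAITS = ("BT%", "TH%", "DR%", "ABF%")
ALL_TRAITS = WEIGHT_TRAITS + PERCENT_TRAITS

_NUCLEOTIDES = frozenset("ACGT")


class FatmapError(ValueError):
    """Base error for malformed inputs."""


@dataclass(frozen=True)
class MarkerMap:
    """Per-marker chromosome, 1-based bp position and alleles.

    Wraps a DataFrame with columns ``marker_id``, ``chromosome``,
    ``position_bp``, ``ref_allele``, ``alt_allele``, sorted by
    (chromosome, position).  Positions are 1-based.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["marker_id", "chromosome", "position_bp", "ref_allele", "alt_allele"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise FatmapError(f"marker map missing columns: {missing}")
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise FatmapError(f"duplicate marker id: {dup!r}")
        if (t["position_bp"] < 1).any():
            raise FatmapError("positions must be >= 1 (1-based)")
        if (t["ref_allele"] == t["alt_allele"]).any():
            bad = t.loc[t["ref_allele"] == t["alt_allele"], "marker_id"].iloc[0]
            raise FatmapError(f"ref and alt allele identical at {bad!r}")
        # canonical order: by chromosome then position, strictly increasing within chrom
        srt = t.sort_values(["chromosome", "position_bp"], kind="mergesort").reset_index(drop=True)
        same = srt["chromosome"].eq(srt["chromosome"].shift()) & srt["position_bp"].eq(
            srt["position_bp"].shift()
        )
        if same.any():
            raise FatmapError("duplicate chromosome/position in marker map")
        object.__setattr__(self, "table", srt)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def index_of(self, marker_ids) -> np.ndarray:
        pos = pd.Index(self.table["marker_id"])
        idx = pos.get_indexer(list(marker_ids))
        if (idx < 0).any():
            unknown = [m for m, i in zip(marker_ids, idx) if i < 0]
            raise FatmapError(f"unknown marker ids: {unknown[:5]}")
        return idx


@dataclass(frozen=True)
class GenotypeMatrix:
    """Animals x markers alt-allele dosages in {0, 1, 2, NaN}."""

    animal_ids: np.ndarray
    dosage: np.ndarray  # float array, n_animals x n_markers

    def __post_init__(self) -> None:
        ids = np.asarray(self.animal_ids, dtype=object)
        dose = np.asarray(self.dosage, dtype=float)
        if dose.ndim != 2:
            raise FatmapError("dosage must be a 2-D array")
        if len(ids) != dose.shape[0]:
            raise FatmapError(
                f"{len(ids)} animal ids but {dose.shape[0]} dosage rows"
            )
        if len(set(ids.tolist())) != len(ids):
            raise FatmapError("animal ids not unique")
        valid = np.isnan(dose) | np.isin(dose, (0.0, 1.0, 2.0))
        if not valid.all():
            raise FatmapError("dosages must be 0, 1, 2 or missing")
        object.__setattr__(self, "animal_ids", ids)
        object.__setattr__(self, "dosage", dose)

    @property
    def n_animals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def subset_markers(self, col_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.animal_ids, self.dosage[:, col_idx])

    def subset_animals(self, row_idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.animal_ids[row_idx], self.dosage[row_idx, :])


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype/covariate table and return it typed.

    Mandatory columns: ``animal_id``, ``sex``, ``hatch``, ``dam_family``,
    ``bw42_g`` plus any subset of the eight trait columns.  Percent traits
    must lie in [0, 100]; weights must be non-negative; any value may be
    missing.
    """
    required = ["animal_id", "sex", "hatch", "dam_family", "bw42_g"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FatmapError(f"phenotype table missing columns: {missing}")
    if table["animal_id"].duplicated().any():
        raise FatmapError("duplicate animal_id in phenotype table")
    out = table.copy()
    for col in ("bw42_g",) + WEIGHT_TRAITS:
        if col in out.columns:
            vals = pd.to_numeric(out[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise FatmapError(f"negative weight in column {col}")
            out[col] = vals
    for col in PERCENT_TRAITS:
        if col in out.columns:
            vals = pd.to_numeric(out[col], errors="coerce")
            ok = vals.dropna().between(0, 100)
            if not ok.all():
                raise FatmapError(f"percent trait {col} outside [0, 100]")
            out[col] = vals
    return out


def validate_annotation(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a VEP-style annotation table (marker, gene, consequence, SIFT)."""
    required = ["marker_id", "gene_symbol", "ensembl_gene_id", "consequence", "sift_score"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FatmapError(f"annotation table missing columns: {missing}")
    out = table.copy()
    sift = pd.to_numeric(out["sift_score"], errors="coerce")
    bad = sift.dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise FatmapError("sift_score outside [0, 1]")
    out["sift_score"] = sift
    return out


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one biallelic site (hom-ref / het / hom-alt)."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        for v in (self.n_hom_ref, self.n_het, self.n_hom_alt):
            if v < 0 or int(v) != v:
                raise FatmapError("genotype counts must be non-negative integers")
        if self.n == 0:
            raise FatmapError("need at least one genotyped animal")

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def n_alt_alleles(self) -> int:
        return 2 * self.n_hom_alt + self.n_het


@dataclass(frozen=True)
class SeqVariant:
    """One site from targeted/whole-genome sequencing with site-level QC fields."""

    marker_id: str
    chromosome: str
    position_bp: int
    ref_allele: str
    alt_alleles: tuple  # one entry for biallelic sites
    genotypes: np.ndarray  # per-animal dosage of first alt, NaN = no call
    depth: float
    qual: float

    @property
    def is_indel(self) -> bool:
        alleles = (self.ref_allele,) + tuple(self.alt_alleles)
        return any(len(a) != 1 or a not in _NUCLEOTIDES for a in alleles)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def call_rate(self) -> float:
        g = np.asarray(self.genotypes, dtype=float)
        return float(np.mean(~np.isnan(g))) if g.size else 0.0

    @property
    def maf(self) -> float:
        g = np.asarray(self.genotypes, dtype=float)
        g = g[~np.isnan(g)]
        if g.size == 0:
            return 0.0
        p = g.sum() / (2 * g.size)
        return float(min(p, 1 - p))


@dataclass
class QcReport:
    """Kept/removed bookkeeping per filter step; totals are conserved."""

    steps: list = field(default_factory=list)  # (step, kind, kept, removed)
    thresholds: dict = field(default_factory=dict)

    def record(self, step: str, kind: str, kept: int, removed: int) -> None:
        self.steps.append({"step": step, "kind": kind, "kept": kept, "removed": removed})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "kind", "kept", "removed"])

    def removed_total(self, kind: str) -> int:
        return sum(s["removed"] for s in self.steps if s["kind"] == kind)
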