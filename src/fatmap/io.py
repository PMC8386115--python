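"""Readers and writers for the pipeline's text formats.

Genotypes travel as PLINK-style text (.ped/.map), phenotypes and variant
annotations as delimited tables (tab or comma, auto-detected from the header
line), sequenced variants as a minimal VCF.  All writers emit tab-separated
text with a ``#`` header comment carrying the tool version and seed, and a
fixed column order, so that write->read round-trips are lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (
    FatmapError,
    GenotypeMatrix,
    MarkerMap,
    SeqVariant,
    validate_annotation,
    validate_phenotypes,
)

log = logging.getLogger(__name__)

_ALLELE_SYMBOLS = frozenset("ACGT")
_PED_MISSING = "0"


@dataclass(frozen=True)
class ParseCounts:
    accepted: int
    rejected: int


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path, count_ref: bool = False):
    """Read PLINK text files into a dosage matrix plus marker map.

    The .map file has four whitespace-delimited columns (chromosome,
    marker id, genetic position, bp position); allele columns may be
    appended as columns 5-6 (ref, alt) — without them the two alleles
    observed in the .ped are oriented so the *second* (minor-last) allele
    symbol seen is counted.  ``count_ref=True`` counts the reference
    allele instead.  "0 0" allele pairs are missing genotypes.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (4, 6):
                raise FatmapError(f"{map_path}: line {ln}: expected 4 or 6 columns, got {len(parts)}")
            map_rows.append(parts)
    n_markers = len(map_rows)

    animal_ids = []
    allele_a = []  # per-animal first allele call per marker
    allele_b = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise FatmapError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_markers} fields "
                    f"for {n_markers} markers, got {len(parts)}"
                )
            animal_ids.append(parts[1])
            calls = parts[6:]
            for sym in calls:
                if sym != _PED_MISSING and sym not in _ALLELE_SYMBOLS:
                    raise FatmapError(f"{ped_path}: line {ln}: unknown allele symbol {sym!r}")
            allele_a.append(calls[0::2])
            allele_b.append(calls[1::2])

    a = np.asarray(allele_a, dtype="U1") if allele_a else np.empty((0, n_markers), dtype="U1")
    b = np.asarray(allele_b, dtype="U1") if allele_b else np.empty((0, n_markers), dtype="U1")

    ref = np.empty(n_markers, dtype="U1")
    alt = np.empty(n_markers, dtype="U1")
    for j, row in enumerate(map_rows):
        if len(row) == 6:
            ref[j], alt[j] = row[4], row[5]
        else:
            seen = [s for s in dict.fromkeys(np.concatenate([a[:, j], b[:, j]]).tolist())
                    if s != _PED_MISSING]
            if len(seen) == 0:
                seen = ["A", "G"]
            if len(seen) == 1:
                seen.append(next(s for s in "ACGT" if s != seen[0]))
            if len(seen) > 2:
                raise FatmapError(f"marker {row[1]}: more than two alleles in .ped")
            ref[j], alt[j] = seen[0], seen[1]

    counted = ref if count_ref else alt
    n = a.shape[0]
    dosage = np.full((n, n_markers), np.nan)
    if n:
        miss = (a == _PED_MISSING) | (b == _PED_MISSING)
        dose = (a == counted[None, :]).astype(float) + (b == counted[None, :]).astype(float)
        dosage = np.where(miss, np.nan, dose)

    mmap = MarkerMap(pd.DataFrame({
        "marker_id": [r[1] for r in map_rows],
        "chromosome": [r[0] for r in map_rows],
        "position_bp": [int(r[3]) for r in map_rows],
        "ref_allele": ref,
        "alt_allele": alt,
    }))
    # MarkerMap sorts by (chrom, pos); reorder dosage columns to match
    order = {m: i for i, m in enumerate(r[1] for r in map_rows)}
    col_idx = [order[m] for m in mmap.table["marker_id"]]
    geno = GenotypeMatrix(np.asarray(animal_ids, dtype=object), dosage[:, col_idx])
    log.info("read %d animals x %d markers from %s", geno.n_animals, n_markers, ped_path)
    return geno, mmap


def write_plink_text(geno: GenotypeMatrix, mmap: MarkerMap, ped_path, map_path) -> None:
    """Write the dosage matrix back to PLINK text (alleles from the map)."""
    t = mmap.table
    with open(map_path, "w") as fh:
        for r in t.itertuples(index=False):
            fh.write(f"{r.chromosome}\t{r.marker_id}\t0\t{r.position_bp}\t{r.ref_allele}\t{r.alt_allele}\n")
    ref = t["ref_allele"].to_numpy()
    alt = t["alt_allele"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, aid in enumerate(geno.animal_ids):
            fields = [str(aid), str(aid), "0", "0", "0", "-9"]
            row = geno.dosage[i]
            for j, d in enumerate(row):
                if np.isnan(d):
                    fields += [_PED_MISSING, _PED_MISSING]
                else:
                    k = int(d)
                    fields += [alt[j]] * k + [ref[j]] * (2 - k)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def _sniff_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def read_table(path) -> pd.DataFrame:
    """Read a delimited table, skipping ``#`` comment lines; sep auto-detected."""
    return pd.read_csv(path, sep=_sniff_sep(path), comment="#")


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate the phenotype/covariate table."""
    return validate_phenotypes(read_table(path))


def read_annotation(path) -> pd.DataFrame:
    """Read and validate the VEP-style annotation table."""
    return validate_annotation(read_table(path))


def write_table(frame: pd.DataFrame, path, seed=None) -> None:
    """Write a result table as tab-separated text with a provenance comment."""
    with open(path, "w") as fh:
        fh.write(f"# fatmap {__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        fh.write("\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Minimal VCF for sequenced variants
# ---------------------------------------------------------------------------

def read_vcf_variants(path) -> list[SeqVariant]:
    """Read sequenced variants from a minimal VCF.

    Uses CHROM/POS/ID/REF/ALT/QUAL, DP from INFO and per-sample GT; records
    with unparseable sites are rejected (counted, never silently dropped).
    """
    variants: list[SeqVariant] = []
    rejected = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                rejected += 1
                continue
            chrom, pos, vid, ref, alt_field, qual = f[0], f[1], f[2], f[3], f[4], f[5]
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            alts = tuple(alt_field.split(","))
            genos = []
            for sample in f[9:]:
                gt = sample.split(":")[0]
                alleles = gt.replace("|", "/").split("/")
                if "." in alleles:
                    genos.append(np.nan)
                else:
                    genos.append(float(sum(a == "1" for a in alleles)))
            variants.append(SeqVariant(
                marker_id=vid if vid != "." else f"{chrom}:{pos}",
                chromosome=chrom,
                position_bp=int(pos),
                ref_allele=ref,
                alt_alleles=alts,
                genotypes=np.asarray(genos),
                depth=float(info.get("DP", "nan")),
                qual=float(qual) if qual != "." else float("nan"),
            ))
    if rejected:
        log.warning("rejected %d malformed VCF lines in %s", rejected, path)
    log.info("read %d variants from %s", len(variants), path)
    return variants
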