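"""Pairwise LD (composite genotype r-squared), greedy tag-SNP pruning and
triage of predicted-deleterious SNPs inside significant windows.

r-squared is the squared Pearson correlation between dosage vectors over
animals non-missing at both markers (composite LD; no phase inference).
Pruning is greedy: markers are visited by descending MAF (position breaks
ties); each visited unremoved marker becomes a tag and removes every other
marker correlated with it above the threshold, so the kept set has all
pairwise r-squared at or below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FatmapError, GenotypeMatrix, MarkerMap

log = logging.getLogger(__name__)


def pairwise_r2(geno, marker_subset=None) -> np.ndarray:
    """Symmetric r-squared matrix across the selected markers.

    Missing dosages are handled pairwise (complete cases per pair); a
    zero-variance marker yields NaN for all its pairs (diagonal included).
    """
    dose = geno.dosage if isinstance(geno, GenotypeMatrix) else np.asarray(geno, dtype=float)
    if marker_subset is not None:
        dose = dose[:, np.asarray(marker_subset)]
    k = dose.shape[1]
    r2 = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            both = ~np.isnan(dose[:, i]) & ~np.isnan(dose[:, j])
            if both.sum() < 2:
                continue
            x, y = dose[both, i], dose[both, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    return r2


@dataclass(frozen=True)
class LdPruneResult:
    kept: np.ndarray  # indices (or ids) of tag markers
    removed: pd.DataFrame  # columns: marker, tag, r2

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def tag_select(
    r2: np.ndarray,
    threshold: float = 0.7,
    maf: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    marker_ids=None,
) -> LdPruneResult:
    """Greedy one-tag-per-correlated-set selection at r2 > threshold.

    Visit order: MAF descending, then position ascending (map order when
    MAF/positions are not given).  Deterministic given that order.
    """
    k = r2.shape[0]
    if r2.shape != (k, k):
        raise FatmapError("r2 matrix must be square")
    ids = np.asarray(marker_ids, dtype=object) if marker_ids is not None else np.arange(k)
    maf_key = -np.asarray(maf, dtype=float) if maf is not None else np.zeros(k)
    pos_key = np.asarray(positions, dtype=float) if positions is not None else np.arange(k)
    order = np.lexsort((pos_key, maf_key))

    removed_mask = np.zeros(k, dtype=bool)
    kept: list[int] = []
    removed_rows = []
    for t in order:
        if removed_mask[t]:
            continue
        kept.append(int(t))
        for j in order:
            if j == t or removed_mask[j] or j in kept:
                continue
            if np.isfinite(r2[t, j]) and r2[t, j] > threshold:
                removed_mask[j] = True
                removed_rows.append({"marker": ids[j], "tag": ids[t], "r2": float(r2[t, j])})
    kept_arr = np.asarray([ids[i] for i in sorted(kept)], dtype=object)
    return LdPruneResult(
        kept=kept_arr,
        removed=pd.DataFrame(removed_rows, columns=["marker", "tag", "r2"]),
    )


def select_deleterious(
    annotation: pd.DataFrame,
    significant_windows: pd.DataFrame,
    mmap: MarkerMap,
    sift_cutoff: float = 0.05,
    window_size_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Predicted-deleterious SNPs (SIFT <= cutoff) inside significant windows.

    ``significant_windows`` needs ``chromosome`` and ``window_mb`` columns
    (rows already filtered to significant ones, or carrying a
    ``significant`` flag).  Annotation rows whose marker id is absent from
    the map are skipped with a warning.
    """
    win = significant_windows
    if "significant" in win.columns:
        win = win[win["significant"].astype(bool)]
    sig_keys = set(zip(win["chromosome"].astype(str), win["window_mb"].astype(int)))

    mtab = mmap.table.set_index("marker_id")
    rows = []
    for rec in annotation.itertuples(index=False):
        score = rec.sift_score
        if pd.isna(score) or score > sift_cutoff:
            continue
        if rec.marker_id not in mtab.index:
            log.warning("annotation marker %s not in map; skipped", rec.marker_id)
            continue
        chrom = str(mtab.loc[rec.marker_id, "chromosome"])
        pos = int(mtab.loc[rec.marker_id, "position_bp"])
        bin_mb = (pos - 1) // window_size_bp
        if (chrom, bin_mb) in sig_keys:
            rows.append({
                "marker_id": rec.marker_id,
                "chromosome": chrom,
                "position_bp": pos,
                "window_mb": bin_mb,
                "gene_symbol": rec.gene_symbol,
                "sift_score": float(score),
            })
    return pd.DataFrame(
        rows,
        columns=["marker_id", "chromosome", "position_bp", "window_mb", "gene_symbol", "sift_score"],
    )
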