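"""1-Mb genomic windows: assignment, per-draw variance decomposition,
posterior probability of association (PPA) and significance calls.

A window's share of the genetic variance in one MCMC draw is the variance
across animals of that window's genomic values divided by the variance of
the total genomic values, in percent.  Under an infinitesimal architecture
each of the ``W`` instantiated windows is expected to explain ``100/W`` %;
a window is called significant when its posterior mean share reaches
``fold`` times that expectation (the five-fold rule by default), and its
PPA is the fraction of retained draws in which its share exceeds the
infinitesimal expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import FatmapError, MarkerMap

log = logging.getLogger(__name__)

WINDOW_SIZE_BP = 1_000_000


def assign_windows(mmap: MarkerMap, size_bp: int = WINDOW_SIZE_BP) -> pd.DataFrame:
    """Assign each marker to a non-overlapping per-chromosome window.

    Bin index = floor((position - 1) / size) on 1-based positions, so
    positions 1..size share bin 0 and size+1 opens bin 1.  Only windows
    holding at least one marker are instantiated; returns a frame with
    ``marker_id``, ``chromosome``, ``window_mb`` (bin index) and a dense
    ``window_idx`` 0..W-1 over instantiated windows.
    """
    t = mmap.table
    bins = (t["position_bp"].to_numpy() - 1) // size_bp
    frame = pd.DataFrame({
        "marker_id": t["marker_id"].to_numpy(),
        "chromosome": t["chromosome"].to_numpy(),
        "position_bp": t["position_bp"].to_numpy(),
        "window_mb": bins.astype(int),
    })
    keys = list(zip(frame["chromosome"], frame["window_mb"]))
    uniq = list(dict.fromkeys(keys))  # map order = (chrom, pos) order
    lookup = {k: i for i, k in enumerate(uniq)}
    frame["window_idx"] = [lookup[k] for k in keys]
    return frame


def window_variance_draws(
    effect_draws: np.ndarray,
    centered_dosage: np.ndarray,
    window_idx: np.ndarray,
) -> np.ndarray:
    """Per-draw per-window percent shares of genetic variance.

    ``effect_draws`` is draws x markers (thinned chain), ``centered_dosage``
    animals x markers.  For each draw the genomic value of every animal is
    decomposed by window; shares are variances across animals, normalized to
    sum to 100.  A draw with zero total genetic variance gets uniform shares
    (with a warning).
    """
    effect_draws = np.atleast_2d(np.asarray(effect_draws, dtype=float))
    window_idx = np.asarray(window_idx)
    if effect_draws.shape[1] != centered_dosage.shape[1] or window_idx.size != effect_draws.shape[1]:
        raise FatmapError(
            f"dimension mismatch: {effect_draws.shape[1]} effects, "
            f"{centered_dosage.shape[1]} markers, {window_idx.size} window labels"
        )
    n_windows = int(window_idx.max()) + 1
    n_draws = effect_draws.shape[0]
    shares = np.empty((n_draws, n_windows))
    degenerate = 0
    cols_by_window = [np.flatnonzero(window_idx == w) for w in range(n_windows)]
    for d in range(n_draws):
        beta = effect_draws[d]
        var_w = np.empty(n_windows)
        for w, cols in enumerate(cols_by_window):
            gv = centered_dosage[:, cols] @ beta[cols]
            var_w[w] = gv.var()
        total = (centered_dosage @ beta).var()
        if total <= 0:
            shares[d] = 100.0 / n_windows
            degenerate += 1
        else:
            shares[d] = 100.0 * var_w / var_w.sum()
    if degenerate:
        log.warning("%d draws had zero genetic variance; uniform shares used", degenerate)
    return shares


def significance_threshold(n_windows: int, fold: float = 5.0) -> float:
    """Significance cutoff in percent: fold x the infinitesimal share 100/W."""
    return fold * 100.0 / n_windows


@dataclass(frozen=True)
class WindowResult:
    chromosome: str
    window_mb: int
    first_pos: int
    last_pos: int
    n_snps: int
    pct_genetic_variance: float
    ppa: float
    significant: bool


def summarize_windows(
    shares: np.ndarray,
    window_frame: pd.DataFrame,
    n_windows: int | None = None,
    fold: float = 5.0,
    ppa_mode: str = "share",
    effect_draws: np.ndarray | None = None,
) -> pd.DataFrame:
    """Posterior summary per window: mean percent share, PPA, significance.

    ``n_windows`` sets the infinitesimal expectation denominator (defaults
    to the number of instantiated windows in ``shares``).  PPA counts the
    draws in which the window's share exceeds the expectation
    (``ppa_mode="share"``, the default) or, with ``ppa_mode="inclusion"``
    and the thinned ``effect_draws`` supplied, the draws in which at least
    one marker of the window carries a nonzero effect.
    """
    shares = np.atleast_2d(np.asarray(shares, dtype=float))
    w_total = n_windows if n_windows is not None else shares.shape[1]
    expected = 100.0 / w_total
    threshold = significance_threshold(w_total, fold)
    mean_pct = shares.mean(axis=0)
    if ppa_mode == "share":
        ppa = (shares > expected).mean(axis=0)
    elif ppa_mode == "inclusion":
        if effect_draws is None:
            raise FatmapError("ppa_mode='inclusion' needs effect_draws")
        draws = np.atleast_2d(np.asarray(effect_draws, dtype=float))
        ppa = np.zeros(shares.shape[1])
        wcol = window_frame["window_idx"].to_numpy()
        for w in range(shares.shape[1]):
            cols = np.flatnonzero(wcol == w)
            ppa[w] = (np.abs(draws[:, cols]) > 0).any(axis=1).mean()
    else:
        raise FatmapError(f"unknown ppa_mode {ppa_mode!r}")

    meta = (
        window_frame.groupby("window_idx", sort=True)
        .agg(
            chromosome=("chromosome", "first"),
            window_mb=("window_mb", "first"),
            first_pos=("position_bp", "min"),
            last_pos=("position_bp", "max"),
            n_snps=("marker_id", "size"),
        )
        .reset_index()
    )
    out = meta.assign(
        pct_genetic_variance=mean_pct[meta["window_idx"].to_numpy()],
        ppa=ppa[meta["window_idx"].to_numpy()],
    )
    out["significant"] = out["pct_genetic_variance"] >= threshold
    return out.drop(columns="window_idx")


def unique_qtl(window_results: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Deduplicate significant windows across traits on (chromosome, window).

    Input rows carry at least ``chromosome`` and ``window_mb`` (a ``trait``
    column is typical); returns the distinct windows and their count.
    """
    if len(window_results) == 0:
        return window_results.copy(), 0
    dedup = window_results.drop_duplicates(subset=["chromosome", "window_mb"])
    return dedup.reset_index(drop=True), len(dedup)


def cumulative_variance(window_results: pd.DataFrame, trait: str | None = None) -> float:
    """Sum of percent genetic variance over a trait's significant windows."""
    t = window_results
    if trait is not None:
        t = t[t["trait"] == trait]
    if "significant" in t.columns:
        t = t[t["significant"].astype(bool)]
    return float(t["pct_genetic_variance"].sum())
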