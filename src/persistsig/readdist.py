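"""Flank-normalized read-distribution profiles around genomic anchors.

Reads are counted in 100-bp bins across a +-1-kb window around each site's
midpoint (21 bins, the middle bin straddling position 0), averaged across
replicates, and normalized by the average count of the two outermost
(flank) bins so openness is expressed relative to local background.
Between-condition comparisons use a Welch t-test on the per-site
normalized center values; per-anchor enrichment scores (e.g., at TSSs)
are compared with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ranksums, ttest_ind

from .io import RegionSet

__all__ = ["BinnedProfile", "binned_profile", "flank_normalize",
           "center_compare", "tss_enrichment_compare"]


@dataclass
class BinnedProfile:
    offsets: np.ndarray        # bin-center offsets, -window .. +window
    site_counts: np.ndarray    # n_sites x n_bins, mean across replicates
    normalized: np.ndarray | None = None  # same shape, after flank division
    norm_mode: str | None = None          # "pooled" | "per_site"

    @property
    def n_bins(self) -> int:
        return len(self.offsets)

    @property
    def center_index(self) -> int:
        return int(np.argmin(np.abs(self.offsets)))

    @property
    def mean_profile(self) -> np.ndarray:
        """Cross-site mean per bin (normalized if available, else raw)."""
        values = self.normalized if self.normalized is not None else self.site_counts
        return values.mean(axis=0)

    @classmethod
    def from_counts(cls, counts: np.ndarray, window: int = 1000,
                    bin_size: int = 100) -> "BinnedProfile":
        counts = np.asarray(counts, dtype=float)
        offsets = np.arange(-window, window + bin_size, bin_size)
        if counts.shape[1] != len(offsets):
            raise ValueError(
                f"expected {len(offsets)} bins, got {counts.shape[1]}")
        return cls(offsets, counts)


def binned_profile(replicates: list[pd.DataFrame], sites: RegionSet,
                   window: int = 1000, bin_size: int = 100,
                   contig_lengths: dict[str, int] | None = None
                   ) -> BinnedProfile:
    """Count reads per 100-bp bin around site midpoints.

    Each replicate is a BED-like DataFrame with columns ``chrom``,
    ``start``, ``end`` (and optionally ``strand``); the counted position is
    the read's 5' end.  Bin b covers ``[mid + offset_b - bin/2,
    mid + offset_b + bin/2)``; counts are averaged across replicates.
    Sites closer than ``window + bin/2`` to a contig edge are dropped with
    a warning when contig lengths are given.
    """
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin_size")
    offsets = np.arange(-window, window + bin_size, bin_size)
    half = bin_size // 2
    reach = window + half

    mids = sites.midpoints
    keep = np.ones(len(sites), dtype=bool)
    for i, (chrom, mid) in enumerate(zip(sites.chroms, mids)):
        limit = contig_lengths.get(chrom) if contig_lengths else None
        if mid - reach < 0 or (limit is not None and mid + reach > limit):
            keep[i] = False
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} site(s) too close to a contig "
                      "edge, dropped", stacklevel=2)
    idx_kept = np.nonzero(keep)[0]
    n_sites = len(idx_kept)
    if n_sites == 0:
        raise ValueError("no usable sites")

    acc = np.zeros((n_sites, len(offsets)))
    for rep in replicates:
        if "strand" in rep.columns:
            pos = np.where(rep["strand"].to_numpy() == "-",
                           rep["end"].to_numpy() - 1,
                           rep["start"].to_numpy())
        else:
            pos = rep["start"].to_numpy()
        chroms = rep["chrom"].to_numpy()
        by_chrom: dict[str, np.ndarray] = {}
        for c in np.unique(chroms):
            by_chrom[c] = np.sort(pos[chroms == c])
        for row, si in enumerate(idx_kept):
            cpos = by_chrom.get(sites.chroms[si])
            if cpos is None:
                continue
            rel = cpos - mids[si]
            if sites.strands[si] == "-":
                rel = -rel
            # bin via half-open intervals [offset - half, offset + half)
            inside = (rel >= -reach) & (rel < reach)
            b = ((rel[inside] + reach) // bin_size).astype(int)
            np.add.at(acc[row], b, 1)
    acc /= max(len(replicates), 1)
    return BinnedProfile(offsets, acc)


def flank_normalize(p: BinnedProfile, per_site: bool = False) -> BinnedProfile:
    """Divide every bin by the mean of the two outermost (flank) bins.

    Default ("pooled") mode uses the flank mean pooled across sites, as in
    an average-profile plot; ``per_site`` divides each site by its own
    flank mean.  Idempotent: normalizing a normalized profile changes
    nothing (flanks already average 1).
    """
    base = p.normalized if p.normalized is not None else p.site_counts
    flanks = base[:, [0, -1]]
    if per_site:
        denom = flanks.mean(axis=1, keepdims=True)
        if np.any(denom <= 0):
            raise ValueError("site with zero flank mean; use pooled mode")
        normalized = base / denom
        mode = "per_site"
    else:
        denom = flanks.mean()
        if denom <= 0:
            raise ValueError("zero flank mean after pooling across sites")
        normalized = base / denom
        mode = "pooled"
    return BinnedProfile(p.offsets.copy(), p.site_counts, normalized, mode)


def center_compare(p1: BinnedProfile, p2: BinnedProfile
                   ) -> tuple[float, float]:
    """Welch t-test on per-site flank-normalized center-bin values."""
    a = _center_values(p1)
    b = _center_values(p2)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 sites per condition")
    res = ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _center_values(p: BinnedProfile) -> np.ndarray:
    if p.normalized is None:
        p = flank_normalize(p)
    return p.normalized[:, p.center_index]


def tss_enrichment_compare(scores1: np.ndarray, scores2: np.ndarray
                           ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on per-anchor enrichment scores."""
    a = np.asarray(scores1, dtype=float)
    b = np.asarray(scores2, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 values per side")
    stat, p = ranksums(a, b)
    return float(stat), float(p)
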