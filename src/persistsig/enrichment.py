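"""Hypergeometric attribute enrichment, differential-feature filters, and
TF-target attribution of differentially expressed genes.

``hypergeom_enrichment`` tests whether each boolean attribute (e.g., a TF
motif hit) is over-represented in a foreground region set relative to a
background universe, optionally resampling the background to match the
foreground's GC-content decile distribution first; p-values are
one-sided upper-tail hypergeometric, adjusted across attributes with
Benjamini-Hochberg.

``apply_deg_filter`` applies the standard three-part differential filter:
adjusted p below a cutoff, detection fraction at least a minimum, and
absolute log-fold-change at least a minimum.

``tf_target_attribution`` decomposes, per cluster, the fraction of DEGs
explained by enriched transcription factors; a DEG targeted by several
enriched TFs contributes fractionally to each.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_enrichment", "apply_deg_filter",
           "tf_target_attribution", "DEG_DEFAULTS", "DAR_DEFAULTS"]

# (p_adj_max, pct_min, lfc_min) conventions for expression and accessibility
DEG_DEFAULTS = (0.01, 0.10, 0.25)
DAR_DEFAULTS = (0.05, 0.10, 0.25)

GC_BINS = 10


def _gc_matched_background(background: pd.DataFrame,
                           foreground: pd.DataFrame,
                           seed: int | None) -> pd.DataFrame:
    """Resample the background (with replacement) to the foreground's GC
    decile distribution."""
    rng = np.random.default_rng(seed)
    edges = np.quantile(background["gc"].to_numpy(), np.linspace(0, 1, GC_BINS + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bg_bin = np.digitize(background["gc"].to_numpy(), edges[1:-1])
    fg_bin = np.digitize(foreground["gc"].to_numpy(), edges[1:-1])
    fg_frac = np.bincount(fg_bin, minlength=GC_BINS) / len(foreground)
    n_target = len(background)
    pieces = []
    for b in range(GC_BINS):
        n_b = int(round(fg_frac[b] * n_target))
        if n_b == 0:
            continue
        pool = np.nonzero(bg_bin == b)[0]
        if pool.size == 0:
            raise ValueError(f"background has no regions in GC decile {b} "
                             "occupied by the foreground")
        pieces.append(background.iloc[rng.choice(pool, size=n_b, replace=True)])
    return pd.concat(pieces)


def hypergeom_enrichment(foreground_ids: list[str], regions: pd.DataFrame,
                         attributes: list[str] | None = None,
                         match_covariates: bool = False,
                         alpha: float = 0.05,
                         seed: int | None = 0) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of boolean attributes.

    ``regions`` indexes the background universe by region id, with boolean
    attribute columns and, when ``match_covariates``, a ``gc`` column in
    [0, 1].  The foreground must be a subset of the universe.  Returns a
    table with counts, raw p, BH-adjusted p, and an ``enriched`` flag at
    adjusted p < ``alpha``.
    """
    fg_ids = [str(i) for i in foreground_ids]
    missing = [i for i in fg_ids if i not in regions.index]
    if missing:
        raise ValueError(f"foreground not a subset of background: {missing[:5]}")
    if len(fg_ids) > len(regions):
        raise ValueError("foreground larger than background")
    if attributes is None:
        attributes = [c for c in regions.columns
                      if regions[c].dtype == bool and c != "gc"]
    if not attributes:
        raise ValueError("no boolean attribute columns found")
    foreground = regions.loc[fg_ids]
    background = regions
    if match_covariates:
        if "gc" not in regions.columns:
            raise ValueError("match_covariates requires a 'gc' column")
        if not regions["gc"].between(0, 1).all():
            raise ValueError("gc must lie in [0, 1]")
        background = _gc_matched_background(regions, foreground, seed)

    rows = []
    n = len(fg_ids)
    N = len(background)
    for attr in attributes:
        K = int(background[attr].sum())
        k = int(foreground[attr].sum())
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"attribute": attr, "n_foreground": n, "k_foreground": k,
                     "n_background": N, "k_background": K, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("attribute")
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["enriched"] = out["p_adj"] < alpha
    return out


def apply_deg_filter(table: pd.DataFrame, p_adj_max: float = 0.01,
                     pct_min: float = 0.10, lfc_min: float = 0.25,
                     directional: bool = False) -> pd.DataFrame:
    """Rows passing adjusted-p, detection-fraction, and log-FC thresholds.

    With ``directional`` the log-FC condition is ``lfc >= lfc_min`` (up
    only); otherwise ``|lfc| >= lfc_min``.
    """
    required = {"p_adj", "pct", "lfc"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    lfc = table["lfc"] if directional else table["lfc"].abs()
    keep = ((table["p_adj"] < p_adj_max)
            & (table["pct"] >= pct_min)
            & (lfc >= lfc_min))
    return table.loc[keep]


def tf_target_attribution(degs_by_cluster: dict[str, list[str]],
                          enriched_tfs: list[str],
                          targets: dict[str, list[str]]) -> pd.DataFrame:
    """Fraction of each cluster's DEGs explained by enriched TF targets.

    A DEG targeted by t enriched TFs contributes 1/t to each of them, so
    the per-TF columns sum exactly to the ``total`` covered fraction.
    Returns a clusters x (TFs + total) DataFrame.
    """
    tf_targets = {}
    for tf in enriched_tfs:
        genes = set(targets.get(tf, ()))
        tf_targets[tf] = genes
    rows = {}
    for cluster, degs in degs_by_cluster.items():
        degs = list(dict.fromkeys(degs))
        n = len(degs)
        contrib = {tf: 0.0 for tf in enriched_tfs}
        covered = 0
        for gene in degs:
            hits = [tf for tf in enriched_tfs if gene in tf_targets[tf]]
            if hits:
                covered += 1
                for tf in hits:
                    contrib[tf] += 1.0 / len(hits)
        row = {tf: (contrib[tf] / n if n else 0.0) for tf in enriched_tfs}
        row["total"] = covered / n if n else 0.0
        rows[cluster] = row
    return pd.DataFrame(rows).T
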