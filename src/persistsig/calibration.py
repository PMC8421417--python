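"""Housekeeping-null calibration of spatial high-score thresholds.

A signature's 90th-percentile threshold on spot scores is only meaningful
if random gene sets of the same length, drawn from stably expressed
housekeeping genes, rarely exceed it.  ``calibrate_threshold`` scores the
query signature, takes its 90th percentile as the candidate threshold,
scores ``n_null_sets`` length-matched housekeeping sets, and reports the
fraction of (spot, null-set) scores at or above the candidate threshold.
The calibration passes when this achieved null exceedance is at most the
allowed false-positive rate (5% by default).

``spot_enrichment_test`` compares the proportion of high-scoring spots
between two tissue clusters with a 2x2 Pearson chi-square test (no
continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io import ExpressionMatrix, SignatureCollection, log_normalize
from .scoring import UnitScoreTable, module_scores_many
from .simulate import sample_housekeeping_sets

__all__ = ["CalibrationReport", "calibrate_threshold", "spot_enrichment_test"]


@dataclass
class CalibrationReport:
    signature: str
    n_null_sets: int
    threshold: float
    percentile: float
    fpr_allowed: float
    null_exceedance: float
    passed: bool
    null_scores: np.ndarray | None = None
    query_scores: pd.Series | None = None


def calibrate_threshold(m: ExpressionMatrix, query_sig: SignatureCollection,
                        query_name: str, hk_pool: list[str],
                        n_null_sets: int = 100, fpr: float = 0.05,
                        percentile: float = 90.0, seed: int = 0,
                        min_counts: int | None = None,
                        n_ctrl: int = 100) -> CalibrationReport:
    """Calibrate a spot high-score threshold against a housekeeping null.

    ``m`` may be counts (log-normalized internally) or lognorm.  Spots with
    fewer than ``min_counts`` total counts are dropped first when the
    filter is configured and the input is counts.

    Spots are scored with control-subtracted module scores (``n_ctrl``
    expression-matched controls per signature gene) so that query and
    housekeeping-null scores share a common zero baseline regardless of
    the sets' absolute expression levels; ``n_ctrl=0`` falls back to plain
    signature-mean scores.
    """
    if n_null_sets < 10:
        raise ValueError("n_null_sets < 10: null too small to estimate a "
                         "5% exceedance")
    size = len(query_sig[query_name])
    if len(hk_pool) < size:
        raise ValueError(
            f"housekeeping pool ({len(hk_pool)}) smaller than query "
            f"signature ({size})")
    if m.value_kind == "counts":
        if min_counts is not None:
            keep = m.values.sum(axis=0) >= min_counts
            if not keep.any():
                raise ValueError("no spot passes the minimum-count filter")
            m = ExpressionMatrix(list(m.gene_ids),
                                 [u for u, k in zip(m.unit_ids, keep) if k],
                                 m.values[:, keep], "counts")
        m = log_normalize(m)

    query_scores = module_scores_many(
        m, query_sig, [query_name], n_ctrl=n_ctrl, seed=seed)[query_name]
    threshold = float(np.percentile(query_scores.to_numpy(), percentile))

    hk_sets = sample_housekeeping_sets(hk_pool, size, n_null_sets, seed=seed)
    null_scores = module_scores_many(
        m, hk_sets, n_ctrl=n_ctrl, seed=seed).to_numpy()
    exceed = float(np.mean(null_scores >= threshold))
    return CalibrationReport(
        signature=query_name, n_null_sets=n_null_sets, threshold=threshold,
        percentile=percentile, fpr_allowed=fpr, null_exceedance=exceed,
        passed=exceed <= fpr, null_scores=null_scores.ravel(),
        query_scores=query_scores)


def spot_enrichment_test(flags: UnitScoreTable,
                         spot_cluster_labels: dict[str, int],
                         cluster_a: int, cluster_b: int
                         ) -> tuple[float, int, float]:
    """2x2 chi-square of high/low proportions between two spot clusters.

    Returns ``(statistic, df, p)``; df is always 1.  Degenerate tables
    (a zero margin) are an error rather than a silent zero.
    """
    tbl = flags.table
    labels = tbl["unit_id"].map(spot_cluster_labels)
    if labels.isna().any():
        raise ValueError("spots missing cluster labels")
    counts = np.zeros((2, 2), dtype=int)
    for col, cluster in enumerate((cluster_a, cluster_b)):
        in_cluster = labels == cluster
        counts[0, col] = int((tbl["is_high"] & in_cluster).sum())
        counts[1, col] = int((~tbl["is_high"] & in_cluster).sum())
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table (zero margin): {counts.tolist()}")
    stat, p, df, _ = chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)
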