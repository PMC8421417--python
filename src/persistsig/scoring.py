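"""Per-cell/per-spot signature scores and percentile high-score calls.

The module score of a cell is the mean log-normalized expression of the
signature genes minus the mean expression of expression-matched control
genes: genes are binned by their pooled average expression and each
signature gene draws its controls from its own bin, so a signature that is
merely composed of highly expressed genes scores near zero.  Setting
``n_ctrl=0`` gives the plain average-expression score.

High-score calls use a percentile threshold on the score vector (90th by
default) with the "at or above" convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SignatureCollection

__all__ = [
    "UnitScoreTable",
    "module_score",
    "module_scores_many",
    "high_score_flags",
    "composition_of_high",
]

DEFAULT_BINS = 24
DEFAULT_CTRL = 100


@dataclass
class UnitScoreTable:
    """One row per (unit, signature): score, high flag, and the threshold."""

    table: pd.DataFrame  # columns: unit_id, signature, score, is_high
    percentile: float
    thresholds: dict[str, float]  # per signature

    @property
    def frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["percentile_threshold"] = out["signature"].map(self.thresholds)
        return out


def _expression_bins(m: ExpressionMatrix, n_bins: int) -> np.ndarray:
    """Bin index per gene by pooled mean expression (quantile bins)."""
    pooled = m.values.mean(axis=1)
    ranks = pd.Series(pooled).rank(method="first")
    return pd.qcut(ranks, n_bins, labels=False, duplicates="drop").to_numpy()


def module_score(m: ExpressionMatrix, sig: SignatureCollection, name: str,
                 n_bins: int = DEFAULT_BINS, n_ctrl: int = DEFAULT_CTRL,
                 seed: int = 0) -> pd.Series:
    """Control-subtracted average signature expression per unit."""
    scores = module_scores_many(m, sig, [name], n_bins=n_bins,
                                n_ctrl=n_ctrl, seed=seed)
    return scores[name]


def module_scores_many(m: ExpressionMatrix, sig: SignatureCollection,
                       names: list[str] | None = None,
                       n_bins: int = DEFAULT_BINS, n_ctrl: int = DEFAULT_CTRL,
                       seed: int = 0) -> pd.DataFrame:
    """Module scores for several signatures sharing one bin structure.

    Returns a units x signatures DataFrame.  Controls are drawn per
    signature gene from its expression bin: without replacement when the
    bin holds at least ``n_ctrl`` genes, with replacement otherwise.
    """
    if m.value_kind != "lognorm":
        raise ValueError("module scores expect log-normalized expression")
    if names is None:
        names = list(sig.names)
    if n_ctrl > 0 and m.n_genes < n_bins:
        raise ValueError(f"need at least {n_bins} genes for {n_bins} bins")
    rng = np.random.default_rng(seed)
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    bins = _expression_bins(m, n_bins) if n_ctrl > 0 else None
    if bins is not None:
        bin_members: dict[int, np.ndarray] = {
            b: np.nonzero(bins == b)[0] for b in np.unique(bins)}

    out = {}
    for name in names:
        members = sig.intersect(m.gene_ids, name)
        if not members:
            missing = [g for g in sig[name] if g not in gene_index]
            raise ValueError(
                f"signature {name!r} shares no genes with the matrix; "
                f"missing: {missing[:10]}")
        sig_idx = np.array([gene_index[g] for g in members])
        sig_mean = m.values[sig_idx, :].mean(axis=0)
        if n_ctrl == 0:
            out[name] = sig_mean
            continue
        ctrl_rows = []
        for gi in sig_idx:
            pool = bin_members[bins[gi]]
            replace = len(pool) < n_ctrl
            ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=replace))
        ctrl_idx = np.concatenate(ctrl_rows)
        ctrl_mean = m.values[ctrl_idx, :].mean(axis=0)
        out[name] = sig_mean - ctrl_mean
    return pd.DataFrame(out, index=m.unit_ids)


def high_score_flags(scores: pd.Series | np.ndarray, percentile: float = 90.0,
                     signature: str = "signature",
                     unit_ids: list[str] | None = None) -> UnitScoreTable:
    """Flag units scoring at or above the given percentile of the scores.

    The threshold is the linear-interpolation (type-7) quantile; ``>=``
    counts as high.
    """
    if isinstance(scores, pd.Series):
        unit_ids = [str(u) for u in scores.index]
        values = scores.to_numpy(dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
        if unit_ids is None:
            unit_ids = [f"u{i}" for i in range(len(values))]
    if len(values) < 10:
        raise ValueError("need at least 10 units for a percentile call")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite scores")
    threshold = float(np.percentile(values, percentile))
    if np.all(values == values[0]):
        warnings.warn("all scores identical: every unit flagged high",
                      stacklevel=2)
    table = pd.DataFrame({
        "unit_id": unit_ids,
        "signature": signature,
        "score": values,
        "is_high": values >= threshold,
    })
    return UnitScoreTable(table, percentile, {signature: threshold})


def composition_of_high(flags: UnitScoreTable,
                        unit_annotations: dict[str, str] | pd.Series
                        ) -> pd.Series:
    """Percentage of flagged units in each annotation category (sums to 100)."""
    if isinstance(unit_annotations, pd.Series):
        unit_annotations = {str(k): v for k, v in unit_annotations.items()}
    tbl = flags.table
    missing = [u for u in tbl["unit_id"] if u not in unit_annotations]
    if missing:
        raise ValueError(f"units missing annotation: {missing[:10]}")
    high = tbl.loc[tbl["is_high"], "unit_id"]
    if len(high) == 0:
        raise ValueError("no units flagged high")
    cats = high.map(unit_annotations)
    return cats.value_counts(normalize=True).sort_index() * 100.0
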