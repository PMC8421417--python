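"""Cluster taxonomy across treatment conditions.

Cell clusters observed across a treatment time course fall into three
categories: *initial* clusters dominated by the untreated / short-treated
(parental-like) samples, *induced* clusters dominated by the resistant
samples, and *persistent* clusters present at similar proportions in all
samples.  Dominance is measured on within-sample proportions renormalized
across samples (so unequal cells-per-sample do not bias the call);
similarity is measured by the coefficient of variation of those
proportions.  Calls that are neither dominated nor clearly uniform are
labeled persistent with a borderline flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClusterCompositionTable", "TaxonomyCall", "composition",
           "classify_clusters"]


@dataclass
class ClusterCompositionTable:
    counts: pd.DataFrame       # clusters x samples, cell counts
    proportions: pd.DataFrame  # within-sample proportions (columns sum to 1)


@dataclass
class TaxonomyCall:
    cluster: str
    label: str  # initial | induced | persistent
    parental_share: float
    resistant_share: float
    cv: float
    borderline: bool = False


def composition(cell_annotations: pd.DataFrame) -> ClusterCompositionTable:
    """Cluster x sample counts and within-sample proportions.

    ``cell_annotations`` needs columns ``sample`` and ``cluster`` (one row
    per cell).
    """
    required = {"sample", "cluster"}
    if not required.issubset(cell_annotations.columns):
        raise ValueError(f"cell table must have columns {sorted(required)}")
    counts = pd.crosstab(cell_annotations["cluster"].astype(str),
                         cell_annotations["sample"].astype(str))
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"empty sample(s): {empty}")
    return ClusterCompositionTable(counts, counts / totals)


def classify_clusters(comp: ClusterCompositionTable,
                      parental_samples: list[str],
                      resistant_samples: list[str],
                      dominance: float = 0.7,
                      similarity_cv: float = 0.5) -> list[TaxonomyCall]:
    """Label each cluster initial / induced / persistent.

    For each cluster, its within-sample proportions are renormalized across
    samples to shares summing to 1; a cluster is *initial* when the
    parental-like share reaches ``dominance``, *induced* when the resistant
    share does, otherwise *persistent* (borderline when the per-sample
    proportions vary more than ``similarity_cv``).
    """
    parental = [str(s) for s in parental_samples]
    resistant = [str(s) for s in resistant_samples]
    if not parental or not resistant:
        raise ValueError("both sample groups must be non-empty")
    props = comp.proportions
    missing = [s for s in parental + resistant if s not in props.columns]
    if missing:
        raise ValueError(f"unknown sample(s): {missing}")
    calls = []
    for cluster, row in props.iterrows():
        total = row.sum()
        if total == 0:
            raise ValueError(f"cluster {cluster!r} absent from all samples")
        shares = row / total
        p_share = float(shares[parental].sum())
        r_share = float(shares[resistant].sum())
        cv = float(row.std(ddof=0) / row.mean()) if row.mean() > 0 else np.inf
        if p_share >= dominance:
            label, borderline = "initial", False
        elif r_share >= dominance:
            label, borderline = "induced", False
        else:
            label = "persistent"
            borderline = cv > similarity_cv
        calls.append(TaxonomyCall(str(cluster), label, p_share, r_share,
                                  cv, borderline))
    return calls
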