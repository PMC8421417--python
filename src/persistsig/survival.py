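"""Signature-score-based survival stratification.

Samples are split into two groups either by the median of one signature's
enrichment scores (strictly above the median = high) or by cutting a
complete-linkage hierarchical clustering of their full score vectors at
two branches.  Groups are then compared with Kaplan-Meier curves and the
two-group log-rank test.

The log-rank statistic is computed directly (observed vs expected events
over the pooled event times with the hypergeometric variance); the
Kaplan-Meier estimator is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2

from .gsva import GsvaScoreMatrix
from .io import ClinicalTable

__all__ = ["SurvivalFit", "median_split", "hclust_two_branch",
           "km_estimate", "logrank"]


@dataclass
class SurvivalFit:
    """Per-group KM step functions plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # per group: time, at_risk, events, survival
    statistic: float | None = None
    df: int | None = None
    p: float | None = None
    groups: dict[str, str] = field(default_factory=dict)


def median_split(scores: pd.Series | np.ndarray,
                 unit_ids: list[str] | None = None) -> dict[str, str]:
    """Two groups by the score median: high iff score > median.

    Samples exactly at the median go to the low group, so an odd number of
    distinct scores gives the smaller half to high.
    """
    if isinstance(scores, pd.Series):
        unit_ids = [str(u) for u in scores.index]
        values = scores.to_numpy(dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
        if unit_ids is None:
            unit_ids = [f"u{i}" for i in range(len(values))]
    if len(values) < 4:
        raise ValueError("need at least 4 samples")
    if np.all(values == values[0]):
        raise ValueError("all scores identical: degenerate split")
    med = float(np.median(values))
    return {u: ("high" if v > med else "low") for u, v in zip(unit_ids, values)}


def hclust_two_branch(scores: GsvaScoreMatrix,
                      method: str = "complete") -> dict[str, str]:
    """Two-branch split from hierarchical clustering of score vectors.

    Samples are clustered on Euclidean distances between their per-
    signature score vectors; the tree is cut at k=2.  Branch names follow
    sample-id order of first occurrence for determinism.
    """
    if len(scores.signature_names) < 2:
        raise ValueError("need at least 2 signatures")
    if len(scores.unit_ids) < 4:
        raise ValueError("need at least 4 samples")
    X = scores.values.T  # samples x signatures
    order = np.argsort(np.asarray(scores.unit_ids, dtype=object), kind="stable")
    Z = linkage(X[order], method=method, metric="euclidean")
    raw = fcluster(Z, t=2, criterion="maxclust")
    labels = np.empty(len(raw), dtype=int)
    labels[order] = raw
    # rename branches by first occurrence in unit-id order
    first = labels[order[0]]
    name = {first: "branch1", 3 - first: "branch2"}
    return {u: name[l] for u, l in zip(scores.unit_ids, labels)}


def km_estimate(tbl: ClinicalTable, groups: dict[str, str]) -> SurvivalFit:
    """Product-limit survival curve per group (right-censored)."""
    frame = tbl.frame
    missing = [u for u in tbl.unit_ids if u not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing[:5]}")
    frame["group"] = frame["unit_id"].map(groups)
    curves = {}
    for g, sub in frame.groupby("group"):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has no samples")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        et = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        curves[str(g)] = pd.DataFrame({
            "time": et.index.to_numpy(dtype=float),
            "at_risk": et["at_risk"].to_numpy(dtype=int),
            "events": et["observed"].to_numpy(dtype=int),
            "survival": surv.reindex(et.index).to_numpy(dtype=float),
        })
    return SurvivalFit(curves, groups=dict(groups))


def logrank(tbl: ClinicalTable, groups: dict[str, str]
            ) -> tuple[float, int, float]:
    """Two-group log-rank test: ``(statistic, df, two-sided p)``.

    At each pooled event time with d events among n at risk (n1 in group
    1), group 1 expects ``d * n1 / n`` events with hypergeometric variance
    ``d (n1/n) (n2/n) (n-d)/(n-1)``; the statistic is
    ``(O1 - E1)^2 / V`` on 1 df.
    """
    frame = tbl.frame
    frame["group"] = frame["unit_id"].map(groups)
    if frame["group"].isna().any():
        raise ValueError("samples without group label")
    names = sorted(frame["group"].unique())
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {names}")
    if frame["event"].sum() == 0:
        raise ValueError("no events observed")
    g1 = frame["group"] == names[0]
    time = frame["time"].to_numpy()
    event = frame["event"].to_numpy().astype(bool)
    event_times = np.unique(time[event])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int((event & (time == t)).sum())
        d1 = int((event & (time == t) & g1).sum())
        if n <= 1:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
        o_minus_e += d1 - e1
        var += v
    if var == 0:
        return 0.0, 1, 1.0
    stat = o_minus_e ** 2 / var
    return float(stat), 1, float(chi2.sf(stat, df=1))
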