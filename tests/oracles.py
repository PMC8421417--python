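"""Independent brute-force oracles, written as literal transcriptions of
the method definitions with plain Python loops.

These deliberately share no code with the package: every step (quartile
scaling, kernel CDFs, ranking, the random walk, the product-limit
estimator, the log-rank event table, hypergeometric draw enumeration,
the BH step-up) is spelled out naively so they can serve as ground truth
for the vectorized implementations.
"""

from __future__ import annotations

import math
from itertools import combinations

from scipy.stats import chi2, norm, poisson


def percentile_type7(sorted_vals: list[float], q: float) -> float:
    """Linear-interpolation quantile on an already-sorted list."""
    if not sorted_vals:
        raise ValueError("empty")
    h = (len(sorted_vals) - 1) * q / 100.0
    lo = int(math.floor(h))
    hi = min(lo + 1, len(sorted_vals) - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def gsva_oracle(values, gene_ids, unit_ids, member_map, value_kind,
                tau=1.0, cohort_mode=False):
    """End-to-end per-sample enrichment scores, all loops.

    ``values`` is a list of per-gene rows; returns {set_name: [score per
    sample]}.
    """
    p = len(gene_ids)
    n = len(unit_ids)
    vals = [[float(v) for v in row] for row in values]
    genes = list(gene_ids)

    if value_kind == "counts":
        # 75th percentile over nonzero genes, scaled to the geometric mean
        q75 = []
        for j in range(n):
            nz = sorted(vals[i][j] for i in range(p) if vals[i][j] > 0)
            q75.append(percentile_type7(nz, 75))
        gmean = math.exp(sum(math.log(x) for x in q75) / n)
        for i in range(p):
            for j in range(n):
                vals[i][j] *= gmean / q75[j]
        if cohort_mode:
            keep = [i for i in range(p)
                    if all(vals[i][j] > 0 for j in range(n))]
            vals = [vals[i] for i in keep]
            genes = [genes[i] for i in keep]
            p = len(genes)
        # Poisson kernel CDF with continuity offset 0.5
        F = [[sum(poisson.cdf(vals[i][j], vals[i][k] + 0.5)
                  for k in range(n)) / n
              for j in range(n)] for i in range(p)]
    else:
        F = []
        for i in range(p):
            row = vals[i]
            mean = sum(row) / n
            if n > 1:
                sd = math.sqrt(sum((v - mean) ** 2 for v in row) / (n - 1))
            else:
                sd = 0.0
            h = max(sd / 4.0, 1e-8 * (1.0 + abs(mean)))
            F.append([sum(norm.cdf((row[j] - row[k]) / h)
                          for k in range(n)) / n for j in range(n)])

    # per-sample ascending ranks, ties in gene-id order, centered at zero
    r = [[0.0] * n for _ in range(p)]
    for j in range(n):
        order = sorted(range(p), key=lambda i: (F[i][j], genes[i]))
        for rank0, i in enumerate(order):
            r[i][j] = (rank0 + 1) - (p + 1) / 2.0

    out = {}
    for name, members in member_map.items():
        members = set(members) & set(genes)
        m = len(members)
        scores = []
        for j in range(n):
            # genes from most to least expressed; gene-id ties
            order = sorted(range(p), key=lambda i: (-r[i][j], genes[i]))
            denom = sum(abs(r[i][j]) ** tau for i in range(p)
                        if genes[i] in members)
            s1 = s2 = 0.0
            best_pos, best_neg = 0.0, 0.0
            for i in order:
                if genes[i] in members:
                    if denom > 0:
                        s1 += abs(r[i][j]) ** tau / denom
                    else:
                        s1 += 1.0 / m
                else:
                    s2 += 1.0 / (p - m)
                d = s1 - s2
                best_pos = max(best_pos, d)
                best_neg = min(best_neg, d)
            scores.append(abs(best_pos) - abs(best_neg))
        out[name] = scores
    return out


def km_oracle(times, events):
    """Hand product-limit estimator: [(time, survival)] at event times."""
    pairs = sorted(zip(times, events))
    event_times = sorted({t for t, e in pairs if e == 1})
    s = 1.0
    curve = []
    for t in event_times:
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, e in pairs if ti == t and e == 1)
        s *= 1.0 - d / at_risk
        curve.append((t, s))
    return curve


def logrank_oracle(times, events, group1_mask):
    """Hand two-group log-rank: (statistic, p)."""
    n_all = len(times)
    event_times = sorted({times[i] for i in range(n_all) if events[i] == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        risk = [i for i in range(n_all) if times[i] >= t]
        n = len(risk)
        if n <= 1:
            continue
        n1 = sum(1 for i in risk if group1_mask[i])
        d = sum(1 for i in risk if times[i] == t and events[i] == 1)
        d1 = sum(1 for i in risk
                 if times[i] == t and events[i] == 1 and group1_mask[i])
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    stat = o_minus_e ** 2 / var
    return stat, float(chi2.sf(stat, 1))


def hypergeom_enumeration(n_universe, n_with_attr, n_draw, k_observed):
    """P(X >= k) by enumerating every size-n_draw subset of the universe."""
    universe = list(range(n_universe))
    with_attr = set(range(n_with_attr))
    hits = total = 0
    for draw in combinations(universe, n_draw):
        total += 1
        if sum(1 for x in draw if x in with_attr) >= k_observed:
            hits += 1
    return hits / total


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values, spelled out."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * m / rank_from_end)
        adj[i] = val
        prev = val
    return adj
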