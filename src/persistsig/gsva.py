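"""Per-sample gene-set variation scores via a KS-like random walk.

The score of signature k in sample j is computed in four stages:

1. **Kernel CDF transform.** Each gene's expression across samples is
   mapped through a smoothed empirical CDF: a Poisson kernel for raw
   counts, ``F_ij = (1/n) sum_k PoisCDF(x_ij; lambda = x_ik + 0.5)``, or a
   Gaussian kernel for log-normalized data,
   ``F_ij = (1/n) sum_k Phi((x_ij - x_ik) / h_i)`` with per-gene bandwidth
   ``h_i = sd_i / 4``.  This expresses each value relative to the gene's
   own cross-sample distribution.
2. **Rank centering.** Within each sample the transformed values are
   ranked ascending (ties broken in gene-id order) and the integer ranks
   are shifted to be symmetric about zero: ``r = rank - (p + 1) / 2``.
3. **Random walk.** Genes are laid out from most to least expressed
   (decreasing centered rank); walking down this list, an in-set gene
   advances the in-set running sum S1 by its ``|r|**tau`` share, an
   out-of-set gene advances S2 by ``1/(p - m)``.
   ES+ is the largest positive and ES- the most negative deviation of
   S1 - S2.
4. **Score.** ``|ES+| - |ES-|``, the magnitude-difference convention: a
   set whose genes act concordantly in one direction scores near +-1,
   while genes pulling in both directions cancel.

Counts pipelines are preceded by 75th-percentile scale normalization and,
in cohort mode, by removal of genes with a zero count in any sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, poisson

from .io import ExpressionMatrix, SignatureCollection

logger = logging.getLogger(__name__)

__all__ = [
    "GsvaOptions",
    "KernelTransformed",
    "CenteredRanks",
    "RandomWalkResult",
    "GsvaScoreMatrix",
    "upper_quartile_normalize",
    "filter_zero_genes",
    "kernel_cdf_transform",
    "rank_center",
    "random_walk_es",
    "gsva_scores",
]

POISSON_OFFSET = 0.5  # continuity offset added to the Poisson kernel rate
BANDWIDTH_FLOOR = 1e-8


@dataclass
class GsvaOptions:
    tau: float = 1.0
    cohort_mode: bool = False       # drop genes with any zero count
    max_deviation: bool = False     # alternative |max|-deviation convention


@dataclass
class KernelTransformed:
    gene_ids: list[str]
    unit_ids: list[str]
    values: np.ndarray  # in (0, 1)
    kernel: str


@dataclass
class CenteredRanks:
    gene_ids: list[str]
    unit_ids: list[str]
    values: np.ndarray  # r_ij, per-sample sum exactly 0


@dataclass
class RandomWalkResult:
    es_plus: float
    es_minus: float
    score: float
    path: np.ndarray | None = None


@dataclass
class GsvaScoreMatrix:
    signature_names: list[str]
    unit_ids: list[str]
    values: np.ndarray  # signatures x samples
    kernel: str = ""
    options: GsvaOptions = field(default_factory=GsvaOptions)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.signature_names,
                            columns=self.unit_ids)


def upper_quartile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample so its 75th percentile over its nonzero genes
    equals the geometric mean of all samples' 75th percentiles."""
    if m.value_kind != "counts":
        raise ValueError("upper_quartile_normalize expects counts")
    q75 = np.empty(m.n_units)
    for j, unit in enumerate(m.unit_ids):
        col = m.values[:, j]
        nz = col[col > 0]
        if nz.size == 0 or np.percentile(nz, 75) == 0:
            raise ValueError(f"sample {unit!r} has zero 75th percentile")
        q75[j] = np.percentile(nz, 75)
    target = np.exp(np.mean(np.log(q75)))
    scaled = m.values * (target / q75)[None, :]
    return ExpressionMatrix(list(m.gene_ids), list(m.unit_ids), scaled, "counts")


def filter_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only genes with a strictly positive value in every sample."""
    if m.value_kind != "counts":
        raise ValueError("filter_zero_genes expects counts")
    keep = np.all(m.values > 0, axis=1)
    if not keep.any():
        raise ValueError("all genes have a zero count in some sample")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_zero_genes: dropped %d gene(s)", n_dropped)
    return ExpressionMatrix(
        [g for g, k in zip(m.gene_ids, keep) if k], list(m.unit_ids),
        m.values[keep, :], "counts")


def kernel_cdf_transform(m: ExpressionMatrix, kernel: str) -> KernelTransformed:
    """Smoothed per-gene empirical-CDF transform across samples."""
    if kernel == "poisson":
        if m.value_kind != "counts":
            raise ValueError("poisson kernel requires counts")
    elif kernel == "gaussian":
        if m.value_kind != "lognorm":
            raise ValueError("gaussian kernel requires lognorm values")
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    x = m.values
    n = m.n_units
    if kernel == "gaussian":
        sd = x.std(axis=1, ddof=1) if n > 1 else np.zeros(m.n_genes)
        h = sd / 4.0
        floor = BANDWIDTH_FLOOR * (1.0 + np.abs(x.mean(axis=1)))
        if n == 1 and np.all(h == 0):
            raise ValueError("gaussian kernel undefined for a single sample")
        h = np.maximum(h, floor)
        # F[i, j] = mean_k Phi((x[i, j] - x[i, k]) / h[i]); per-gene loop
        # keeps memory at O(n^2) instead of O(genes * n^2)
        out = np.empty_like(x)
        for i in range(m.n_genes):
            z = (x[i][:, None] - x[i][None, :]) / h[i]
            out[i] = norm.cdf(z).mean(axis=1)
    else:
        lam = x + POISSON_OFFSET  # rate per (gene, reference sample)
        out = np.empty_like(x)
        for i in range(m.n_genes):
            out[i] = poisson.cdf(x[i][:, None], lam[i][None, :]).mean(axis=1)
    out = np.clip(out, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return KernelTransformed(list(m.gene_ids), list(m.unit_ids), out, kernel)


def rank_center(t: KernelTransformed) -> CenteredRanks:
    """Rank genes ascending within each sample and center at zero.

    Ties receive adjacent integer ranks in gene-id order, making the
    result deterministic; the centered ranks of p genes are the integers
    (or half-integers) ``rank - (p + 1) / 2`` and sum exactly to zero.
    """
    p = len(t.gene_ids)
    ids = np.asarray(t.gene_ids, dtype=object)
    id_order = np.argsort(ids, kind="stable")  # lexicographic tie order
    ranks = np.empty_like(t.values)
    for j in range(len(t.unit_ids)):
        order = id_order[np.argsort(t.values[id_order, j], kind="stable")]
        ranks[order, j] = np.arange(1, p + 1)
    centered = ranks - (p + 1) / 2.0
    return CenteredRanks(list(t.gene_ids), list(t.unit_ids), centered)


def _walk(r_col: np.ndarray, in_set: np.ndarray, gene_ids: np.ndarray,
          tau: float) -> np.ndarray:
    """Running S1 - S2 over genes in decreasing centered-rank order.

    Genes are laid out from most to least expressed (decreasing r); the
    in-set running sum advances by the gene's |r|**tau share so extreme
    genes dominate, giving the walk its direction: a set at the top of the
    ordering peaks early (positive score), a set at the bottom dips first
    (negative score).
    """
    absr = np.abs(r_col)
    # decreasing r (expression order), ties by lexicographic gene id
    order = np.lexsort((gene_ids, -r_col))
    in_ord = in_set[order]
    w = absr[order] ** tau
    m = int(in_set.sum())
    p = len(r_col)
    denom_in = w[in_ord].sum()
    step_in = np.zeros(p)
    if denom_in > 0:
        step_in[in_ord] = w[in_ord] / denom_in
    else:  # all in-set genes have |r| = 0: fall back to equal steps
        step_in[in_ord] = 1.0 / m
    step_out = np.zeros(p)
    step_out[~in_ord] = 1.0 / (p - m)
    return np.cumsum(step_in - step_out)


def random_walk_es(r: CenteredRanks, sig: SignatureCollection, unit: str,
                   signature: str, tau: float = 1.0,
                   keep_path: bool = False,
                   max_deviation: bool = False) -> RandomWalkResult:
    """ES+ / ES- / score for one (sample, signature) pair."""
    members = set(sig.intersect(r.gene_ids, signature))
    if not members:
        raise ValueError(f"signature {signature!r} has no genes in the matrix")
    in_set = np.array([g in members for g in r.gene_ids])
    if in_set.all():
        raise ValueError("no out-of-set genes: signature covers the matrix")
    j = r.unit_ids.index(unit)
    path = _walk(r.values[:, j], in_set,
                 np.asarray(r.gene_ids, dtype=object), tau)
    es_plus = max(0.0, float(path.max()))
    es_minus = min(0.0, float(path.min()))
    if max_deviation:
        score = es_plus if es_plus >= -es_minus else es_minus
    else:
        score = abs(es_plus) - abs(es_minus)
    return RandomWalkResult(es_plus, es_minus, score,
                            path if keep_path else None)


def gsva_scores(m: ExpressionMatrix, sigs: SignatureCollection,
                options: GsvaOptions | None = None) -> GsvaScoreMatrix:
    """End-to-end score matrix (signatures x samples).

    Counts input: 75th-percentile scaling, optional zero-count gene filter
    (cohort mode), Poisson kernel.  Log-normalized input: Gaussian kernel.
    Then rank centering and the random walk per (sample, signature).
    """
    options = options or GsvaOptions()
    if m.n_units < 3:
        warnings.warn("fewer than 3 samples: kernel CDFs are poorly "
                      "estimated", stacklevel=2)
    if m.value_kind == "counts":
        work = upper_quartile_normalize(m)
        if options.cohort_mode:
            work = filter_zero_genes(work)
        kernel = "poisson"
    else:
        work = m
        kernel = "gaussian"
    ranks = rank_center(kernel_cdf_transform(work, kernel))
    gene_arr = np.asarray(ranks.gene_ids, dtype=object)
    values = np.empty((len(sigs), len(ranks.unit_ids)))
    for k, name in enumerate(sigs.names):
        members = set(sigs.intersect(ranks.gene_ids, name))
        if not members:
            raise ValueError(f"signature {name!r} has no genes in the matrix")
        in_set = np.array([g in members for g in ranks.gene_ids])
        if in_set.all():
            raise ValueError(
                f"signature {name!r} covers every gene: no out-of-set genes")
        for j in range(len(ranks.unit_ids)):
            path = _walk(ranks.values[:, j], in_set, gene_arr, options.tau)
            es_plus = max(0.0, float(path.max()))
            es_minus = min(0.0, float(path.min()))
            if options.max_deviation:
                values[k, j] = es_plus if es_plus >= -es_minus else es_minus
            else:
                values[k, j] = abs(es_plus) - abs(es_minus)
    return GsvaScoreMatrix(list(sigs.names), list(ranks.unit_ids), values,
                           kernel, options)
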