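"""Single-sample GSEA enrichment scoring on z-scored expression.

The enrichment statistic for a sample is the integral (sum over ranked
positions) of the difference between two running ECDFs over the genes
sorted by expression, highest first:

* the in-set ECDF weighted by rank position, ``P_in(i) = sum_{j<=i, j in S}
  r_j**alpha / sum_{j in S} r_j**alpha`` with ``r_j = N - position_j + 1``
  (top gene has weight N);
* the unweighted out-of-set ECDF ``P_out(i) = #{non-members at or before
  i} / (N - |S|)``.

``ES = sum_i (P_in(i) - P_out(i))``. With ``alpha = 0`` this is a pure
rank statistic, invariant under any strictly increasing per-sample
transform of the expression values. Scores are NOT rescaled across
samples, so each sample's ES is independent of cohort composition.

Expression ties are broken by lexical gene identifier so results are
platform- and ordering-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .gene_sets import GeneSetCollection, restrict_to_universe

log = logging.getLogger(__name__)

__all__ = [
    "SsgseaParams",
    "gene_zscore",
    "ssgsea_sample",
    "ssgsea_matrix",
    "median_dichotomize",
]


@dataclass(frozen=True)
class SsgseaParams:
    """Parameters of the enrichment engine.

    alpha
        Exponent on the rank-position weight ``r = N - position + 1``.
        0.25 is the canonical ssGSEA default; 0 gives the unweighted
        (Kolmogorov–Smirnov-like integral) rank statistic.
    zscore_genes
        Z-score each gene across samples before ranking (population sd).
    """

    alpha: float = 0.25
    zscore_genes: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "zscore_genes": self.zscore_genes}

    @classmethod
    def from_dict(cls, d: dict) -> "SsgseaParams":
        return cls(**d)


def gene_zscore(x: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene (row) across samples using the population sd.

    Zero-variance genes map to all-zero rows (logged). Requires >= 2
    samples.
    """
    if x.shape[1] < 2:
        raise DegenerateDataError("gene z-scoring requires >= 2 samples")
    vals = x.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        log.warning("%d zero-variance gene(s) mapped to all-zero rows", int(flat.sum()))
    sd[sd == 0] = 1.0
    out = (vals - mu) / sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def _rank_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorting genes by value descending, ties by lexical gene id."""
    # lexsort: last key is primary
    return np.lexsort((gene_ids, -values))


def ssgsea_sample(
    values: np.ndarray,
    members: np.ndarray,
    alpha: float,
    gene_ids: np.ndarray | None = None,
) -> float:
    """Enrichment score for one sample and one gene set.

    Parameters
    ----------
    values : expression values over all genes (one sample).
    members : boolean membership mask of the gene set.
    alpha : rank-weight exponent (>= 0).
    gene_ids : optional symbols used only to break expression ties
        deterministically; defaults to the positional index.
    """
    values = np.asarray(values, dtype=float)
    members = np.asarray(members, dtype=bool)
    n = values.size
    n_in = int(members.sum())
    if n_in == 0 or n_in == n:
        raise DegenerateDataError(
            "gene set must contain >=1 member and >=1 non-member gene"
        )
    if gene_ids is None:
        gene_ids = np.array([f"{i:09d}" for i in range(n)])
    order = _rank_order(values, np.asarray(gene_ids))
    m = members[order]
    r = np.arange(n, 0, -1, dtype=float)  # N, N-1, ..., 1
    w = r**alpha
    in_w = np.where(m, w, 0.0)
    p_in = np.cumsum(in_w) / in_w.sum()
    p_out = np.cumsum(~m) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    x: pd.DataFrame,
    collection: GeneSetCollection,
    params: SsgseaParams = SsgseaParams(),
    min_size: int = 3,
) -> pd.DataFrame:
    """Enrichment scores for every (signature, sample) pair.

    ``x`` is a genes × samples frame of log-scale expression. The
    collection is restricted to the measured universe first; signatures
    retaining fewer than ``min_size`` genes are dropped. Returns a
    signatures × samples frame. Deterministic for fixed input and params.
    """
    gene_ids = np.asarray(x.index.astype(str).str.upper())
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("expression matrix has duplicate gene identifiers")
    restricted = restrict_to_universe(collection, gene_ids, min_size=min_size)
    data = gene_zscore(x) if params.zscore_genes else x
    vals = data.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("expression matrix contains non-finite values")
    n_genes, n_samples = vals.shape
    idx = {g: i for i, g in enumerate(gene_ids)}
    membership = np.zeros((len(restricted), n_genes), dtype=bool)
    for k, s in enumerate(restricted):
        membership[k, [idx[g] for g in s.genes]] = True
    sizes = membership.sum(axis=1)
    if ((sizes == 0) | (sizes == n_genes)).any():
        raise DegenerateDataError("each signature needs members and non-members")

    r = np.arange(n_genes, 0, -1, dtype=float)
    w = r**params.alpha
    es = np.empty((len(restricted), n_samples))
    for j in range(n_samples):
        order = _rank_order(vals[:, j], gene_ids)
        m = membership[:, order]  # sets × genes, ranked
        in_w = np.where(m, w[np.newaxis, :], 0.0)
        p_in = np.cumsum(in_w, axis=1) / in_w.sum(axis=1, keepdims=True)
        p_out = np.cumsum(~m, axis=1) / (n_genes - sizes)[:, np.newaxis]
        es[:, j] = (p_in - p_out).sum(axis=1)
    return pd.DataFrame(es, index=restricted.names, columns=x.columns)


def median_dichotomize(v: pd.Series | np.ndarray) -> np.ndarray:
    """Label each value ``high`` iff strictly above the midpoint median.

    Values equal to the median go to ``low`` (fixed tie rule). Raises
    :class:`DegenerateDataError` when all values are identical, since the
    stratification would be degenerate.
    """
    arr = np.asarray(v, dtype=float)
    if arr.size < 2:
        raise DegenerateDataError("median dichotomization requires >= 2 values")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in median dichotomization")
    if np.ptp(arr) == 0:
        raise DegenerateDataError("all values identical: degenerate stratification")
    med = np.median(arr)
    return np.where(arr > med, "high", "low")
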