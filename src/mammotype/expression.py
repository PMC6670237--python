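"""Expression preprocessing, nearest-centroid subtyping, clustering, cluster significance.

The transcriptomic arm of the pipeline mirrors a standard microarray
workflow for mouse mammary tumor cohorts:

* quantile normalization of the probe-level matrix;
* removal of low-variance probes (SD below a fraction of the largest
  observed probe SD, default 2.8%);
* collapse of multi-probe genes to their mean;
* nearest-centroid subtype assignment by Spearman correlation to murine
  intrinsic subtype centroids (the subtype with the highest correlation is
  assigned);
* average-linkage hierarchical clustering of tumors with distance
  1 - Spearman correlation restricted to an intrinsic gene list, cut at the
  root merge into two clusters; and
* a Monte-Carlo two-cluster significance test in the spirit of SigClust:
  the observed 2-cluster index (within-cluster SS / total SS) is compared
  to its distribution over null datasets drawn from a single Gaussian whose
  diagonal covariance is the data's covariance eigenvalue spectrum floored
  at a MAD-based background-noise estimate, each null split by 2-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .errors import (
    ClusteringError,
    EmptyResultError,
    InsufficientOverlapError,
    InvalidLabelsError,
    PreprocessingError,
)

__all__ = [
    "SubtypeCall",
    "ClusterResult",
    "quantile_normalize",
    "collapse_probes",
    "variance_filter",
    "assign_subtypes",
    "hierarchical_cluster",
    "cluster_significance",
    "cluster_index",
    "preprocess",
]

#: default SD threshold as a fraction of the largest observed probe SD
DEFAULT_SD_FRACTION = 0.028
#: default minimum gene overlap for centroid correlation
DEFAULT_MIN_OVERLAP = 20


@dataclass(frozen=True)
class SubtypeCall:
    """Nearest-centroid subtype assignment for one sample."""

    sample_id: str
    assigned_subtype: str
    correlations: pd.Series  # Spearman rho to each centroid, in [-1, 1]
    tie: bool = False


@dataclass(frozen=True)
class ClusterResult:
    """A two-cluster split of a cohort with its significance."""

    labels: pd.Series  # sample -> cluster id in {1, 2}
    linkage_record: np.ndarray | None  # scipy linkage matrix (merge history)
    cluster_index: float | None = None  # within-cluster SS / total SS, in [0, 1]
    p_value: float | None = None
    n_null: int | None = None


def _check_no_missing(matrix: pd.DataFrame) -> None:
    if matrix.isna().any().any():
        bad = matrix.index[matrix.isna().any(axis=1)].tolist()
        raise PreprocessingError(f"missing values in genes: {bad[:10]}")


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares the same value
    distribution (the across-sample mean of sorted columns).

    Ties within a column receive the mean of the reference quantile values
    they span, which makes the transform idempotent.
    """
    if matrix.shape[1] < 2:
        raise PreprocessingError("quantile normalization requires >= 2 samples")
    _check_no_missing(matrix)
    values = matrix.to_numpy(dtype=float)
    reference = np.mean(np.sort(values, axis=0), axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        order = np.argsort(values[:, j], kind="stable")
        col = np.empty(len(order))
        col[order] = reference
        # ties span several reference quantiles: give them the mean
        ranks = rankdata(values[:, j], method="average")
        if np.unique(values[:, j]).size != len(col):
            df = pd.Series(col).groupby(ranks).transform("mean")
            col = df.to_numpy()
        out[:, j] = col
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_probes(matrix: pd.DataFrame, probe_gene_map: pd.Series) -> pd.DataFrame:
    """Collapse probe rows to one row per gene by the arithmetic mean.

    ``probe_gene_map`` maps probe id -> gene id and must cover every probe
    in the matrix.
    """
    probe_gene_map = pd.Series(probe_gene_map)
    unmapped = matrix.index.difference(probe_gene_map.index)
    if len(unmapped) > 0:
        raise PreprocessingError(f"unmapped probes: {unmapped.tolist()[:10]}")
    genes = probe_gene_map.reindex(matrix.index)
    collapsed = matrix.groupby(genes.to_numpy()).mean()
    collapsed.index.name = matrix.index.name
    return collapsed


def variance_filter(matrix: pd.DataFrame, fraction: float = DEFAULT_SD_FRACTION) -> pd.DataFrame:
    """Drop rows whose sample SD falls below ``fraction`` of the largest row SD.

    SD uses the n-1 denominator; row order is preserved.
    """
    if matrix.shape[1] < 2:
        raise PreprocessingError("variance filter requires >= 2 samples")
    _check_no_missing(matrix)
    sds = matrix.std(axis=1, ddof=1)
    kept = matrix.loc[sds >= fraction * sds.max()]
    if kept.shape[0] == 0:
        raise EmptyResultError("variance filter removed every row")
    return kept


def preprocess(
    matrix: pd.DataFrame,
    probe_gene_map: pd.Series,
    sd_fraction: float = DEFAULT_SD_FRACTION,
) -> pd.DataFrame:
    """Full preprocessing chain: quantile normalize, SD-filter probes, collapse to genes."""
    return collapse_probes(
        variance_filter(quantile_normalize(matrix), sd_fraction), probe_gene_map
    )


def _column_ranks(values: np.ndarray) -> np.ndarray:
    """Midrank transform of each column."""
    return np.apply_along_axis(rankdata, 0, values)


def _spearman_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman correlation between every column of ``a`` and of ``b`` (midranks)."""
    ra = _column_ranks(a)
    rb = _column_ranks(b)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    denom = np.outer(
        np.sqrt(np.einsum("ij,ij->j", ra, ra)), np.sqrt(np.einsum("ij,ij->j", rb, rb))
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ra.T @ rb) / denom
    return rho


def assign_subtypes(
    matrix: pd.DataFrame,
    centroids: pd.DataFrame,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[SubtypeCall]:
    """Assign each sample the subtype whose centroid it is most Spearman-correlated with.

    Correlations are computed over the gene intersection of the matrix and
    the centroid set (midranks for ties); exact correlation ties are broken
    by lexicographic subtype name and flagged in the call.
    """
    shared = matrix.index.intersection(centroids.index)
    if len(shared) < min_overlap:
        raise InsufficientOverlapError(
            f"gene overlap {len(shared)} below the floor of {min_overlap}"
        )
    # lexicographic column order makes argmax's first-hit the deterministic tie-break
    cents = centroids.loc[shared].reindex(sorted(centroids.columns), axis=1)
    rho = _spearman_cross(matrix.loc[shared].to_numpy(), cents.to_numpy())
    calls = []
    for i, sample in enumerate(matrix.columns):
        corrs = pd.Series(rho[i], index=cents.columns)
        best = corrs.idxmax()
        tie = bool((corrs == corrs.max()).sum() > 1)
        calls.append(SubtypeCall(str(sample), str(best), corrs, tie))
    return calls


def hierarchical_cluster(
    matrix: pd.DataFrame,
    gene_list: list[str] | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> ClusterResult:
    """Average-linkage hierarchical clustering of samples with distance
    1 - Spearman correlation, restricted to ``gene_list``; the root merge of
    the dendrogram defines two clusters."""
    if matrix.shape[1] < 3:
        raise ClusteringError("clustering requires >= 3 samples")
    if gene_list is not None:
        shared = matrix.index.intersection(pd.Index(gene_list))
        if len(shared) < min_overlap:
            raise InsufficientOverlapError(
                f"gene-list overlap {len(shared)} below the floor of {min_overlap}"
            )
        matrix = matrix.loc[shared]
    rho = _spearman_cross(matrix.to_numpy(), matrix.to_numpy())
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = pd.Series(fcluster(Z, 2, criterion="maxclust"), index=matrix.columns)
    return ClusterResult(labels=labels, linkage_record=Z)


def cluster_index(X: np.ndarray, labels: np.ndarray) -> float:
    """2-cluster index: within-cluster sum of squares about the cluster means
    divided by total sum of squares about the grand mean (samples are points
    in gene space).  0 for perfectly tight clusters; <= 1."""
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    if total == 0.0:
        return 0.0
    within = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        within += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return within / total


def _two_means_ci(X: np.ndarray, n_restarts: int, rng: np.random.Generator) -> float:
    """Best (lowest) 2-means cluster index over ``n_restarts`` seeded Lloyd runs."""
    n = X.shape[0]
    best = np.inf
    for _ in range(n_restarts):
        idx = rng.choice(n, size=2, replace=False)
        centers = X[idx].copy()
        assign = np.zeros(n, dtype=int)
        for it in range(100):
            d0 = ((X - centers[0]) ** 2).sum(axis=1)
            d1 = ((X - centers[1]) ** 2).sum(axis=1)
            new_assign = (d1 < d0).astype(int)
            if it > 0 and (new_assign == assign).all():
                break
            assign = new_assign
            if assign.all() or not assign.any():  # one cluster emptied
                break
            centers[0] = X[assign == 0].mean(axis=0)
            centers[1] = X[assign == 1].mean(axis=0)
        if 0 < assign.sum() < n:
            best = min(best, cluster_index(X, assign))
    return best if np.isfinite(best) else 1.0


def cluster_significance(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_null: int = 1000,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterResult:
    """Monte-Carlo significance of a two-cluster split (SigClust-style).

    The observed statistic is the cluster index of the supplied labels.
    The null is ``n_null`` datasets of the same shape drawn from a single
    zero-mean Gaussian with diagonal covariance equal to the data's sample
    covariance eigenvalues (top n-1 from an SVD of the centered matrix,
    remaining dimensions and any smaller eigenvalue floored at a MAD-based
    background-noise variance).  Each null dataset is split by 2-means
    (best of ``n_restarts`` restarts) and its cluster index recorded;
    p = (1 + #{null CI <= observed CI}) / (n_null + 1).
    """
    if n_null < 100:
        raise ClusteringError("n_null must be >= 100")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    labels = labels.reindex(matrix.columns)
    uniq = labels.unique()
    if len(uniq) != 2 or labels.value_counts().min() == 0:
        raise InvalidLabelsError("cluster_significance requires exactly 2 non-empty clusters")
    observed = cluster_index(X, labels.to_numpy())

    n, d = X.shape
    centered = X - X.mean(axis=0)
    # background noise variance from the MAD of all matrix entries
    flat = centered.ravel()
    mad = np.median(np.abs(flat - np.median(flat)))
    sigma2_bg = (mad / 0.6744897501960817) ** 2
    sv = np.linalg.svd(centered, compute_uv=False)
    eigs = np.zeros(d)
    eigs[: len(sv)] = sv**2 / max(n - 1, 1)
    eigs = np.maximum(eigs, sigma2_bg if sigma2_bg > 0 else np.finfo(float).tiny)

    rng = np.random.default_rng(seed)
    scale = np.sqrt(eigs)
    null_ci = np.empty(n_null)
    for b in range(n_null):
        sim = rng.standard_normal((n, d)) * scale
        null_ci[b] = _two_means_ci(sim, n_restarts, rng)
    p = (1.0 + float((null_ci <= observed).sum())) / (n_null + 1.0)
    return ClusterResult(
        labels=labels, linkage_record=None,
        cluster_index=observed, p_value=p, n_null=n_null,
    )
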