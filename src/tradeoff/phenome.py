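"""Growth-phenome preprocessing and two-block trade-off detection.

The pipeline for a strains x conditions growth matrix is::

    filter_missing -> impute_knn -> standardize_conditions
        -> svd_reconstruct (rank 2) -> condition_correlation
        -> hcluster / consensus_cluster -> pac

Rows/columns with more than 10% missing values are dropped, the remainder
is imputed by k-nearest-neighbour averaging, every condition is scaled to
mean 0 / unit variance, and the matrix is reconstructed from its two
leading singular triplets to suppress condition-specific idiosyncrasies.
Conditions are then clustered on the 1 - Spearman correlation distance
(average linkage); the robustness of each candidate cluster number K is
quantified by consensus clustering over resampled subsets and the
proportion of ambiguous clustering (PAC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy import stats

from .errors import ContractError, EmptyResultError

logger = logging.getLogger(__name__)

__all__ = [
    "PhenomeMatrix",
    "LowRankPhenome",
    "ConsensusResult",
    "ClusterAssignment",
    "filter_missing",
    "impute_knn",
    "standardize_conditions",
    "svd_reconstruct",
    "condition_correlation",
    "hcluster",
    "consensus_cluster",
    "pac",
    "cluster_composition_test",
]


@dataclass
class PhenomeMatrix:
    """Strains x conditions growth values plus optional annotations."""

    values: pd.DataFrame
    clade_label: pd.Series | None = None  # strain -> clade class
    stress_type: pd.Series | None = None  # condition -> stress category

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ContractError("strain and condition ids must be unique")


@dataclass
class LowRankPhenome:
    """A rank-r reconstruction together with its singular triplets."""

    values: pd.DataFrame
    rank_used: int
    u: np.ndarray  # strains x rank, sign-oriented
    s: np.ndarray  # singular values, nonincreasing (all of them)
    vt: np.ndarray  # rank x conditions, sign-oriented


@dataclass
class ClusterAssignment:
    assignment: pd.Series  # item -> cluster id (1..K)
    K: int
    linkage_method: str = "average"
    distance_name: str = "1-spearman"


@dataclass
class ConsensusResult:
    """Per-K consensus matrices and PAC values from resampled clustering."""

    consensus: dict[int, pd.DataFrame]
    pac_values: dict[int, float]
    n_iterations: int
    resample_fraction: float
    assignments: dict[int, ClusterAssignment] = field(default_factory=dict)

    def optimal_k(self, exclude_singletons: bool = False) -> list[int]:
        """K values minimising PAC; ties reported as a list.

        With ``exclude_singletons`` K values whose full-data cut contains a
        singleton cluster are not eligible.
        """
        eligible = dict(self.pac_values)
        if exclude_singletons:
            for k, asg in self.assignments.items():
                if asg.assignment.value_counts().min() == 1:
                    eligible.pop(k, None)
        if not eligible:
            raise EmptyResultError("no eligible K after singleton exclusion")
        best = min(eligible.values())
        return sorted(k for k, v in eligible.items() if v == best)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, PhenomeMatrix):
        return matrix.values
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return pd.DataFrame(np.asarray(matrix, dtype=float))


def _require_complete(df: pd.DataFrame, op: str) -> None:
    if df.isna().values.any():
        raise ContractError(
            f"{op} requires a fully observed matrix; run filter_missing and "
            "impute_knn first"
        )


def filter_missing(matrix, max_missing_frac: float = 0.1) -> pd.DataFrame:
    """Drop rows then columns whose missing fraction exceeds the threshold.

    Applied iteratively (rows first, then columns) until a fixed point, so
    a column rescued by the removal of a bad row is retained.
    """
    df = _as_frame(matrix)
    if df.size == 0:
        raise ContractError("input matrix is empty")
    while True:
        row_frac = df.isna().mean(axis=1)
        df2 = df.loc[row_frac <= max_missing_frac]
        if df2.shape[0] == 0:
            raise EmptyResultError("all rows exceeded the missing threshold")
        col_frac = df2.isna().mean(axis=0)
        df2 = df2.loc[:, col_frac <= max_missing_frac]
        if df2.shape[1] == 0:
            raise EmptyResultError("all columns exceeded the missing threshold")
        if df2.shape == df.shape:
            return df2
        df = df2


def impute_knn(matrix, k: int = 10) -> pd.DataFrame:
    """Impute missing cells from the k nearest rows.

    Distance between two rows is the root mean squared difference over
    their mutually observed columns (rescaling by the shared-column count
    makes rows with different missingness comparable); rows sharing no
    observed column are excluded as neighbours.  A missing cell takes the
    mean of the column values of the k nearest rows that observe that
    column.  When fewer than k such neighbours exist the column mean of
    the observed values is used instead (logged).
    """
    df = _as_frame(matrix)
    if df.isna().all(axis=1).any() or df.isna().all(axis=0).any():
        raise ContractError("every row and column needs at least one observed value")
    values = df.to_numpy(dtype=float)
    obs = ~np.isnan(values)
    n = values.shape[0]

    # pairwise RMS distance over shared columns
    filled = np.where(obs, values, 0.0)
    shared = obs.astype(float) @ obs.T.astype(float)
    sq = filled**2
    cross = filled @ filled.T
    ssq = sq @ obs.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (ssq + ssq.T - 2.0 * cross) / shared
        d2 = np.where(d2 < 0, 0.0, d2)  # numeric guard
        dist = np.sqrt(d2)
    dist[shared == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    out = values.copy()
    col_means = np.nanmean(values, axis=0)
    miss_rows, miss_cols = np.where(~obs)
    for i, j in zip(miss_rows, miss_cols):
        cand = np.where(obs[:, j] & np.isfinite(dist[i]))[0]
        if cand.size < k:
            logger.warning(
                "impute_knn: only %d candidate neighbours (< k=%d) for cell "
                "(%s, %s); falling back to column mean",
                cand.size, k, df.index[i], df.columns[j],
            )
            out[i, j] = col_means[j]
            continue
        order = cand[np.argsort(dist[i, cand], kind="stable")[:k]]
        out[i, j] = values[order, j].mean()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def standardize_conditions(matrix) -> pd.DataFrame:
    """Scale every condition column to mean 0, unit sample variance (n-1)."""
    df = _as_frame(matrix)
    _require_complete(df, "standardize_conditions")
    sd = df.std(axis=0, ddof=1)
    bad = sd[(sd == 0) | sd.isna()]
    if len(bad):
        raise ContractError(
            f"zero-variance condition(s): {', '.join(map(str, bad.index))}"
        )
    return (df - df.mean(axis=0)) / sd


def svd_reconstruct(matrix, rank: int = 2) -> LowRankPhenome:
    """Reconstruct the matrix from its leading ``rank`` singular triplets.

    Computes M = U S V^T and returns sum_{k<=rank} s_k u_k v_k^T.  Each
    retained singular pair is sign-oriented so the largest-magnitude entry
    of the right singular vector is positive (determinism; the product is
    unaffected).
    """
    df = _as_frame(matrix)
    _require_complete(df, "svd_reconstruct")
    if not 1 <= rank <= min(df.shape):
        raise ContractError(f"rank must be in [1, {min(df.shape)}]")
    u, s, vt = np.linalg.svd(df.to_numpy(dtype=float), full_matrices=False)
    for kk in range(rank):
        j = np.argmax(np.abs(vt[kk]))
        if vt[kk, j] < 0:
            vt[kk] *= -1.0
            u[:, kk] *= -1.0
    recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
    return LowRankPhenome(
        values=pd.DataFrame(recon, index=df.index, columns=df.columns),
        rank_used=rank,
        u=u[:, :rank],
        s=s,
        vt=vt[:rank],
    )


def condition_correlation(matrix) -> pd.DataFrame:
    """Condition x condition Spearman correlation (midrank ties)."""
    df = _as_frame(matrix)
    _require_complete(df, "condition_correlation")
    if df.shape[0] < 3:
        raise ContractError("need at least 3 strains for rank correlation")
    rho = stats.spearmanr(df.to_numpy(dtype=float), axis=0).statistic
    rho = np.atleast_2d(rho)
    if rho.shape != (df.shape[1], df.shape[1]):  # 2-column input
        r = float(rho.ravel()[0]) if rho.size else 1.0
        rho = np.array([[1.0, r], [r, 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def _linkage_from_distance(dist: pd.DataFrame, method: str) -> np.ndarray:
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ContractError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ContractError("distance matrix must have a zero diagonal")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return sch.linkage(squareform(d, checks=False), method=method)


def hcluster(distance_matrix, K: int, linkage: str = "average",
             distance_name: str = "1-spearman") -> ClusterAssignment:
    """Agglomerative clustering of a precomputed distance matrix, cut at K."""
    dist = distance_matrix if isinstance(distance_matrix, pd.DataFrame) else pd.DataFrame(
        np.asarray(distance_matrix, dtype=float))
    n = dist.shape[0]
    if K > n:
        raise ContractError(f"K={K} exceeds the number of items ({n})")
    if K < 1:
        raise ContractError("K must be >= 1")
    Z = _linkage_from_distance(dist, linkage)
    labels = sch.fcluster(Z, t=K, criterion="maxclust")
    if len(np.unique(labels)) != K:
        # tied merge heights can make maxclust undershoot; cut by merge order
        labels = sch.fcluster(Z, t=Z[-(K - 1), 2] - 1e-12, criterion="distance") if K > 1 else np.ones(n, int)
    asg = pd.Series(labels, index=dist.index, name="cluster")
    if asg.nunique() != K:
        raise ContractError(f"could not produce exactly {K} clusters")
    return ClusterAssignment(assignment=asg, K=K, linkage_method=linkage,
                             distance_name=distance_name)


def _spearman_distance(values: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation between columns, NaN-correlations -> rho=0."""
    rho = stats.spearmanr(values, axis=0).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if rho.shape != (values.shape[1],) * 2:
        r = float(rho.ravel()[0]) if rho.size else 0.0
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.where(np.isnan(rho), 0.0, rho)
    np.fill_diagonal(rho, 1.0)
    return 1.0 - rho


def consensus_cluster(
    matrix,
    K_range=range(2, 7),
    n_iterations: int = 1000,
    resample_fraction: float = 0.8,
    seed: int = 0,
    linkage: str = "average",
) -> ConsensusResult:
    """Consensus clustering of conditions over resampled data subsets.

    Per iteration, ``floor(f * n_conditions)`` conditions (items) and
    ``floor(f * n_strains)`` strains (features) are drawn without
    replacement; the sampled conditions are clustered on 1 - Spearman
    distance (average linkage, one tree cut at every K).  The consensus
    index of a condition pair at K is the number of iterations in which
    they were co-clustered divided by the number in which both were
    sampled; a pair never co-sampled gets index 0 (logged).  PAC is
    computed for every K from the consensus matrix.
    """
    df = _as_frame(matrix)
    _require_complete(df, "consensus_cluster")
    if not 0 < resample_fraction <= 1:
        raise ContractError("resample_fraction must lie in (0, 1]")
    K_range = sorted(set(int(k) for k in K_range))
    if min(K_range) < 2:
        raise ContractError("minimum K must be >= 2")
    n_strain, n_cond = df.shape
    if max(K_range) > n_cond:
        raise ContractError("K exceeds the number of conditions")
    n_item = int(np.floor(resample_fraction * n_cond))
    n_feat = int(np.floor(resample_fraction * n_strain))
    if n_item < max(K_range):
        raise ContractError("resampled item count smaller than the largest K")

    rng = np.random.default_rng(seed)
    values = df.to_numpy(dtype=float)
    co_sampled = np.zeros((n_cond, n_cond))
    co_clustered = {k: np.zeros((n_cond, n_cond)) for k in K_range}

    for _ in range(n_iterations):
        items = np.sort(rng.choice(n_cond, size=n_item, replace=False))
        feats = rng.choice(n_strain, size=n_feat, replace=False)
        sub = values[np.ix_(feats, items)]
        co_sampled[np.ix_(items, items)] += 1.0
        dist = _spearman_distance(sub)
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0
        Z = sch.linkage(squareform(dist, checks=False), method=linkage)
        for k in K_range:
            labels = sch.fcluster(Z, t=k, criterion="maxclust")
            same = labels[:, None] == labels[None, :]
            co_clustered[k][np.ix_(items, items)] += same

    never = (co_sampled == 0) & ~np.eye(n_cond, dtype=bool)
    if never.any():
        logger.warning("consensus_cluster: %d pairs never co-sampled; index set to 0",
                       int(never.sum()) // 2)
    denom = np.where(co_sampled == 0, np.inf, co_sampled)

    consensus, pac_values, assignments = {}, {}, {}
    full_dist = pd.DataFrame(_spearman_distance(values), index=df.columns,
                             columns=df.columns)
    for k in K_range:
        cm = co_clustered[k] / denom
        np.fill_diagonal(cm, 1.0)
        cm = (cm + cm.T) / 2.0
        cdf = pd.DataFrame(cm, index=df.columns, columns=df.columns)
        consensus[k] = cdf
        pac_values[k] = pac(cdf)
        assignments[k] = hcluster(full_dist, K=k, linkage=linkage)
    return ConsensusResult(
        consensus=consensus,
        pac_values=pac_values,
        n_iterations=n_iterations,
        resample_fraction=resample_fraction,
        assignments=assignments,
    )


def pac(consensus_matrix, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of ambiguous clustering: fraction of off-diagonal pairs
    whose consensus index falls strictly inside (lower, upper)."""
    if lower >= upper:
        raise ContractError("lower bound must be below upper bound")
    cm = _as_frame(consensus_matrix).to_numpy(dtype=float)
    if cm.min() < 0 or cm.max() > 1:
        raise ContractError("consensus entries must lie in [0, 1]")
    iu = np.triu_indices(cm.shape[0], k=1)
    vals = cm[iu]
    if vals.size == 0:
        raise ContractError("need at least 2 items")
    return float(np.mean((vals > lower) & (vals < upper)))


def cluster_composition_test(strain_clusters: pd.Series, clade_labels: pd.Series):
    """Pearson chi-squared test of cluster x clade independence.

    Returns ``(chi2, dof, p)`` from the contingency table of the shared
    strains.  Requires at least two clusters and two label classes.
    """
    shared = strain_clusters.index.intersection(clade_labels.index)
    table = pd.crosstab(strain_clusters.loc[shared], clade_labels.loc[shared])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ContractError("need >= 2 clusters and >= 2 clade classes")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ContractError("a cluster or clade class has zero members")
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
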