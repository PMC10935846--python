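"""Locus-to-gene association mapping and network connectedness testing.

Association scans report p-values for genomic loci; each gene inherits
the smallest p-value among the loci overlapping its gene body (1-based
inclusive coordinates; >= 1 bp overlap).  Per-gene p-values from several
scans are aggregated (Fisher's method by default, or a minimum rule), the
top-ranked genes are selected, and their functional interconnectedness is
quantified as the size of the largest connected component (LCC) of the
induced subgraph on a confidence-scored interaction network (edges with
confidence strictly above 0.4 by default, i.e. medium confidence).
Significance comes from comparing against random gene samples of the same
size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ContractError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "LccTestResult",
    "gene_pvalue_from_loci",
    "aggregate_pvalues",
    "top_genes",
    "lcc_size",
    "lcc_null_test",
    "lcc_size_curve",
]


class GeneNetwork:
    """Undirected simple graph with per-edge confidence in [0, 1].

    Self-loops are dropped; duplicate unordered pairs keep the maximum
    confidence (logged).
    """

    def __init__(self, edges: pd.DataFrame):
        req = {"gene_a", "gene_b", "confidence"}
        if not req.issubset(edges.columns):
            raise ContractError(f"edge table needs columns {sorted(req)}")
        conf = edges["confidence"].to_numpy(dtype=float)
        if conf.size and (conf.min() < 0 or conf.max() > 1):
            raise ContractError("edge confidences must lie in [0, 1]")
        e = edges.loc[edges["gene_a"] != edges["gene_b"]].copy()
        n_loops = len(edges) - len(e)
        if n_loops:
            logger.warning("GeneNetwork: dropped %d self-loops", n_loops)
        a = e[["gene_a", "gene_b"]].min(axis=1)
        b = e[["gene_a", "gene_b"]].max(axis=1)
        e = pd.DataFrame({"gene_a": a, "gene_b": b, "confidence": e["confidence"].values})
        before = len(e)
        e = e.groupby(["gene_a", "gene_b"], as_index=False)["confidence"].max()
        if len(e) < before:
            logger.warning("GeneNetwork: collapsed %d duplicate edges (max confidence kept)",
                           before - len(e))
        self.edges = e
        self.nodes = sorted(set(e["gene_a"]) | set(e["gene_b"]))

    def graph(self, min_confidence: float = 0.4) -> nx.Graph:
        """Graph over all nodes keeping edges with confidence strictly above
        the threshold."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        keep = self.edges["confidence"] > min_confidence
        g.add_weighted_edges_from(
            self.edges.loc[keep, ["gene_a", "gene_b", "confidence"]].itertuples(index=False),
            weight="confidence",
        )
        return g


@dataclass
class LccTestResult:
    observed_lcc_size: int
    null_mean: float
    null_sd: float
    empirical_p: float
    n_iterations: int
    n_genes_selected: int


def _check_intervals(df: pd.DataFrame, what: str) -> None:
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]][0]
        raise ContractError(f"malformed {what} interval at {bad!r}: start > end")


def gene_pvalue_from_loci(locus_pvalues: pd.DataFrame,
                          gene_intervals: pd.DataFrame) -> pd.Series:
    """Minimum locus p-value over the loci intersecting each gene body.

    Both tables use 1-based inclusive coordinates; overlap means
    ``max(starts) <= min(ends)`` on the same chromosome.  Genes with no
    intersecting locus are omitted.
    """
    loci = pd.DataFrame(locus_pvalues)
    req = {"chrom", "start", "end", "p"}
    if not req.issubset(loci.columns):
        raise ContractError(f"locus table needs columns {sorted(req)}")
    _check_intervals(loci, "locus")
    _check_intervals(gene_intervals, "gene")

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in loci.groupby("chrom"):
        # IntervalTree is half-open; +1 on the end converts 1-based inclusive
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e) + 1, float(p))
            for s, e, p in zip(sub["start"], sub["end"], sub["p"])
        )
    out = {}
    for gene, row in gene_intervals.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        hits = tree.overlap(int(row["start"]), int(row["end"]) + 1)
        if hits:
            out[gene] = min(iv.data for iv in hits)
    return pd.Series(out, name="p", dtype=float)


def aggregate_pvalues(per_condition: list[pd.Series], method: str = "fisher") -> pd.Series:
    """Aggregate per-gene p-values across condition sets.

    ``fisher``: -2 * sum(ln p) against chi-squared with 2k degrees of
    freedom, k = number of condition sets in which the gene is scored
    (k = 1 reduces to the input p).  ``min``: smallest p across sets.
    Zero p-values are clamped to the smallest positive double (logged).
    """
    if method not in ("fisher", "min"):
        raise ContractError(f"unknown aggregation method {method!r}")
    if not per_condition:
        raise ContractError("need at least one condition set")
    frames = []
    tiny = 1e-300  # keeps -2 ln p finite and the chi-squared tail nonzero
    for i, s in enumerate(per_condition):
        s = pd.Series(s, dtype=float)
        if (s <= 0).any():
            logger.warning("aggregate_pvalues: clamping %d non-positive p-values",
                           int((s <= 0).sum()))
            s = s.clip(lower=tiny)
        if (s > 1).any():
            raise ContractError("p-values must lie in (0, 1]")
        frames.append(s.rename(i))
    wide = pd.concat(frames, axis=1)
    if method == "min":
        return wide.min(axis=1, skipna=True).rename("p")
    k = wide.notna().sum(axis=1)
    stat = -2.0 * np.log(wide).sum(axis=1, skipna=True)
    agg = pd.Series(stats.chi2.sf(stat, 2 * k), index=wide.index, name="p")
    return agg


def top_genes(aggregated: pd.Series, k: int = 50) -> list:
    """The k genes with the smallest aggregated p; ties broken by gene id."""
    if k <= 0:
        raise ContractError("k must be positive")
    agg = pd.Series(aggregated).dropna()
    if k > len(agg):
        raise ContractError(f"k={k} exceeds the number of scored genes ({len(agg)})")
    ordered = agg.sort_index().sort_values(kind="stable")
    if k < len(agg) and ordered.iloc[k - 1] == ordered.iloc[k]:
        logger.info("top_genes: tie at the rank-%d boundary broken lexicographically", k)
    return list(ordered.index[:k])


def lcc_size(network: GeneNetwork, gene_set, min_confidence: float = 0.4) -> int:
    """Largest connected component of the induced subgraph on gene_set.

    Edges need confidence strictly above ``min_confidence``; genes absent
    from the network count as isolated nodes (component size 1).
    """
    genes = set(gene_set)
    if not genes:
        raise ContractError("gene_set is empty")
    g = network.graph(min_confidence)
    present = genes & set(g.nodes)
    sub = g.subgraph(present)
    best = max((len(c) for c in nx.connected_components(sub)), default=0)
    return max(best, 1)  # absent genes are isolated singletons


def lcc_null_test(
    network: GeneNetwork,
    n_genes: int,
    observed_size: int,
    n_iterations: int = 1000,
    min_confidence: float = 0.4,
    seed: int = 0,
) -> LccTestResult:
    """Compare an observed LCC size against random same-size gene samples.

    Genes are sampled uniformly without replacement from the network
    nodes; the empirical p-value uses the add-one permutation estimator
    ``(1 + #{null >= observed}) / (n_iterations + 1)`` and is never zero.
    """
    if n_iterations < 1:
        raise ContractError("n_iterations must be >= 1")
    if n_genes > len(network.nodes):
        raise ContractError("n_genes exceeds the network node count")
    rng = np.random.default_rng(seed)
    g = network.graph(min_confidence)
    nodes = np.array(network.nodes, dtype=object)
    sizes = np.empty(n_iterations, dtype=float)
    for i in range(n_iterations):
        sample = nodes[rng.choice(len(nodes), size=n_genes, replace=False)]
        sub = g.subgraph(sample)
        sizes[i] = max((len(c) for c in nx.connected_components(sub)), default=1)
    p = (1.0 + float((sizes >= observed_size).sum())) / (n_iterations + 1.0)
    return LccTestResult(
        observed_lcc_size=int(observed_size),
        null_mean=float(sizes.mean()),
        null_sd=float(sizes.std(ddof=1)) if n_iterations > 1 else 0.0,
        empirical_p=float(p),
        n_iterations=n_iterations,
        n_genes_selected=int(n_genes),
    )


def lcc_size_curve(
    network: GeneNetwork,
    ranked_genes: list,
    k_grid: list[int],
    n_iterations: int = 1000,
    min_confidence: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed LCC size of the top-k genes vs the random-sample null, per k.

    Null samples are drawn independently for every k (sub-seeded from
    ``seed`` by position in the grid).
    """
    if not list(k_grid):
        raise ContractError("k_grid is empty")
    if max(k_grid) > len(ranked_genes):
        raise ContractError("k_grid exceeds the ranking length")
    rows = []
    for i, k in enumerate(k_grid):
        obs = lcc_size(network, ranked_genes[:k], min_confidence)
        res = lcc_null_test(network, k, obs, n_iterations=n_iterations,
                            min_confidence=min_confidence, seed=seed + 1000 * i)
        rows.append((k, obs, res.null_mean, res.null_sd, res.empirical_p))
    return pd.DataFrame(rows, columns=["k", "observed_lcc", "null_mean",
                                       "null_sd", "empirical_p"]).set_index("k")
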