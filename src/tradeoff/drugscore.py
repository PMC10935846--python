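"""PS/NS expression scoring of cell-line panels vs drug resistance.

Orthologs of the growth-program (PS) and survival-program (NS) gene sets
are scored on a cell-line expression matrix as the per-line median of the
gene-wise mean-centred expression over each set.  Per drug, Spearman
correlations of the PS, NS and PS-NS difference scores against a
resistance measure (e.g. a normalised IC50 Z-score, higher = more
resistant) quantify whether survival-program expression predicts
resistance.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, EmptyResultError
from .signature import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "map_orthologs",
    "score_cell_lines",
    "correlate_with_resistance",
    "summarize_correlations",
]


def map_orthologs(gene_set: GeneSet, ortholog_map: dict) -> GeneSet:
    """Map a yeast gene set to the union of its human ortholog targets.

    ``ortholog_map`` maps a source gene id to an iterable of target ids
    (one-to-many allowed).  Members without a mapping are dropped and
    counted in the log.
    """
    if not ortholog_map:
        raise ContractError("ortholog map is empty")
    targets: set = set()
    unmapped = 0
    for gene in gene_set.members:
        hits = ortholog_map.get(gene)
        if hits:
            targets.update(hits)
        else:
            unmapped += 1
    if unmapped:
        logger.info("map_orthologs: %d/%d members of %s had no ortholog",
                    unmapped, len(gene_set.members), gene_set.name)
    if not targets:
        raise EmptyResultError(f"no member of {gene_set.name!r} mapped to an ortholog")
    return GeneSet(f"{gene_set.name}_orthologs", frozenset(targets),
                   f"ortholog targets of {gene_set.name}")


def score_cell_lines(expression: pd.DataFrame, ps_set: GeneSet,
                     ns_set: GeneSet) -> pd.DataFrame:
    """Per-cell-line PS/NS median scores on gene-centred expression.

    The matrix (genes x cell lines) is gene-wise mean-centred, then each
    cell line's ps_score / ns_score is the median over the genes of the
    respective set present in the matrix (even counts: midpoint of the two
    central order statistics).  Genes claimed by both sets are excluded
    from both (warned).  Returns a DataFrame indexed by cell line with
    columns ``ps_score``, ``ns_score`` and ``diff_score = ps - ns``.
    """
    overlap = ps_set.members & ns_set.members
    ps_genes = set(ps_set.members)
    ns_genes = set(ns_set.members)
    if overlap:
        warnings.warn(f"{len(overlap)} genes in both PS and NS sets; excluded from both",
                      stacklevel=2)
        ps_genes -= overlap
        ns_genes -= overlap
    ps_idx = expression.index.intersection(list(ps_genes))
    ns_idx = expression.index.intersection(list(ns_genes))
    if len(ps_idx) == 0 or len(ns_idx) == 0:
        raise ContractError("PS or NS set has no gene in the expression matrix")
    centred = expression.sub(expression.mean(axis=1), axis=0)
    scores = pd.DataFrame({
        "ps_score": centred.loc[ps_idx].median(axis=0),
        "ns_score": centred.loc[ns_idx].median(axis=0),
    })
    scores["diff_score"] = scores["ps_score"] - scores["ns_score"]
    return scores


def correlate_with_resistance(scores: pd.DataFrame, resistance: pd.DataFrame,
                              min_cell_lines: int = 10) -> pd.DataFrame:
    """Per-drug Spearman correlation of PS/NS/diff scores vs resistance.

    ``resistance`` is cell lines x drugs; missing entries are dropped per
    drug (pairwise deletion).  Drugs with fewer than ``min_cell_lines``
    usable lines are skipped with a warning.  Returns a DataFrame indexed
    by drug with ``rho_ps``, ``p_ps``, ``rho_ns``, ``p_ns``, ``rho_diff``,
    ``p_diff`` and ``n_cell_lines``.
    """
    shared = scores.index.intersection(resistance.index)
    rows = {}
    for drug in resistance.columns:
        vals = resistance.loc[shared, drug].dropna()
        if len(vals) < min_cell_lines:
            warnings.warn(f"drug {drug!r}: only {len(vals)} cell lines "
                          f"(< {min_cell_lines}); skipped", stacklevel=2)
            continue
        sub = scores.loc[vals.index]
        row = {"n_cell_lines": len(vals)}
        for tag, col in (("ps", "ps_score"), ("ns", "ns_score"), ("diff", "diff_score")):
            res = stats.spearmanr(sub[col], vals)
            row[f"rho_{tag}"] = float(res.statistic)
            row[f"p_{tag}"] = float(res.pvalue)
        rows[drug] = row
    if not rows:
        raise EmptyResultError("no drug met the minimum cell-line count")
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Distribution summary of per-drug correlations for each score type.

    Per score type: median, first and third quartile of rho across drugs,
    plus a two-sided sign test of whether the median correlation differs
    from zero (drugs with rho exactly 0 excluded from the sign test).
    """
    if table.empty:
        raise ContractError("empty correlation table")
    rows = {}
    for tag in ("ps", "ns", "diff"):
        rho = table[f"rho_{tag}"].dropna()
        pos = int((rho > 0).sum())
        neg = int((rho < 0).sum())
        if pos + neg:
            sign_p = float(stats.binomtest(pos, pos + neg, 0.5).pvalue)
        else:
            sign_p = 1.0
        rows[tag] = {
            "median_rho": float(rho.median()),
            "q1_rho": float(rho.quantile(0.25)),
            "q3_rho": float(rho.quantile(0.75)),
            "n_drugs": int(len(rho)),
            "sign_test_p": sign_p,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
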