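"""Robust recurrent gene-expression signatures and their characterisation.

The dominant transcriptional axis of a gene x sample matrix is its first
eigenarray — the leading left singular vector of the sample-centred
matrix.  Each gene's entry is its *gene signature score*; genes with
positive scores (PS, growth program: ribosome biogenesis and friends) and
negative scores (NS, survival program: stress/catabolic genes) move in
opposition across samples.

Robustness is assessed by re-extracting the eigenarray under repeated
Gaussian perturbation of every expression value and keeping only genes
whose score sign never flips.  Signatures from independent datasets are
integrated by orienting them consistently, keeping sign-concordant genes
and averaging scores.

Two input dialects are handled:

* ``relative``  — two-colour log-ratio style data, already expressed
  relative to a reference; only sample-wise zero-centring is applied.
* ``absolute``  — count/intensity-scale data; gene-wise mean-centring
  precedes the sample-wise centring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, EmptyResultError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "RecurrentSignature",
    "GeneSet",
    "scale_samples",
    "center_genes",
    "first_eigenarray",
    "robust_signature",
    "integrate_datasets",
    "integrate_signatures",
    "split_ps_ns",
    "compare_signatures",
    "gene_set_score_distribution",
    "correlate_signature_with_measurement",
    "group_log2fc",
]

_SCALE_TOL = 1e-6


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with dialect and batch labels."""

    values: pd.DataFrame
    dialect: str = "relative"  # "relative" | "absolute"
    batch_label: pd.Series | None = None  # sample -> batch id

    def __post_init__(self) -> None:
        if self.dialect not in ("relative", "absolute"):
            raise ContractError(f"unknown dialect {self.dialect!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ContractError("gene and sample ids must be unique")

    @property
    def is_sample_scaled(self) -> bool:
        col_means = self.values.mean(axis=0)
        scale = max(1.0, float(np.abs(self.values.to_numpy()).max(initial=0.0)))
        return bool((col_means.abs() <= _SCALE_TOL * scale).all())


@dataclass
class GeneSet:
    name: str
    members: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ContractError(f"gene set {self.name!r} is empty")


@dataclass
class RecurrentSignature:
    """Per-gene scores from the first eigenarray plus a consistency mask."""

    score: pd.Series  # gene -> signature score (unit-norm vector entries)
    consistent: pd.Series  # gene -> sign stable across all perturbations
    n_iterations: int = 0
    noise_sd: float = 0.0
    source_tag: str = "other"

    def consistent_scores(self) -> pd.Series:
        return self.score[self.consistent]


def _as_em(matrix, dialect: str = "relative") -> ExpressionMatrix:
    if isinstance(matrix, ExpressionMatrix):
        return matrix
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(
        np.asarray(matrix, dtype=float))
    return ExpressionMatrix(values=df, dialect=dialect)


def scale_samples(matrix) -> ExpressionMatrix:
    """Zero-centre every sample column (no variance scaling)."""
    em = _as_em(matrix)
    if em.values.size == 0:
        raise ContractError("expression matrix is empty")
    if em.values.isna().values.any():
        raise ContractError("matrix has missing values; filter/impute first")
    centred = em.values - em.values.mean(axis=0)
    return ExpressionMatrix(values=centred, dialect=em.dialect,
                            batch_label=em.batch_label)


def center_genes(matrix) -> ExpressionMatrix:
    """Zero-centre every gene row (absolute-dialect data only).

    Relative-dialect data are already expressed against a reference and
    must not be re-centred per gene; calling this on them is an error.
    """
    em = matrix if isinstance(matrix, ExpressionMatrix) else _as_em(matrix, "absolute")
    if em.dialect != "absolute":
        raise ContractError("center_genes applies to absolute-dialect data only")
    if em.values.isna().values.any():
        raise ContractError("matrix has missing values; filter/impute first")
    centred = em.values.sub(em.values.mean(axis=1), axis=0)
    return ExpressionMatrix(values=centred, dialect="absolute",
                            batch_label=em.batch_label)


def _oriented_first_left_vector(values: np.ndarray):
    u, s, _ = np.linalg.svd(values, full_matrices=False)
    v = u[:, 0]
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    return v, s


def first_eigenarray(matrix) -> RecurrentSignature:
    """Unit-norm first left singular vector of a sample-scaled matrix.

    Sign-oriented so the gene with the largest absolute score is positive.
    A degenerate leading singular pair (s1 == s2 within 1e-9) makes the
    eigenarray non-identifiable and raises.
    """
    em = _as_em(matrix)
    if not em.is_sample_scaled:
        raise ContractError("matrix is not sample-scaled; call scale_samples first")
    v, s = _oriented_first_left_vector(em.values.to_numpy(dtype=float))
    if len(s) > 1 and s[0] - s[1] <= 1e-9:
        raise ContractError(
            f"degenerate leading singular values (s1={s[0]:.6g}, s2={s[1]:.6g}); "
            "the first eigenarray is not identifiable"
        )
    score = pd.Series(v, index=em.values.index, name="score")
    return RecurrentSignature(
        score=score,
        consistent=pd.Series(True, index=score.index, name="consistent"),
    )


def robust_signature(
    matrix,
    n_iterations: int = 1000,
    noise_mean: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    source_tag: str = "other",
) -> RecurrentSignature:
    """Noise-perturbed eigenarray with a sign-consistency mask.

    The unperturbed first eigenarray provides the reported score.  Per
    iteration, i.i.d. Gaussian noise is added to every expression value
    and the eigenarray re-extracted; it is oriented against the
    unperturbed vector (flip when their dot product is negative; flips are
    logged) and genes whose sign differs from the unperturbed sign in any
    iteration are marked inconsistent.
    """
    if n_iterations < 1:
        raise ContractError("n_iterations must be >= 1")
    em = _as_em(matrix)
    base = first_eigenarray(em)
    base_vec = base.score.to_numpy()
    base_sign = np.sign(base_vec)
    consistent = base_sign != 0

    rng = np.random.default_rng(seed)
    values = em.values.to_numpy(dtype=float)
    flips = 0
    for _ in range(n_iterations):
        noisy = values + rng.normal(noise_mean, noise_sd, size=values.shape)
        u, _, _ = np.linalg.svd(noisy, full_matrices=False)
        vec = u[:, 0]
        if vec @ base_vec < 0:
            vec = -vec
            flips += 1
        consistent &= np.sign(vec) == base_sign
    if flips:
        logger.info("robust_signature: re-oriented %d/%d perturbed eigenarrays",
                    flips, n_iterations)
    return RecurrentSignature(
        score=base.score,
        consistent=pd.Series(consistent, index=base.score.index, name="consistent"),
        n_iterations=n_iterations,
        noise_sd=noise_sd,
        source_tag=source_tag,
    )


def integrate_datasets(matrices: list) -> ExpressionMatrix:
    """Merge datasets on shared genes with per-batch gene centring.

    Genes are restricted to the intersection across all datasets, sample
    columns are concatenated, and within each source batch every gene row
    is mean-centred — a location-only batch adjustment that removes
    additive per-batch, per-gene offsets.  Samples keep (or receive) a
    batch label identifying their source dataset.
    """
    ems = [_as_em(m) for m in matrices]
    if len(ems) < 2:
        raise ContractError("need at least two datasets to integrate")
    genes = ems[0].values.index
    for em in ems[1:]:
        genes = genes.intersection(em.values.index)
    if len(genes) == 0:
        raise EmptyResultError("datasets share no genes")

    blocks, labels = [], []
    for b, em in enumerate(ems):
        sub = em.values.loc[genes]
        sub = sub.sub(sub.mean(axis=1), axis=0)  # per-batch gene centring
        tag = f"batch{b}"
        sub = sub.rename(columns=lambda c, t=tag: f"{t}:{c}")
        blocks.append(sub)
        labels.extend([tag] * sub.shape[1])
    merged = pd.concat(blocks, axis=1)
    return ExpressionMatrix(
        values=merged,
        dialect="relative",
        batch_label=pd.Series(labels, index=merged.columns, name="batch"),
    )


def _orient_pair(a: pd.Series, b: pd.Series):
    shared = a.index.intersection(b.index)
    if len(shared) < 2:
        raise ContractError("signatures share too few genes to orient")
    rho = stats.spearmanr(a.loc[shared], b.loc[shared]).statistic
    if np.isnan(rho) or abs(rho) < 0.05:
        raise ContractError(
            f"signature orientation is ambiguous (|rho| = {abs(rho):.3f} < 0.05)"
        )
    return (b if rho >= 0 else -b), shared


def integrate_signatures(sig_a: RecurrentSignature,
                         sig_b: RecurrentSignature) -> RecurrentSignature:
    """Combine two signatures into one integrated signature.

    Both are restricted to their consistent genes; the second is flipped
    if anti-correlated with the first; genes present in both with the
    same sign keep the mean of the two scores.  The result is re-oriented
    (largest-|score| gene positive) so integration is symmetric in its
    arguments.
    """
    a = sig_a.consistent_scores()
    b = sig_b.consistent_scores()
    if a.empty or b.empty:
        raise EmptyResultError("a signature has no consistent genes")
    b, shared = _orient_pair(a, b)
    a = a.loc[shared]
    b = b.loc[shared]
    same_sign = np.sign(a) == np.sign(b)
    kept = shared[same_sign.to_numpy()]
    if len(kept) == 0:
        raise EmptyResultError("no sign-concordant genes between the signatures")
    score = (a.loc[kept] + b.loc[kept]) / 2.0
    j = score.abs().idxmax()
    if score.loc[j] < 0:
        score = -score
    score = score.sort_index()
    return RecurrentSignature(
        score=score.rename("score"),
        consistent=pd.Series(True, index=score.index, name="consistent"),
        n_iterations=max(sig_a.n_iterations, sig_b.n_iterations),
        noise_sd=max(sig_a.noise_sd, sig_b.noise_sd),
        source_tag="integrated",
    )


def split_ps_ns(signature: RecurrentSignature) -> tuple[GeneSet, GeneSet]:
    """Split consistent genes into positive-score (PS) and negative-score
    (NS) sets; zero-score genes are excluded and logged."""
    scores = signature.consistent_scores()
    zeros = scores.index[scores == 0]
    if len(zeros):
        logger.info("split_ps_ns: excluding %d zero-score genes", len(zeros))
    ps = set(scores.index[scores > 0])
    ns = set(scores.index[scores < 0])
    if not ps or not ns:
        raise EmptyResultError("PS or NS side of the signature is empty")
    return (
        GeneSet("PS", frozenset(ps), "positive-score (growth program) genes"),
        GeneSet("NS", frozenset(ns), "negative-score (survival program) genes"),
    )


def compare_signatures(sig_a: RecurrentSignature, sig_b: RecurrentSignature,
                       min_shared: int = 10):
    """Spearman correlation between two signatures on shared genes."""
    a, b = sig_a.score, sig_b.score
    shared = a.index.intersection(b.index)
    if len(shared) < min_shared:
        raise ContractError(f"only {len(shared)} shared genes (< {min_shared})")
    res = stats.spearmanr(a.loc[shared], b.loc[shared])
    return float(res.statistic), float(res.pvalue)


def gene_set_score_distribution(signature: RecurrentSignature,
                                gene_sets: list[GeneSet]):
    """Score distributions per gene set plus pairwise rank-sum tests.

    Returns ``(distributions, tests)``: a dict mapping set name to the
    score vector of its member genes, and a DataFrame with two-sided
    Wilcoxon rank-sum statistics, raw p-values and Benjamini-Hochberg
    q-values for every set pair.  Sets with no gene in the signature are
    skipped with a warning.
    """
    distributions = {}
    for gs in gene_sets:
        members = signature.score.index.intersection(list(gs.members))
        if len(members) == 0:
            warnings.warn(f"gene set {gs.name!r} has no gene in the signature; skipped",
                          stacklevel=2)
            continue
        distributions[gs.name] = signature.score.loc[members]
    if not distributions:
        raise EmptyResultError("no gene set intersects the signature")

    names = list(distributions)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = stats.ranksums(distributions[names[i]], distributions[names[j]])
            rows.append((names[i], names[j], float(res.statistic), float(res.pvalue)))
    tests = pd.DataFrame(rows, columns=["set_a", "set_b", "statistic", "p"])
    if len(tests):
        tests["q"] = multipletests(tests["p"], method="fdr_bh")[1]
    return distributions, tests


def correlate_signature_with_measurement(signature: RecurrentSignature,
                                         measurement: pd.Series,
                                         min_shared: int = 10):
    """Spearman correlation of signature scores with a per-gene measurement."""
    meas = measurement.dropna()
    shared = signature.score.index.intersection(meas.index)
    if len(shared) < min_shared:
        raise ContractError(f"only {len(shared)} genes with both values (< {min_shared})")
    res = stats.spearmanr(signature.score.loc[shared], meas.loc[shared])
    return float(res.statistic), float(res.pvalue)


def group_log2fc(matrix, group_labels: pd.Series, gene_set: GeneSet,
                 pre_logged: bool = False) -> pd.Series:
    """Per-gene log2 fold change between two sample groups, over a gene set.

    On linear-scale data the value is ``log2(mean(g1) / mean(g2))``; with
    ``pre_logged`` it is the difference of group means (already log2).
    """
    em = _as_em(matrix, dialect="absolute")
    groups = group_labels.dropna()
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ContractError(f"need exactly 2 groups, got {levels}")
    cols1 = groups.index[groups == levels[0]].intersection(em.values.columns)
    cols2 = groups.index[groups == levels[1]].intersection(em.values.columns)
    if len(cols1) == 0 or len(cols2) == 0:
        raise ContractError("both groups must have samples in the matrix")
    genes = em.values.index.intersection(list(gene_set.members))
    if len(genes) == 0:
        raise EmptyResultError(f"gene set {gene_set.name!r} absent from the matrix")
    m1 = em.values.loc[genes, cols1].mean(axis=1)
    m2 = em.values.loc[genes, cols2].mean(axis=1)
    if pre_logged:
        return (m1 - m2).rename("log2fc")
    if (m1 <= 0).any() or (m2 <= 0).any():
        raise ContractError("non-positive group mean on linear scale; "
                            "use pre_logged for log-scale data")
    return np.log2(m1 / m2).rename("log2fc")
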