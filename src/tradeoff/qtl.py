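"""Overall-growth trait extraction and single-marker LOD linkage mapping.

The overall growth phenotype of a strain panel is its score on the first
principal component of the (condition-standardised) growth matrix, sign
oriented so the trait increases with mean growth.  Linkage of a biallelic
marker to the trait is scored as

    LOD = -n * ln(1 - r^2) / (2 * ln 10)

where ``r`` is the Pearson correlation between the 0/1 genotype column and
the trait over the ``n`` segregants.  This equals the log10 likelihood
ratio of the single-marker regression against the intercept-only model,
``(n/2) * log10(SS_tot / SS_res)``.  Genome-wide significance is assessed
by permuting the trait and taking an upper quantile of the per-permutation
maximum LOD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTrait",
    "LodScan",
    "overall_growth_pc1",
    "lod_score",
    "lod_scan",
    "permutation_threshold",
]

_LN10 = np.log(10.0)


@dataclass
class GenotypeTrait:
    """Segregant genotypes (0/1 parental origin), marker map and trait."""

    genotypes: pd.DataFrame  # segregants x markers in {0, 1}
    trait: pd.Series  # segregant -> trait value
    marker_pos: pd.DataFrame | None = None  # marker -> (chrom, pos)

    def __post_init__(self) -> None:
        g = self.genotypes
        if g.isna().values.any():
            raise ContractError("missing genotypes are not allowed; impute upstream")
        vals = g.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ContractError("genotypes must be coded 0/1 by parental origin")
        if not g.index.equals(self.trait.index):
            self.trait = self.trait.reindex(g.index)
            if self.trait.isna().any():
                raise ContractError("trait missing for some segregants")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]


@dataclass
class LodScan:
    lod: pd.Series  # marker -> LOD (NaN for skipped monomorphic markers)
    permutation_threshold: float | None = None
    n_permutations: int = 0


def overall_growth_pc1(phenome) -> pd.Series:
    """Strain scores on PC1 of a preprocessed growth matrix.

    The matrix must be complete and condition-standardised (correlation
    PCA).  The sign is chosen so the scores correlate non-negatively
    (Spearman) with per-strain mean growth.
    """
    df = phenome.values if hasattr(phenome, "values") and isinstance(
        getattr(phenome, "values"), pd.DataFrame) else pd.DataFrame(phenome)
    if df.shape[1] < 2:
        raise ContractError("need at least 2 conditions for PCA")
    if df.isna().values.any():
        raise ContractError("phenome must be imputed before PCA")
    x = df.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, 0] * s[0]
    row_mean = df.mean(axis=1).to_numpy()
    if np.ptp(row_mean) > 0:
        rho = stats.spearmanr(scores, row_mean).statistic
        if not np.isnan(rho) and rho < 0:
            scores = -scores
    return pd.Series(scores, index=df.index, name="pc1")


def lod_score(genotype_column, trait) -> float:
    """LOD for one biallelic marker: ``-n ln(1 - r^2) / (2 ln 10)``."""
    g = np.asarray(genotype_column, dtype=float)
    y = np.asarray(trait, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ContractError("genotype and trait must be equal-length vectors")
    if np.ptp(g) == 0:
        raise ContractError("monomorphic marker: correlation undefined")
    if np.ptp(y) == 0:
        raise ContractError("constant trait: correlation undefined")
    n = g.size
    r = np.corrcoef(g, y)[0, 1]
    r2 = min(r * r, 1.0)
    if r2 == 1.0:
        return float("inf")
    return float(-n * np.log1p(-r2) / (2.0 * _LN10))


def _correlations(G: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between every genotype column and every trait column."""
    Gc = G - G.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    gs = np.sqrt((Gc**2).sum(axis=0))
    ys = np.sqrt((Yc**2).sum(axis=0))
    return (Gc.T @ Yc) / np.outer(gs, ys)


def lod_scan(gt: GenotypeTrait) -> LodScan:
    """LOD at every marker; monomorphic markers are skipped (NaN, logged)."""
    G = gt.genotypes.to_numpy(dtype=float)
    y = gt.trait.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ContractError("constant trait")
    poly = np.ptp(G, axis=0) > 0
    if not poly.any():
        raise ContractError("all markers are monomorphic")
    n_skip = int((~poly).sum())
    if n_skip:
        logger.warning("lod_scan: skipping %d monomorphic markers", n_skip)
    n = gt.n
    r = _correlations(G[:, poly], y[:, None])[:, 0]
    r2 = np.minimum(r * r, 1.0)
    with np.errstate(divide="ignore"):
        lod_vals = -n * np.log1p(-r2) / (2.0 * _LN10)
    lod = pd.Series(np.nan, index=gt.genotypes.columns, name="lod")
    lod.iloc[np.where(poly)[0]] = lod_vals
    return LodScan(lod=lod)


def permutation_threshold(
    gt: GenotypeTrait,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Genome-wide LOD threshold from trait permutations.

    The trait is permuted across segregants ``n_permutations`` times; each
    permutation records its maximum LOD over all polymorphic markers and
    the threshold is the empirical (1 - alpha) quantile of those maxima.
    ``alpha = 1`` is allowed and returns the minimum of the distribution.
    """
    if not 0 < alpha <= 1:
        raise ContractError("alpha must lie in (0, 1]")
    if n_permutations < 100:
        raise ContractError("need at least 100 permutations")
    G = gt.genotypes.to_numpy(dtype=float)
    y = gt.trait.to_numpy(dtype=float)
    poly = np.ptp(G, axis=0) > 0
    if not poly.any():
        raise ContractError("all markers are monomorphic")
    G = G[:, poly]
    rng = np.random.default_rng(seed)
    n = gt.n
    perms = np.empty((n, n_permutations))
    for p in range(n_permutations):
        perms[:, p] = y[rng.permutation(n)]
    R = _correlations(G, perms)
    r2 = np.minimum(R * R, 1.0)
    with np.errstate(divide="ignore"):
        lods = -n * np.log1p(-r2) / (2.0 * _LN10)
    max_lod = lods.max(axis=0)
    return float(np.quantile(max_lod, 1.0 - alpha))
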