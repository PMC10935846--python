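"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its integer seed (identical seed gives
bit-identical output) and returns both the data matrix the pipeline would
read from disk and the planted truth needed to verify recovery.  Pipeline
stages never see the truth objects; they consume only the data members (or
the TSV files written by :mod:`tradeoff.io`).

The generators emulate the structure of the real study inputs:

* ``gen_phenome``     — a strains x conditions growth matrix whose
  conditions split into two anti-correlated blocks (growth-favouring vs
  stress-resisting), driven by a latent per-strain trade-off axis.
* ``gen_expression``  — a genes x samples matrix dominated by one rank-1
  mutually-exclusive two-arm signature, plus per-batch offsets.
* ``gen_cross``       — a biallelic segregant cross with additive QTL
  effects on a quantitative trait.
* ``gen_network``     — a confidence-scored gene network containing one
  planted connected module, plus gene genomic intervals.
* ``gen_drug_panel``  — cell-line expression and drug-resistance tables in
  which resistance tracks the NS-arm (stress/survival) expression score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = [
    "PlantedPhenome",
    "PlantedExpression",
    "PlantedCross",
    "PlantedNetwork",
    "PlantedDrugPanel",
    "gen_phenome",
    "gen_expression",
    "gen_cross",
    "gen_network",
    "gen_drug_panel",
    "gen_locus_pvalues",
]

CLADES = ("wild", "domesticated", "unassigned")


@dataclass
class PlantedPhenome:
    """A growth phenome with two planted anti-correlated condition blocks."""

    matrix: pd.DataFrame  # strains x conditions, NaN where missing
    block_assignment: pd.Series  # condition -> "A" | "B"
    clade_label: pd.Series  # strain -> wild | domesticated | unassigned
    strain_axis: pd.Series  # strain -> latent trade-off position
    missing_mask: pd.DataFrame  # boolean, True where the cell is missing

    def truth_dict(self) -> dict:
        return {
            "block_assignment": self.block_assignment.to_dict(),
            "clade_label": self.clade_label.to_dict(),
            "strain_axis": self.strain_axis.to_dict(),
            "n_missing": int(self.missing_mask.values.sum()),
        }


@dataclass
class PlantedExpression:
    """An expression matrix with one planted two-arm rank-1 signature."""

    matrix: pd.DataFrame  # genes x samples
    true_signature: pd.Series  # gene -> planted score (zero-centered)
    batch_label: pd.Series  # sample -> batch id
    dialect: str  # "relative" | "absolute"

    def truth_dict(self) -> dict:
        return {
            "true_signature": self.true_signature.to_dict(),
            "batch_label": self.batch_label.to_dict(),
            "dialect": self.dialect,
        }


@dataclass
class PlantedCross:
    """A haploid segregant cross with planted additive QTL effects."""

    genotypes: pd.DataFrame  # segregants x markers, entries in {0,1}
    marker_pos: pd.DataFrame  # marker -> (chrom, pos), 1-based
    qtl_markers: list  # [(marker_id, effect in residual-SD units), ...]
    trait: pd.Series  # segregant -> trait value

    def truth_dict(self) -> dict:
        return {"qtl_markers": [[m, float(e)] for m, e in self.qtl_markers]}


@dataclass
class PlantedNetwork:
    """A scored gene network with one planted dense connected module."""

    edges: pd.DataFrame  # columns gene_a, gene_b, confidence
    module_genes: set
    gene_intervals: pd.DataFrame  # gene -> (chrom, start, end), 1-based incl.

    def truth_dict(self) -> dict:
        return {"module_genes": sorted(self.module_genes)}


@dataclass
class PlantedDrugPanel:
    """Cell-line expression plus resistance driven by the NS-PS balance."""

    expression: pd.DataFrame  # genes x cell lines
    resistance: pd.DataFrame  # cell lines x drugs (Z-score scale)
    ns_genes: set
    ps_genes: set
    planted_effect: float
    cell_axis: pd.Series = field(default=None)  # latent growth axis per line

    def truth_dict(self) -> dict:
        return {
            "ns_genes": sorted(self.ns_genes),
            "ps_genes": sorted(self.ps_genes),
            "planted_effect": self.planted_effect,
        }


def gen_phenome(
    n_strains: int,
    n_conditions: int,
    block_sizes: tuple[int, int],
    tradeoff_strength: float = 5.0,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> PlantedPhenome:
    """Generate a two-block trade-off phenome.

    Each strain draws a latent axis value ``a_s ~ N(0, 1)``; a cell value is
    ``+tradeoff_strength * a_s`` for block-A conditions and
    ``-tradeoff_strength * a_s`` for block-B conditions, plus
    ``N(0, noise_sd^2)`` noise.  A fraction ``missing_rate`` of cells
    (rounded to the nearest count) is blanked uniformly at random.

    Clade labels are drawn with a mild tilt along the axis (strains on the
    stress-resistant side are more often "wild"), so that downstream
    cluster-composition tests have signal to find.
    """
    if n_strains <= 0 or n_conditions <= 0:
        raise ContractError("matrix dimensions must be positive")
    if len(block_sizes) != 2 or min(block_sizes) < 1:
        raise ContractError("both condition blocks must be nonempty")
    if sum(block_sizes) != n_conditions:
        raise ContractError("block_sizes must sum to n_conditions")
    if not 0 <= missing_rate < 1:
        raise ContractError("missing_rate must lie in [0, 1)")
    if tradeoff_strength < 0:
        raise ContractError("tradeoff_strength must be >= 0")

    rng = np.random.default_rng(seed)
    strains = [f"strain{i:04d}" for i in range(n_strains)]
    conditions = [f"cond{j:02d}" for j in range(n_conditions)]
    blocks = np.array(["A"] * block_sizes[0] + ["B"] * block_sizes[1])
    sign = np.where(blocks == "A", 1.0, -1.0)

    axis = rng.standard_normal(n_strains)
    values = tradeoff_strength * np.outer(axis, sign)
    values = values + rng.normal(0.0, noise_sd, size=values.shape)

    # wild strains sit preferentially on the stress-resistant (negative) side
    clades = np.empty(n_strains, dtype=object)
    for i, a in enumerate(axis):
        p = (0.2, 0.6, 0.2) if a > 0 else (0.6, 0.2, 0.2)
        clades[i] = rng.choice(CLADES, p=p)

    n_cells = n_strains * n_conditions
    n_missing = int(round(missing_rate * n_cells))
    mask = np.zeros(n_cells, dtype=bool)
    if n_missing:
        mask[rng.choice(n_cells, size=n_missing, replace=False)] = True
    mask = mask.reshape(n_strains, n_conditions)
    values = np.where(mask, np.nan, values)

    return PlantedPhenome(
        matrix=pd.DataFrame(values, index=strains, columns=conditions),
        block_assignment=pd.Series(blocks, index=conditions),
        clade_label=pd.Series(clades, index=strains),
        strain_axis=pd.Series(axis, index=strains),
        missing_mask=pd.DataFrame(mask, index=strains, columns=conditions),
    )


def gen_expression(
    n_genes: int,
    n_samples: int,
    signature_sd: float = 3.0,
    noise_sd: float = 0.5,
    n_batches: int = 1,
    batch_sd: float = 0.0,
    dialect: str = "relative",
    seed: int = 0,
) -> PlantedExpression:
    """Generate an expression matrix with one planted rank-1 signature.

    Sample activities ``t_j ~ N(0,1)`` and gene scores
    ``g_i ~ N(0, signature_sd^2)`` (re-centred to mean zero) combine as
    ``value_ij = g_i * t_j + batch_offset_(b(j), i) + N(0, noise_sd^2)``.
    Batch offsets are per (batch, gene) with SD ``batch_sd``; samples are
    split into ``n_batches`` contiguous, near-equal batches.  For the
    ``absolute`` dialect a positive per-gene baseline (uniform on [5, 15])
    is added, mimicking intensity/count-scale data.
    """
    if n_genes < 2 or n_samples < 2:
        raise ContractError("need at least 2 genes and 2 samples")
    if dialect not in ("relative", "absolute"):
        raise ContractError(f"unknown dialect {dialect!r}")
    if n_batches < 1:
        raise ContractError("n_batches must be >= 1")

    rng = np.random.default_rng(seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    samples = [f"sample{j:04d}" for j in range(n_samples)]

    t = rng.standard_normal(n_samples)
    g = rng.normal(0.0, signature_sd, size=n_genes) if signature_sd > 0 else np.zeros(n_genes)
    g = g - g.mean()  # planted signature is zero-centered by construction

    batch_ids = np.array_split(np.arange(n_samples), n_batches)
    batch_label = np.empty(n_samples, dtype=object)
    values = np.outer(g, t)
    for b, cols in enumerate(batch_ids):
        batch_label[cols] = f"batch{b}"
        if batch_sd > 0:
            offs = rng.normal(0.0, batch_sd, size=n_genes)
            values[:, cols] += offs[:, None]
    values = values + rng.normal(0.0, noise_sd, size=values.shape)
    if dialect == "absolute":
        baseline = rng.uniform(5.0, 15.0, size=n_genes)
        values = values + baseline[:, None]

    return PlantedExpression(
        matrix=pd.DataFrame(values, index=genes, columns=samples),
        true_signature=pd.Series(g, index=genes),
        batch_label=pd.Series(batch_label, index=samples),
        dialect=dialect,
    )


def gen_cross(
    n_segregants: int,
    n_markers: int,
    qtl: list[tuple[int, float]] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PlantedCross:
    """Generate an unlinked biallelic segregant cross with additive QTL.

    Genotypes at every marker are independent fair coin flips (0/1 parental
    origin).  The trait is ``sum_m effect_m * (genotype_m - 0.5)`` plus
    ``N(0, noise_sd^2)`` noise, so with the default ``noise_sd = 1`` an
    effect is the between-allele trait shift in residual-SD units.
    """
    if n_segregants <= 0 or n_markers <= 0:
        raise ContractError("cross dimensions must be positive")
    qtl = list(qtl or [])
    for m, _ in qtl:
        if not 0 <= m < n_markers:
            raise ContractError(f"QTL marker index {m} out of range")

    rng = np.random.default_rng(seed)
    segs = [f"seg{i:04d}" for i in range(n_segregants)]
    markers = [f"m{j:05d}" for j in range(n_markers)]

    geno = rng.integers(0, 2, size=(n_segregants, n_markers))
    trait = rng.normal(0.0, noise_sd, size=n_segregants)
    for m, eff in qtl:
        trait = trait + eff * (geno[:, m] - 0.5)

    marker_pos = pd.DataFrame(
        {"chrom": "chr1", "pos": 1 + 1000 * np.arange(n_markers)},
        index=markers,
    )
    return PlantedCross(
        genotypes=pd.DataFrame(geno, index=segs, columns=markers),
        marker_pos=marker_pos,
        qtl_markers=[(markers[m], eff) for m, eff in qtl],
        trait=pd.Series(trait, index=segs),
    )


def gen_network(
    n_genes: int,
    module_size: int = 10,
    background_p: float = 0.001,
    module_confidence: float = 0.9,
    background_confidence: float = 0.2,
    seed: int = 0,
) -> PlantedNetwork:
    """Generate a scored network with one planted connected module.

    The module genes are wired as a random spanning tree plus extra edges
    (each remaining module pair with probability 0.3) at
    ``module_confidence``; background edges are Erdos-Renyi at
    ``background_p`` with ``background_confidence``.  Gene intervals tile a
    single synthetic chromosome: gene ``i`` spans
    ``[1 + 2000*i, 1000 + 2000*i]`` (1-based inclusive, 1 kb genes spaced
    1 kb apart), so locus-gene intersections are deterministic.
    """
    if module_size > n_genes:
        raise ContractError("module_size cannot exceed n_genes")
    for c in (module_confidence, background_confidence):
        if not 0 <= c <= 1:
            raise ContractError("confidences must lie in [0, 1]")
    if module_size >= 2 and module_confidence <= 0.4:
        warnings.warn(
            "module_confidence <= 0.4: the planted module will vanish at the "
            "standard medium-confidence threshold",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:04d}" for i in range(n_genes)])
    module_idx = rng.choice(n_genes, size=module_size, replace=False)
    module = set(genes[module_idx])

    rows = []
    # spanning tree over the module guarantees connectivity
    order = rng.permutation(module_idx)
    tree_pairs = set()
    for k in range(1, len(order)):
        parent = order[rng.integers(0, k)]
        a, b = sorted((genes[order[k]], genes[parent]))
        tree_pairs.add((a, b))
        rows.append((a, b, module_confidence))
    if module_size >= 2:
        mod_sorted = sorted(module)
        for i in range(len(mod_sorted)):
            for j in range(i + 1, len(mod_sorted)):
                pair = (mod_sorted[i], mod_sorted[j])
                if pair not in tree_pairs and rng.random() < 0.3:
                    rows.append((*pair, module_confidence))
                    tree_pairs.add(pair)

    if background_p > 0:
        # vectorized ER sampling over all non-module pairs
        iu, ju = np.triu_indices(n_genes, k=1)
        hit = rng.random(iu.size) < background_p
        for i, j in zip(iu[hit], ju[hit]):
            a, b = sorted((genes[i], genes[j]))
            if (a, b) not in tree_pairs:
                rows.append((a, b, background_confidence))

    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])
    starts = 1 + 2000 * np.arange(n_genes)
    gene_intervals = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 999}, index=genes
    )
    return PlantedNetwork(edges=edges, module_genes=module, gene_intervals=gene_intervals)


def gen_drug_panel(
    n_genes: int,
    n_cell_lines: int,
    n_drugs: int,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> PlantedDrugPanel:
    """Generate a cell-line panel where resistance tracks NS expression.

    A latent per-line growth axis ``u_c ~ N(0,1)`` drives expression:
    PS (growth-program) genes get ``+u_c``, NS (survival-program) genes get
    ``-u_c``, background genes are pure noise.  Resistance for every drug is
    ``effect * (NS_score - PS_score) + N(0, noise_sd^2)`` where the true
    scores are the noiseless arm means, so higher NS expression implies
    higher resistance.  PS/NS sets are disjoint halves of a 20% signature
    gene pool (at least one gene each).
    """
    if n_drugs < 1:
        raise ContractError("n_drugs must be >= 1")
    if effect < 0:
        raise ContractError("effect must be >= 0")
    if n_genes < 2:
        raise ContractError("need at least 2 genes for a PS and an NS arm")

    rng = np.random.default_rng(seed)
    genes = [f"hgene{i:04d}" for i in range(n_genes)]
    lines = [f"cell{c:03d}" for c in range(n_cell_lines)]
    drugs = [f"drug{d:03d}" for d in range(n_drugs)]

    pool = max(2, int(round(0.2 * n_genes)) // 2 * 2)  # even, >= 2
    ps = set(genes[: pool // 2])
    ns = set(genes[pool // 2 : pool])

    u = rng.standard_normal(n_cell_lines)
    direction = np.zeros(n_genes)
    direction[: pool // 2] = 1.0
    direction[pool // 2 : pool] = -1.0
    expr = np.outer(direction, u) + rng.normal(0.0, noise_sd, size=(n_genes, n_cell_lines))

    # true scores are the noiseless arm means: +u (PS) and -u (NS)
    resist = effect * (-u - u)[:, None] + rng.normal(
        0.0, noise_sd, size=(n_cell_lines, n_drugs)
    )
    return PlantedDrugPanel(
        expression=pd.DataFrame(expr, index=genes, columns=lines),
        resistance=pd.DataFrame(resist, index=lines, columns=drugs),
        ns_genes=ns,
        ps_genes=ps,
        planted_effect=effect,
        cell_axis=pd.Series(u, index=lines),
    )


def gen_locus_pvalues(
    network: PlantedNetwork,
    low_p_scale: float = 1e-5,
    seed: int = 0,
) -> pd.DataFrame:
    """Demo plumbing: association loci over the synthetic genome.

    Emits one locus per gene covering the gene body; module genes receive
    small p-values (uniform scaled by ``low_p_scale``), background genes
    uniform p-values.  This mimics the locus-level output of an external
    genome-wide association scan so the locus-to-gene mapping and the
    connectedness test can run end to end on synthetic data.
    """
    rng = np.random.default_rng(seed)
    iv = network.gene_intervals
    p = rng.uniform(size=len(iv))
    in_module = iv.index.isin(network.module_genes)
    p = np.where(in_module, p * low_p_scale, p)
    return pd.DataFrame(
        {"chrom": iv["chrom"].values, "start": iv["start"].values,
         "end": iv["end"].values, "p": p}
    )
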