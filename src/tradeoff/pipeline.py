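"""End-to-end orchestration of the synthetic demo pipeline.

``run_pipeline`` generates every synthetic input, writes them as the
plain-text formats the stages read, then executes the analysis stages in
dependency order (phenome -> qtl -> network; signature -> drugscore) from
the files alone — planted-truth JSON files are written next to the inputs
but never read back by any stage.  A manifest records per-stage inputs,
outputs, checksums and wall time.

All randomness flows from the single configured seed; each stage derives
its own stream as ``(seed + crc32(stage_name)) % 2**31`` so adding a stage
never perturbs the streams of existing stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import drugscore as ds
from . import io as tio
from . import network as net
from . import phenome as ph
from . import qtl
from . import signature as sg
from . import synthetic as syn
from .errors import ContractError

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: (seed + crc32(stage)) mod 2^31."""
    return (int(seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Resolved parameters for a full synthetic demo run."""

    seed: int = 0
    out_dir: str = "tradeoff_run"
    # phenome generation + analysis
    n_strains: int = 200
    n_conditions: int = 20
    block_sizes: tuple[int, int] = (10, 10)
    tradeoff_strength: float = 5.0
    phenome_noise_sd: float = 0.5
    missing_rate: float = 0.05
    rank: int = 2
    k_min: int = 2
    k_max: int = 6
    consensus_iterations: int = 200
    resample_fraction: float = 0.8
    # expression generation + signature extraction
    n_genes: int = 500
    n_samples: int = 100
    signature_sd: float = 3.0
    expression_noise_sd: float = 0.5
    n_batches: int = 2
    batch_sd: float = 2.0
    signature_iterations: int = 100
    signature_noise_sd: float = 1.0
    # cross generation + linkage
    n_segregants: int = 500
    n_markers: int = 200
    qtl_effect: float = 1.0
    qtl_marker: int = 100
    trait_noise_sd: float = 1.0
    n_permutations: int = 200
    alpha: float = 0.05
    # network generation + connectedness test
    net_genes: int = 1000
    module_size: int = 10
    background_p: float = 0.001
    module_confidence: float = 0.9
    background_confidence: float = 0.2
    lcc_iterations: int = 200
    min_confidence: float = 0.4
    aggregation: str = "fisher"
    coords: str = "one"
    # drug panel
    panel_genes: int = 200
    n_cell_lines: int = 50
    n_drugs: int = 20
    drug_effect: float = 2.0
    drug_noise_sd: float = 0.5
    min_cell_lines: int = 10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block_sizes"] = list(self.block_sizes)
        return d

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ContractError(f"unknown config keys: {sorted(unknown)}")
        if "block_sizes" in raw:
            raw["block_sizes"] = tuple(raw["block_sizes"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self) -> None:
        self.stages: list[dict] = []

    def record(self, stage: str, inputs: list[Path], outputs: list[Path],
               wall_time: float) -> None:
        self.stages.append({
            "stage": stage,
            "inputs": [str(p) for p in inputs],
            "outputs": {str(p): _sha256(p) for p in outputs},
            "wall_time_s": round(wall_time, 3),
        })

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=1)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic demo; returns a summary dict.

    Raises before any stage runs if the output directory cannot be
    created.  Stage contract violations propagate with the stage name.
    """
    out = Path(config.out_dir)
    inputs_dir = out / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    manifest = _Manifest()
    summary: dict = {"seed": config.seed}

    # ---- synth: generate and write every input --------------------------
    t0 = time.perf_counter()
    phen = syn.gen_phenome(
        config.n_strains, config.n_conditions, tuple(config.block_sizes),
        tradeoff_strength=config.tradeoff_strength,
        noise_sd=config.phenome_noise_sd, missing_rate=config.missing_rate,
        seed=stage_seed(config.seed, "phenome"),
    )
    expr = syn.gen_expression(
        config.n_genes, config.n_samples, signature_sd=config.signature_sd,
        noise_sd=config.expression_noise_sd, n_batches=config.n_batches,
        batch_sd=config.batch_sd, dialect="relative",
        seed=stage_seed(config.seed, "expression"),
    )
    cross = syn.gen_cross(
        config.n_segregants, config.n_markers,
        qtl=[(config.qtl_marker, config.qtl_effect)],
        noise_sd=config.trait_noise_sd, seed=stage_seed(config.seed, "cross"),
    )
    network = syn.gen_network(
        config.net_genes, module_size=config.module_size,
        background_p=config.background_p,
        module_confidence=config.module_confidence,
        background_confidence=config.background_confidence,
        seed=stage_seed(config.seed, "network"),
    )
    loci = syn.gen_locus_pvalues(network, seed=stage_seed(config.seed, "loci"))
    panel = syn.gen_drug_panel(
        config.panel_genes, config.n_cell_lines, config.n_drugs,
        effect=config.drug_effect, noise_sd=config.drug_noise_sd,
        seed=stage_seed(config.seed, "drugpanel"),
    )

    files = {
        "phenome": inputs_dir / "phenome.tsv",
        "clades": inputs_dir / "clades.tsv",
        "expression": inputs_dir / "expression.tsv",
        "batches": inputs_dir / "batches.tsv",
        "genotypes": inputs_dir / "genotypes.tsv",
        "markers": inputs_dir / "markers.tsv",
        "trait": inputs_dir / "trait.tsv",
        "edges": inputs_dir / "network.tsv",
        "gene_intervals": inputs_dir / "gene_intervals.tsv",
        "loci": inputs_dir / "locus_pvalues.tsv",
        "panel_expr": inputs_dir / "panel_expression.tsv",
        "resistance": inputs_dir / "resistance.tsv",
        "panel_sets": inputs_dir / "panel_gene_sets.txt",
    }
    tio.write_matrix(phen.matrix, files["phenome"])
    tio.write_series(phen.clade_label, files["clades"], name="clade")
    tio.write_matrix(expr.matrix, files["expression"])
    tio.write_series(expr.batch_label, files["batches"], name="batch")
    tio.write_matrix(cross.genotypes, files["genotypes"])
    tio.write_intervals(cross.marker_pos.assign(start=cross.marker_pos["pos"],
                                                end=cross.marker_pos["pos"])
                        [["chrom", "start", "end"]], files["markers"],
                        id_label="marker")
    tio.write_series(cross.trait, files["trait"], name="trait")
    tio.write_edge_list(network.edges, files["edges"])
    tio.write_intervals(network.gene_intervals, files["gene_intervals"],
                        id_label="gene")
    tio.write_locus_pvalues(loci, files["loci"])
    tio.write_matrix(panel.expression, files["panel_expr"])
    tio.write_matrix(panel.resistance, files["resistance"])
    tio.write_gene_sets(
        [sg.GeneSet("PS", frozenset(panel.ps_genes), "planted growth arm"),
         sg.GeneSet("NS", frozenset(panel.ns_genes), "planted survival arm")],
        files["panel_sets"],
    )
    for name, obj in (("phenome", phen), ("expression", expr), ("cross", cross),
                      ("network", network), ("drugpanel", panel)):
        tio.write_truth(obj.truth_dict(), inputs_dir / f"{name}.truth.json")
    manifest.record("synth", [], sorted(files.values()), time.perf_counter() - t0)

    # ---- phenome stage --------------------------------------------------
    t0 = time.perf_counter()
    pdir = out / "phenome"
    raw = tio.read_matrix(files["phenome"])
    filtered = ph.filter_missing(raw)
    imputed = ph.impute_knn(filtered)
    standardized = ph.standardize_conditions(imputed)
    recon = ph.svd_reconstruct(standardized, rank=config.rank)
    corr = ph.condition_correlation(recon.values)
    cons = ph.consensus_cluster(
        recon.values, K_range=range(config.k_min, config.k_max + 1),
        n_iterations=config.consensus_iterations,
        resample_fraction=config.resample_fraction,
        seed=stage_seed(config.seed, "consensus"),
    )
    tio.write_matrix(recon.values, pdir / "reconstructed.tsv")
    tio.write_matrix(corr, pdir / "correlation.tsv")
    outs = [pdir / "reconstructed.tsv", pdir / "correlation.tsv"]
    for k, cm in cons.consensus.items():
        p = pdir / f"consensus_K{k}.tsv"
        tio.write_matrix(cm, p)
        outs.append(p)
    pac_tsv = pd.DataFrame({"K": list(cons.pac_values),
                            "PAC": list(cons.pac_values.values())})
    tio.write_matrix(pac_tsv.set_index("K"), pdir / "pac.tsv")
    best_k = cons.optimal_k()
    clusters = cons.assignments[best_k[0]].assignment
    tio.write_series(clusters, pdir / "condition_clusters.tsv", name="cluster")
    outs += [pdir / "pac.tsv", pdir / "condition_clusters.tsv"]

    # strain clustering vs clade composition
    strain_dist = pd.DataFrame(
        ph._spearman_distance(recon.values.T.to_numpy()),
        index=recon.values.index, columns=recon.values.index)
    strain_clusters = ph.hcluster(strain_dist, K=2).assignment
    clades = tio.read_series(files["clades"])
    chi2, dof, pval = ph.cluster_composition_test(strain_clusters, clades)
    comp = {"chi2": chi2, "dof": dof, "p": pval}
    with open(pdir / "composition_test.json", "w") as fh:
        json.dump(comp, fh, indent=1)
    outs.append(pdir / "composition_test.json")
    summary["phenome"] = {"optimal_k": best_k, "pac": cons.pac_values,
                          "composition_test": comp}
    manifest.record("phenome", [files["phenome"], files["clades"]], outs,
                    time.perf_counter() - t0)

    # ---- qtl stage ------------------------------------------------------
    t0 = time.perf_counter()
    qdir = out / "qtl"
    qdir.mkdir(parents=True, exist_ok=True)
    pc1 = qtl.overall_growth_pc1(standardized)
    tio.write_series(pc1, qdir / "pc1.tsv", name="pc1")
    genotypes = tio.read_matrix(files["genotypes"])
    trait = tio.read_series(files["trait"])
    markers = tio.read_intervals(files["markers"], coords=config.coords)
    gt = qtl.GenotypeTrait(genotypes=genotypes, trait=trait, marker_pos=markers)
    scan = qtl.lod_scan(gt)
    thr = qtl.permutation_threshold(
        gt, alpha=config.alpha, n_permutations=config.n_permutations,
        seed=stage_seed(config.seed, "permutation"),
    )
    scan_tsv = markers.join(scan.lod)
    tio.write_matrix(scan_tsv, qdir / "lod_scan.tsv")
    with open(qdir / "threshold.json", "w") as fh:
        json.dump({"alpha": config.alpha, "threshold": thr,
                   "n_permutations": config.n_permutations}, fh, indent=1)
    peak = scan.lod.idxmax()
    summary["qtl"] = {"peak_marker": str(peak),
                      "peak_lod": float(scan.lod.max()),
                      "threshold": thr}
    manifest.record("qtl", [files["genotypes"], files["trait"], files["markers"]],
                    [qdir / "pc1.tsv", qdir / "lod_scan.tsv", qdir / "threshold.json"],
                    time.perf_counter() - t0)

    # ---- network stage --------------------------------------------------
    t0 = time.perf_counter()
    ndir = out / "network"
    ndir.mkdir(parents=True, exist_ok=True)
    edges = tio.read_edge_list(files["edges"])
    gene_iv = tio.read_intervals(files["gene_intervals"], coords=config.coords)
    loci_df = tio.read_locus_pvalues(files["loci"], coords=config.coords)
    gene_p = net.gene_pvalue_from_loci(loci_df, gene_iv)
    agg = net.aggregate_pvalues([gene_p], method=config.aggregation)
    gnet = net.GeneNetwork(edges)
    k_sel = min(config.module_size * 2, len(agg))
    ranked = net.top_genes(agg, k=k_sel)
    obs = net.lcc_size(gnet, ranked, min_confidence=config.min_confidence)
    test = net.lcc_null_test(
        gnet, len(ranked), obs, n_iterations=config.lcc_iterations,
        min_confidence=config.min_confidence,
        seed=stage_seed(config.seed, "lcc"),
    )
    curve = net.lcc_size_curve(
        gnet, ranked, k_grid=sorted({max(2, k_sel // 2), k_sel}),
        n_iterations=config.lcc_iterations,
        min_confidence=config.min_confidence,
        seed=stage_seed(config.seed, "lcc_curve"),
    )
    tio.write_matrix(curve, ndir / "lcc_curve.tsv")
    with open(ndir / "lcc_test.json", "w") as fh:
        json.dump(dataclasses.asdict(test), fh, indent=1)
    summary["network"] = {"observed_lcc": obs, "empirical_p": test.empirical_p}
    manifest.record("network",
                    [files["edges"], files["gene_intervals"], files["loci"]],
                    [ndir / "lcc_curve.tsv", ndir / "lcc_test.json"],
                    time.perf_counter() - t0)

    # ---- signature stage ------------------------------------------------
    t0 = time.perf_counter()
    sdir = out / "signature"
    expr_df = tio.read_matrix(files["expression"])
    batches = tio.read_series(files["batches"])
    parts = [sg.ExpressionMatrix(expr_df.loc[:, batches.index[batches == b]])
             for b in sorted(batches.unique())]
    integrated = parts[0] if len(parts) == 1 else sg.integrate_datasets(parts)
    scaled = sg.scale_samples(integrated)
    sig = sg.robust_signature(
        scaled, n_iterations=config.signature_iterations,
        noise_sd=config.signature_noise_sd,
        seed=stage_seed(config.seed, "signature"),
    )
    ps, ns = sg.split_ps_ns(sig)
    sig_tsv = pd.DataFrame({"score": sig.score, "consistent": sig.consistent})
    tio.write_matrix(sig_tsv, sdir / "signature.tsv")
    tio.write_gene_sets([ps, ns], sdir / "ps_ns_sets.txt")
    summary["signature"] = {
        "n_consistent": int(sig.consistent.sum()),
        "n_ps": len(ps.members), "n_ns": len(ns.members),
    }
    manifest.record("signature", [files["expression"], files["batches"]],
                    [sdir / "signature.tsv", sdir / "ps_ns_sets.txt"],
                    time.perf_counter() - t0)

    # ---- drugscore stage ------------------------------------------------
    t0 = time.perf_counter()
    ddir = out / "drugscore"
    ddir.mkdir(parents=True, exist_ok=True)
    panel_expr = tio.read_matrix(files["panel_expr"])
    resistance = tio.read_matrix(files["resistance"])
    sets = {s.name: s for s in tio.read_gene_sets(files["panel_sets"])}
    scores = ds.score_cell_lines(panel_expr, sets["PS"], sets["NS"])
    corr_table = ds.correlate_with_resistance(scores, resistance,
                                              min_cell_lines=config.min_cell_lines)
    summ = ds.summarize_correlations(corr_table)
    tio.write_matrix(scores, ddir / "cell_line_scores.tsv")
    tio.write_matrix(corr_table, ddir / "drug_correlations.tsv")
    tio.write_matrix(summ, ddir / "correlation_summary.tsv")
    summary["drugscore"] = {
        "median_rho_diff": float(summ.loc["diff", "median_rho"]),
        "median_rho_ns": float(summ.loc["ns", "median_rho"]),
    }
    manifest.record("drugscore",
                    [files["panel_expr"], files["resistance"], files["panel_sets"]],
                    [ddir / "cell_line_scores.tsv", ddir / "drug_correlations.tsv",
                     ddir / "correlation_summary.tsv"],
                    time.perf_counter() - t0)

    manifest.save(out / "manifest.json")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
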