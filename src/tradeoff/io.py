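"""Plain-text readers and writers for every pipeline format.

Conventions:

* Matrices are TSV with the first column holding row ids and the header
  row holding column ids; empty cells or ``NA`` are missing.
* Coordinate tables (markers, genes, loci) are TSV with 1-based inclusive
  ``start``/``end`` columns, declared in a leading ``#`` comment;
  BED-dialect inputs (0-based half-open) are converted at parse time via
  ``coords="bed"``.
* Networks are 3-column TSV (``gene_a``, ``gene_b``, ``confidence``).
* Gene sets are one set per line: name, description, then member ids, all
  tab separated (GMT-style).
* Ortholog maps are 2-column TSV (source id, target id; repeated source
  rows accumulate).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ContractError
from .signature import GeneSet

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_intervals",
    "write_intervals",
    "read_locus_pvalues",
    "read_edge_list",
    "write_edge_list",
    "read_gene_sets",
    "write_gene_sets",
    "read_ortholog_map",
    "write_truth",
    "read_series",
    "write_series",
]


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""],
                     comment="#")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ContractError(f"{path}: duplicate row or column ids")
    return df


def write_matrix(df: pd.DataFrame, path, na_rep: str = "NA") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=na_rep)


def read_series(path) -> pd.Series:
    df = read_matrix(path)
    return df.iloc[:, 0]


def write_series(s: pd.Series, path, name: str | None = None) -> None:
    frame = s.rename(name or s.name or "value").to_frame()
    write_matrix(frame, path)


def _convert_coords(df: pd.DataFrame, coords: str) -> pd.DataFrame:
    if coords == "one":
        return df
    if coords == "bed":  # 0-based half-open -> 1-based inclusive
        df = df.copy()
        df["start"] = df["start"] + 1
        return df
    raise ContractError(f"unknown coordinate dialect {coords!r}")


def read_intervals(path, coords: str = "one") -> pd.DataFrame:
    """Read an id/chrom/start/end table (marker or gene coordinates)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    missing = {"chrom", "start", "end"} - set(df.columns)
    if missing:
        raise ContractError(f"{path}: missing columns {sorted(missing)}")
    return _convert_coords(df, coords)


def write_intervals(df: pd.DataFrame, path, id_label: str = "id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        df.to_csv(fh, sep="\t", index_label=id_label)


def read_locus_pvalues(path, coords: str = "one") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"chrom", "start", "end", "p"} - set(df.columns)
    if missing:
        raise ContractError(f"{path}: missing columns {sorted(missing)}")
    return _convert_coords(df, coords)


def write_locus_pvalues(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        df.to_csv(fh, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene_a", "gene_b", "confidence"} - set(df.columns)
    if missing:
        raise ContractError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_edge_list(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ContractError(f"{path}: gene-set line needs name, "
                                    "description and >= 1 member")
            sets.append(GeneSet(parts[0], frozenset(parts[2:]), parts[1]))
    return sets


def write_gene_sets(sets: list[GeneSet], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


def read_ortholog_map(path) -> dict:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["source", "target"])
    out: dict = {}
    for src, tgt in zip(df["source"], df["target"]):
        out.setdefault(src, set()).add(tgt)
    return out


def write_truth(truth: dict, path) -> None:
    """Write a planted-truth side channel as JSON (never read by stages)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=str)
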