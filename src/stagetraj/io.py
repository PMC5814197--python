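"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are tab-separated text. Expression matrices are written with the
gene identifier in the first column and one column per sample; sample-to-stage
assignment lives in a companion metadata table. Interaction tables follow the
STRING detailed-scores dialect (integer channel scores 0-1000 plus a
``combined_score`` column). Gene sets can also be exchanged as GMT.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """Raised when an input table is missing required columns."""


# ---------------------------------------------------------------- expression

def write_expression(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a genes x samples matrix; first column holds gene ids."""
    expr.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FORMAT)


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index.name = "gene"
    return expr


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    _require(meta, ["sample_id", "stage"], "sample metadata")
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    _require(meta, ["sample_id", "stage"], "sample metadata")
    return meta


# --------------------------------------------------------------- truth table

def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    # keep_default_na=False: the literal class label "null" is data here
    truth = pd.read_csv(path, sep="\t", dtype={"gene": str, "class": str},
                        keep_default_na=False, na_values=[""])
    for col in ("drop_stage", "module_id"):
        if col in truth.columns:
            truth[col] = truth[col].astype("Int64")
    return truth


# --------------------------------------------------------------- annotations

def write_annotation_pairs(
    pairs: pd.DataFrame, path: str | os.PathLike
) -> None:
    """Write a two-column (gene, term) association table."""
    _require(pairs, ["gene", "term"], "annotation")
    pairs.to_csv(path, sep="\t", index=False)


def read_annotation_pairs(path: str | os.PathLike) -> pd.DataFrame:
    pairs = pd.read_csv(path, sep="\t", dtype=str)
    _require(pairs, ["gene", "term"], "annotation")
    return pairs


def write_term_metadata(terms: pd.DataFrame, path: str | os.PathLike) -> None:
    _require(terms, ["term", "name", "namespace"], "term metadata")
    terms.to_csv(path, sep="\t", index=False)


def read_term_metadata(path: str | os.PathLike) -> pd.DataFrame:
    terms = pd.read_csv(path, sep="\t", dtype=str)
    _require(terms, ["term", "name", "namespace"], "term metadata")
    return terms


def write_gmt(
    gene_sets: Mapping[str, Iterable[str]],
    path: str | os.PathLike,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    """Write named gene sets in GMT (one set per line: name, description, genes)."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = sorted(set(gene_sets[name]))
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                raise FormatError(f"malformed GMT line: {line!r}")
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets


# -------------------------------------------------------------- interactions

STRING_REQUIRED = ["protein1", "protein2", "combined_score"]


def write_interactions(edges: pd.DataFrame, path: str | os.PathLike) -> None:
    _require(edges, STRING_REQUIRED, "interaction table")
    edges.to_csv(path, sep="\t", index=False)


def read_interaction_table(path: str | os.PathLike) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    _require(edges, STRING_REQUIRED, "interaction table")
    return edges


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s) {missing}")
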