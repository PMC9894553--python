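"""Readers and writers for the pipeline's tab-separated formats.

All tables are UTF-8 TSV with '.' decimal separators.  Expression tables
are transcripts x libraries with a header row of library ids; metadata has
columns library_id, species, individual, tissue; homology maps have
columns transcript, homology_group, parent_gene (parent_gene may be
empty); interaction tables have columns gene_a, gene_b, class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionTable,
    HomologyMap,
    InteractionTable,
    metadata_from_frame,
)
from .tree import read_tree  # noqa: F401  (re-exported: trees are part of the I/O surface)

logger = logging.getLogger(__name__)


def read_expression_table(path, meta_path) -> ExpressionTable:
    """Read a transcripts x libraries TSV plus its library metadata.

    Libraries present in the expression table but absent from the metadata
    are rejected; metadata rows for unknown libraries are ignored.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    meta = metadata_from_frame(pd.read_csv(meta_path, sep="\t", dtype=str))
    return ExpressionTable(values, meta)


def write_expression_table(table: ExpressionTable, path, meta_path=None) -> None:
    out = table.values.copy()
    out.index.name = "transcript"
    out.to_csv(path, sep="\t")
    if meta_path is not None:
        meta = table.meta.copy()
        meta.index.name = "library_id"
        meta.to_csv(meta_path, sep="\t")


def read_homology_map(path) -> HomologyMap:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("transcript", "homology_group"):
        if col not in df.columns:
            raise ValueError(f"homology map missing column {col!r}")
    if df["transcript"].duplicated().any():
        dups = df.loc[df["transcript"].duplicated(), "transcript"].tolist()
        raise ValueError(f"transcript mapped more than once: {dups[:5]}")
    group_of = dict(zip(df["transcript"], df["homology_group"]))
    parent = {}
    symbols: dict[str, set[str]] = {}
    if "parent_gene" in df.columns:
        for t, g, p in zip(df["transcript"], df["homology_group"], df["parent_gene"]):
            if p:
                parent[t] = p
                symbols.setdefault(g, set()).add(p)
    return HomologyMap(
        group_of,
        {g: frozenset(s) for g, s in symbols.items()},
        parent,
    )


def write_homology_map(hmap: HomologyMap, path) -> None:
    rows = [
        (t, g, hmap.parent_gene.get(t, ""))
        for t, g in sorted(hmap.group_of.items())
    ]
    pd.DataFrame(rows, columns=["transcript", "homology_group", "parent_gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_interactions(path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_a", "gene_b", "class"):
        if col not in df.columns:
            raise ValueError(f"interaction table missing column {col!r}")
    return InteractionTable(zip(df["gene_a"], df["gene_b"], df["class"]))


def write_interactions(table: InteractionTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Generic numeric matrix with row-label first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def write_matrix_tsv(df: pd.DataFrame, path, index_name: str = "id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")
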