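"""Cross-species expression normalization and averaging.

TPM is a within-library relative unit; across species it is confounded by
reference transcriptome size.  TPM10k rescales each library's TPM by the
number of genes in that species' reference divided by 10^4, making values
comparable across references of different sizes.  Downstream modeling uses
natural-log TPM10k averaged first over the transcripts of a homology group
and then over replicate individuals.

Order of operations: normalize -> log -> group-average -> replicate-average.
Zeros under the log are kept as missing (NaN) rather than pseudocounted;
the only pseudocount in the pipeline lives in the expression-bias ratio
(see :mod:`exprphylo.phyloexpr`).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import ExpressionTable, HomologyMap

logger = logging.getLogger(__name__)

__all__ = [
    "tpm10k",
    "log_transform",
    "average_by_group",
    "average_replicates",
    "reference_gene_counts",
]


def reference_gene_counts(hmap: HomologyMap, species: list[str]) -> dict[str, int]:
    """Default per-species reference size: the number of homology groups
    (collapsed genes).  Real references differ per species; callers with
    per-species annotations should pass their own map to :func:`tpm10k`."""
    n = len(set(hmap.group_of.values()))
    return {s: n for s in species}


def tpm10k(table: ExpressionTable, n_reference_genes: Mapping[str, int]) -> ExpressionTable:
    """Rescale TPM to TPM10k: value * n_reference_genes(species) / 10^4.

    ``n_reference_genes`` maps each species code to the gene count of its
    reference; a missing species is a hard error.
    """
    if table.unit != "TPM":
        raise ValueError(f"expected a TPM table, got unit {table.unit!r}")
    n_map = {str(k).lower(): v for k, v in n_reference_genes.items()}
    factors = []
    for lib in table.library_ids:
        sp = table.meta.loc[lib, "species"]
        if sp not in n_map:
            raise KeyError(f"no reference gene count for species {sp!r}")
        n = n_map[sp]
        if n <= 0:
            raise ValueError(f"reference gene count for {sp!r} must be > 0")
        factors.append(n / 1e4)
    values = table.values * np.asarray(factors)[None, :]
    return ExpressionTable(values, table.meta, unit="TPM10k")


def log_transform(table: ExpressionTable, eps: float = 0.0) -> ExpressionTable:
    """Natural-log transform: ln(x + eps).

    With the default ``eps = 0``, zeros become NaN (missing) and are
    excluded from downstream modeling.  Applying the transform twice is an
    error.
    """
    if table.log_applied:
        raise ValueError("log transform already applied")
    with np.errstate(divide="ignore"):
        values = np.log(table.values + eps)
    values = values.where(np.isfinite(values))
    return ExpressionTable(
        values,
        table.meta,
        unit=f"ln({table.unit})",
        log_applied=True,
        allow_negative=True,
    )


def average_by_group(table: ExpressionTable, hmap: HomologyMap) -> pd.DataFrame:
    """Average values per library across the transcripts of each homology
    group.  Returns a homology_group x library DataFrame; unmapped
    transcripts are dropped with a logged warning."""
    unmapped = [t for t in table.transcript_ids if t not in hmap.group_of]
    if unmapped:
        logger.warning(
            "dropping %d transcripts without a homology group (e.g. %s)",
            len(unmapped),
            unmapped[:3],
        )
    groups = pd.Series(
        {t: hmap.group_of[t] for t in table.transcript_ids if t in hmap.group_of},
        name="homology_group",
    )
    sub = table.values.loc[groups.index]
    out = sub.groupby(groups).mean()
    out.index.name = "homology_group"
    return out


def average_replicates(group_values: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Average group-level values across replicate individuals.

    ``group_values`` is homology_group x library; ``meta`` carries species
    and tissue per library.  Returns a homology_group x (species, tissue)
    DataFrame.  A missing value in any replicate propagates (the averaged
    cell is NaN), and a (species, tissue) combination with no libraries is
    simply absent — never silently zero.
    """
    missing = [l for l in group_values.columns if l not in meta.index]
    if missing:
        raise KeyError(f"libraries without metadata: {missing[:5]}")
    key = pd.MultiIndex.from_frame(
        meta.loc[group_values.columns, ["species", "tissue"]]
    )
    out = group_values.T.groupby(key).mean(numeric_only=False).T
    # pandas' groupby mean skips NaN; enforce propagation instead
    has_nan = group_values.isna().T.groupby(key).any().T
    out = out.mask(has_nan)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["species", "tissue"])
    return out.sort_index(axis=1)
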