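"""Expression-bias evolution on the species tree.

*Bias* is the natural-log ratio of a focal tissue's TPM10k to the
reference tissue's (carcass), with a pseudocount of 0.01 added to both
sides so that zeros are defined.  Ratios are taken per replicate
individual first — systematic per-individual effects cancel between
numerator and denominator — then averaged over the transcripts of a
homology group and over replicate individuals, giving one value per gene
per species.

Ancestral bias values are maximum-likelihood estimates under Brownian
motion: the internal-node values minimizing sum over edges of
(child - parent)^2 / branch_length, computed by a two-pass linear-time
message-passing scheme (equivalently, the GLS solution under the BM
covariance; the BM rate cancels from the point estimates).  Tips without
data are pruned, and reconstruction requires more than three tips.

The *scaled change* on a branch is (descendant - ancestral) / branch
length.  A *qualitative shift* is a branch on which the bias crosses
zero: a gain of focal-tissue bias (<= 0 to > 0) or a loss (> 0 to <= 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionTable, HomologyMap
from .normalization import average_by_group, average_replicates
from .tree import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "compute_bias",
    "asr_bm",
    "asr_all_genes",
    "scaled_changes",
    "call_shifts",
    "rank_swings",
    "ASRResult",
]

BIAS_PSEUDOCOUNT = 0.01
MIN_TIPS_WITH_DATA = 4  # "more than three tips"


def compute_bias(
    table: ExpressionTable,
    focal_tissue: str,
    reference_tissue: str,
    hmap: HomologyMap,
    pseudocount: float = BIAS_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Group- and replicate-averaged log expression-bias per species.

    ``table`` must hold TPM10k values (not log transformed).  For every
    individual with both a focal and a reference library, the
    per-transcript ratio ln((focal + c) / (reference + c)) is computed;
    these are then averaged across group members and across individuals.
    Returns homology_group x species; species without any complete
    focal/reference individual pair are absent.
    """
    if table.log_applied:
        raise ValueError("bias ratios are computed on linear TPM10k values")
    meta = table.meta
    ratio_cols: dict[str, np.ndarray] = {}
    ratio_meta: list[tuple[str, str, str, str]] = []
    for (sp, ind), grp in meta.groupby(["species", "individual"]):
        f = grp.index[grp["tissue"] == focal_tissue]
        r = grp.index[grp["tissue"] == reference_tissue]
        if len(f) != 1 or len(r) != 1:
            if len(f) > 1 or len(r) > 1:
                logger.warning(
                    "individual %s has multiple %s/%s libraries; skipped",
                    ind, focal_tissue, reference_tissue,
                )
            continue
        num = table.values[f[0]].to_numpy() + pseudocount
        den = table.values[r[0]].to_numpy() + pseudocount
        key = f"{sp}::{ind}"
        ratio_cols[key] = np.log(num / den)
        ratio_meta.append((key, sp, ind, focal_tissue))
    if not ratio_cols:
        raise ValueError(
            f"no individual has both a {focal_tissue} and a "
            f"{reference_tissue} library"
        )
    ratios = ExpressionTable(
        pd.DataFrame(ratio_cols, index=table.transcript_ids),
        pd.DataFrame(
            ratio_meta, columns=["library_id", "species", "individual", "tissue"]
        ).set_index("library_id"),
        unit="log-bias",
        allow_negative=True,
    )
    grouped = average_by_group(ratios, hmap)
    averaged = average_replicates(grouped, ratios.meta)
    out = averaged.xs(focal_tissue, axis=1, level="tissue")
    out.columns.name = "species"
    return out


@dataclass
class ASRResult:
    """Reconstructed node values for one gene on a (possibly pruned) tree."""

    gene: str
    tree: Phylogeny  # pruned tree used for the reconstruction
    node_values: dict[str, float]  # node name (tips included) -> value
    branch_map: dict[int, int | None]  # pruned branch id -> full-tree id
    n_tips_used: int


def _bm_ml_nodes(tree: Phylogeny, tip_values: dict[str, float]) -> dict[str, float]:
    """Two-pass ML reconstruction of internal-node values under BM.

    Upward pass: each node collects a Gaussian message (mean, variance in
    branch-length units) from its subtree.  Downward pass: each node's ML
    value combines its upward message with the message from the rest of
    the tree, transported across the connecting edge.
    """
    up_mean: dict[int, float] = {}
    up_var: dict[int, float] = {}
    nodes = list(tree.nodes())
    for node in reversed(nodes):  # postorder
        if node.is_leaf():
            up_mean[id(node)] = tip_values[node.taxon.label]
            up_var[id(node)] = 0.0
        else:
            msgs = [
                (up_mean[id(c)], up_var[id(c)] + c.edge.length)
                for c in node.child_nodes()
            ]
            prec = sum(1.0 / v for _, v in msgs)
            up_mean[id(node)] = sum(m / v for m, v in msgs) / prec
            up_var[id(node)] = 1.0 / prec

    out: dict[str, float] = {}
    down: dict[int, tuple[float, float] | None] = {id(nodes[0]): None}
    for node in nodes:  # preorder
        parent_msg = down[id(node)]
        if not node.is_leaf():
            if parent_msg is None:
                est = up_mean[id(node)]
            else:
                pm, pv = parent_msg
                w1, w2 = 1.0 / max(up_var[id(node)], 1e-300), 1.0 / pv
                est = (up_mean[id(node)] * w1 + pm * w2) / (w1 + w2)
            out[tree.node_name(node)] = est
        else:
            out[node.taxon.label] = tip_values[node.taxon.label]
        # messages to each child: combine parent_msg with siblings' upward
        for child in node.child_nodes():
            msgs = []
            if parent_msg is not None:
                msgs.append(parent_msg)
            for sib in node.child_nodes():
                if sib is not child:
                    msgs.append((up_mean[id(sib)], up_var[id(sib)] + sib.edge.length))
            prec = sum(1.0 / v for _, v in msgs)
            mean = sum(m / v for m, v in msgs) / prec
            down[id(child)] = (mean, 1.0 / prec + child.edge.length)
    return out


def asr_bm(tree: Phylogeny, tip_values: dict[str, float], gene: str = "") -> ASRResult:
    """BM ancestral state reconstruction with missing tips dropped.

    ``tip_values`` maps species codes to bias values; NaN entries count as
    missing.  Raises ``ValueError`` when three or fewer tips have data.
    """
    have = {k: float(v) for k, v in tip_values.items() if np.isfinite(v)}
    if len(have) < MIN_TIPS_WITH_DATA:
        raise ValueError(
            f"gene {gene or '<unnamed>'}: ancestral state reconstruction "
            f"requires more than three tips with data, got {len(have)}"
        )
    unknown = set(have) - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"tip values for species not in tree: {sorted(unknown)}")
    if len(have) < tree.n_tips:
        pruned, branch_map = tree.prune_to(sorted(have))
    else:
        pruned, branch_map = tree, {b: b for b in tree.branch_ids}
    node_values = _bm_ml_nodes(pruned, have)
    return ASRResult(
        gene=gene,
        tree=pruned,
        node_values=node_values,
        branch_map=branch_map,
        n_tips_used=len(have),
    )


def asr_all_genes(tree: Phylogeny, bias: pd.DataFrame) -> dict[str, ASRResult]:
    """Reconstruct every gene of a homology_group x species bias table;
    genes with too few data tips are skipped and logged."""
    results = {}
    n_skipped = 0
    for gene, row in bias.iterrows():
        try:
            results[gene] = asr_bm(tree, row.to_dict(), gene=str(gene))
        except ValueError:
            n_skipped += 1
    if n_skipped:
        logger.info("skipped %d genes with <= 3 data tips", n_skipped)
    return results


def scaled_changes(
    asr_results: dict[str, ASRResult], tree: Phylogeny
) -> pd.DataFrame:
    """Per-gene scaled change on every full-tree branch.

    Scaled change = (descendant value - ancestral value) / branch length,
    on the pruned tree of each gene, reported under the full-tree branch
    id where the pruned edge has a full-tree equivalent (both endpoints
    survive pruning); other full-tree branches are NaN for that gene.
    Columns are the 2n-2 full-tree branch ids.
    """
    branch_ids = tree.branch_ids
    rows = {}
    for gene, res in asr_results.items():
        row = np.full(len(branch_ids), np.nan)
        for node in res.tree.nodes():
            if node.parent_node is None:
                continue
            full_id = res.branch_map.get(node.branch_id)
            if full_id is None:
                continue
            child_v = res.node_values[res.tree.node_name(node)]
            parent_v = res.node_values[res.tree.node_name(node.parent_node)]
            row[full_id - 1] = (child_v - parent_v) / node.edge.length
        rows[gene] = row
    out = pd.DataFrame.from_dict(rows, orient="index", columns=branch_ids)
    out.index.name = "homology_group"
    out.columns.name = "branch_id"
    return out


def call_shifts(asr_results: dict[str, ASRResult], tree: Phylogeny) -> pd.DataFrame:
    """Qualitative gains and losses of focal-tissue bias.

    A branch hosts a *gain* when the ancestral bias is <= 0 and the
    descendant bias > 0, and a *loss* in the reverse case.  Returns one
    row per event with the gene, full-tree branch id (NaN when the pruned
    edge has no full-tree equivalent), direction, ancestral and descendant
    values, and the swing magnitude |descendant - ancestral|.
    """
    rows = []
    for gene, res in asr_results.items():
        for node in res.tree.nodes():
            if node.parent_node is None:
                continue
            child_v = res.node_values[res.tree.node_name(node)]
            parent_v = res.node_values[res.tree.node_name(node.parent_node)]
            if parent_v <= 0 < child_v:
                direction = "gain"
            elif child_v <= 0 < parent_v:
                direction = "loss"
            else:
                continue
            rows.append(
                {
                    "gene": gene,
                    "branch_id": res.branch_map.get(node.branch_id),
                    "direction": direction,
                    "ancestral": parent_v,
                    "descendant": child_v,
                    "swing": abs(child_v - parent_v),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "branch_id", "direction", "ancestral", "descendant", "swing"],
    )


def rank_swings(shifts: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k largest-magnitude shifts in each direction.

    Ties are broken deterministically by (gene, branch_id).  Raises on
    ``k <= 0`` and on an empty shift set.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if shifts.empty:
        raise ValueError("no shifts to rank")
    out = []
    for direction, grp in shifts.groupby("direction"):
        ranked = grp.sort_values(
            ["swing", "gene", "branch_id"], ascending=[False, True, True]
        )
        out.append(ranked.head(k))
    return pd.concat(out).reset_index(drop=True)
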