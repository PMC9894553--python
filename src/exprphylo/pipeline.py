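"""End-to-end orchestration of the comparative expression pipeline.

Chains the stages on in-memory objects: TPM -> TPM10k -> log/group/replicate
averaging -> per-species differential expression and core cohorts ->
variance partitioning over nested clades -> expression-bias ratios -> BM
ancestral reconstruction and scaled branch changes -> gene-gene
evolutionary correlation and interaction comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import coevolution, diffexpr, normalization, phyloexpr, varpart
from .datamodel import ExpressionTable, HomologyMap, InteractionTable
from .tree import Phylogeny

__all__ = ["PipelineResult", "run_pipeline", "nested_clades"]


def nested_clades(tree: Phylogeny, max_clades: int = 4) -> dict[str, list[str]]:
    """A ladder of nested monophyletic tip sets of increasing depth.

    Walks from the shallowest cherry toward the root and keeps up to
    ``max_clades`` distinct clades (labels A, B, C, ... shallow to deep,
    the last being all tips), emulating a nested-clade comparison design.
    """
    # deepest node whose clade has exactly 2 tips = shallowest cherry
    cherries = [n for n in tree.nodes() if len(n.clade) == 2]
    start = max(cherries, key=lambda n: (tree.depth_of(n), min(n.clade)))
    clades = []
    node = start
    while node is not None:
        if not clades or node.clade != clades[-1]:
            clades.append(node.clade)
        node = node.parent_node
    if len(clades) > max_clades:
        # keep shallowest, deepest, and evenly spaced intermediates
        idx = sorted({round(i * (len(clades) - 1) / (max_clades - 1)) for i in range(max_clades)})
        clades = [clades[i] for i in idx]
    labels = [chr(ord("A") + i) for i in range(len(clades))]
    return {lab: sorted(c) for lab, c in zip(labels, clades)}


@dataclass
class PipelineResult:
    tpm10k: ExpressionTable
    group_log_expr: pd.DataFrame  # group x library, ln TPM10k
    averaged_expr: pd.DataFrame  # group x (species, tissue)
    de: dict[str, pd.DataFrame]
    cohort: pd.DataFrame
    varpart: dict[str, pd.DataFrame]
    varpart_counts: pd.DataFrame
    bias: pd.DataFrame  # group x species
    asr: dict[str, phyloexpr.ASRResult]
    changes: pd.DataFrame  # group x branch_id
    shifts: pd.DataFrame
    correlation: coevolution.CorrelationMatrix
    interaction_report: dict | None


def run_pipeline(
    expression: ExpressionTable,
    tree: Phylogeny,
    hmap: HomologyMap,
    interactions: InteractionTable | None = None,
    *,
    focal_tissue: str = "ovary",
    reference_tissue: str = "carcass",
    n_reference_genes: dict[str, int] | None = None,
    alpha: float = diffexpr.DEFAULT_ALPHA,
    min_species: int | None = None,
    clades: dict[str, list[str]] | None = None,
    drop_outliers: bool = False,
    n_sample: int = 5000,
    n_repeats: int = 100,
    seed: int = 0,
) -> PipelineResult:
    """Run every stage on one dataset and return all intermediates.

    ``min_species`` defaults to n_species - 2 (10 of 12 in the reference
    design); ``clades`` defaults to an automatic nested ladder.
    """
    if n_reference_genes is None:
        n_reference_genes = normalization.reference_gene_counts(
            hmap, expression.species
        )
    t10k = normalization.tpm10k(expression, n_reference_genes)
    logged = normalization.log_transform(t10k)
    group_log = normalization.average_by_group(logged, hmap)
    averaged = normalization.average_replicates(group_log, logged.meta)

    de = diffexpr.de_by_species(expression, focal_tissue, reference_tissue, alpha=alpha)
    if min_species is None:
        min_species = max(len(de) - 2, 1)
    cohort = diffexpr.core_cohort(de, hmap, min_species=min_species)

    if clades is None:
        clades = nested_clades(tree)
    vp = varpart.clade_sweep(
        averaged, tree, clades, tissues=(focal_tissue, reference_tissue)
    )
    vp_counts = varpart.class_counts(vp)

    bias = phyloexpr.compute_bias(t10k, focal_tissue, reference_tissue, hmap)
    asr = phyloexpr.asr_all_genes(tree, bias)
    changes = phyloexpr.scaled_changes(asr, tree)
    shifts = phyloexpr.call_shifts(asr, tree)

    corr_input = changes
    if drop_outliers:
        corr_input, _ = coevolution.remove_outliers(changes)
    corr = coevolution.correlation_matrix(corr_input)
    report = None
    if interactions is not None and len(interactions):
        report = coevolution.compare_to_interactions(
            corr, interactions, hmap, n_sample=n_sample, n_repeats=n_repeats, seed=seed
        )
    return PipelineResult(
        tpm10k=t10k,
        group_log_expr=group_log,
        averaged_expr=averaged,
        de=de,
        cohort=cohort,
        varpart=vp,
        varpart_counts=vp_counts,
        bias=bias,
        asr=asr,
        changes=changes,
        shifts=shifts,
        correlation=corr,
        interaction_report=report,
    )
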