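"""Per-species differential expression and cross-species core cohorts.

Differential expression between a focal tissue and the carcass is tested
per transcript with a negative-binomial Wald test: the NB is parameterized
by mean mu and dispersion phi (Var = mu + phi mu^2), phi is
moment-estimated from the replicates and floored at 1e-8, the effect is
log2((mean_focal + 0.5) / (mean_carcass + 0.5)), and its delta-method
standard error gives a Wald z.  P-values are Benjamini-Hochberg adjusted
across all tested transcripts of a species.  This is a deliberately simple,
fully documented stand-in for shrinkage-based DE packages: downstream
stages consume only the effect size and adjusted p-value.

A *core cohort* gene is a reference parent gene with at least one
transcript significantly upregulated in the focal tissue in at least
``min_species`` of the species analyzed — fragmented or divergent sibling
transcripts that never reach significance do not disqualify a gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionTable, HomologyMap

logger = logging.getLogger(__name__)

__all__ = ["de_test", "de_by_species", "core_cohort", "reference_enrichment"]

DISPERSION_FLOOR = 1e-8
LOG2FC_PSEUDOCOUNT = 0.5
DEFAULT_ALPHA = 0.01


def _moment_dispersion(x: np.ndarray) -> np.ndarray:
    """Per-row method-of-moments NB dispersion: (s^2 - m) / m^2."""
    m = x.mean(axis=1)
    v = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (v - m) / m**2
    phi = np.where(np.isfinite(phi), phi, 0.0)
    return phi


def de_test(
    focal: pd.DataFrame,
    reference: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """NB Wald test per transcript, focal vs reference tissue.

    Parameters
    ----------
    focal, reference :
        Transcripts x replicate-libraries abundance frames with identical
        row index (>= 2 replicates each).
    alpha :
        Adjusted-p significance threshold.

    Returns a frame indexed by transcript with columns ``log2fc, p, padj,
    significant, direction, tested``; transcripts that are all-zero in
    both tissues are excluded from testing (``tested = False``) and from
    the BH correction.
    """
    if not focal.index.equals(reference.index):
        raise ValueError("focal and reference tables must share a transcript index")
    if focal.shape[1] < 2 or reference.shape[1] < 2:
        raise ValueError("need at least 2 replicates per tissue")
    xf = focal.to_numpy(dtype=float)
    xr = reference.to_numpy(dtype=float)
    allzero = (xf.sum(axis=1) == 0) & (xr.sum(axis=1) == 0)
    if allzero.any():
        logger.info("excluding %d all-zero transcripts from DE", int(allzero.sum()))

    mf, mr = xf.mean(axis=1), xr.mean(axis=1)
    nf, nr = xf.shape[1], xr.shape[1]
    # pooled moment dispersion across the two tissues, floored
    phi = 0.5 * (_moment_dispersion(xf) + _moment_dispersion(xr))
    phi = np.maximum(phi, DISPERSION_FLOOR)

    log2fc = np.log2((mf + LOG2FC_PSEUDOCOUNT) / (mr + LOG2FC_PSEUDOCOUNT))
    # delta method on ln(mean): Var(ln m_hat) ~ (m + phi m^2)/(n m^2)
    vf = 1.0 / (nf * (mf + LOG2FC_PSEUDOCOUNT)) + phi / nf
    vr = 1.0 / (nr * (mr + LOG2FC_PSEUDOCOUNT)) + phi / nr
    se = np.sqrt(vf + vr) / np.log(2.0)
    z = np.where(log2fc == 0, 0.0, log2fc / se)
    p = 2 * stats.norm.sf(np.abs(z))

    padj = np.full_like(p, np.nan)
    tested = ~allzero
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": np.where(tested, p, np.nan),
            "padj": padj,
            "tested": tested,
        },
        index=focal.index,
    )
    out["significant"] = out["padj"] < alpha
    out["direction"] = np.where(out["log2fc"] > 0, "up", np.where(out["log2fc"] < 0, "down", "none"))
    return out


def de_by_species(
    table: ExpressionTable,
    focal_tissue: str,
    reference_tissue: str = "carcass",
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, pd.DataFrame]:
    """Run :func:`de_test` independently for every species in the table."""
    results = {}
    for sp in table.species:
        f_libs = table.libraries_for(species=sp, tissue=focal_tissue)
        r_libs = table.libraries_for(species=sp, tissue=reference_tissue)
        if len(f_libs) < 2 or len(r_libs) < 2:
            logger.warning(
                "skipping species %s: fewer than 2 replicates (%d %s, %d %s)",
                sp, len(f_libs), focal_tissue, len(r_libs), reference_tissue,
            )
            continue
        results[sp] = de_test(table.values[f_libs], table.values[r_libs], alpha=alpha)
    return results


def core_cohort(
    de_results: dict[str, pd.DataFrame],
    hmap: HomologyMap,
    min_species: int = 10,
    direction: str = "up",
) -> pd.DataFrame:
    """Count, per parent gene, the species with at least one significant
    transcript in the stated direction, and flag cohort membership.

    ``min_species`` defaults to 10 of 12 and is inclusive (>=).  Returns a
    frame indexed by parent gene with ``n_supporting_species`` and
    ``member``.
    """
    n_species = len(de_results)
    if min_species > n_species:
        raise ValueError(
            f"min_species={min_species} exceeds the {n_species} species analyzed"
        )
    support: dict[str, set[str]] = {}
    n_unannotated = 0
    for sp, de in de_results.items():
        hits = de.index[(de["significant"]) & (de["direction"] == direction)]
        for t in hits:
            gene = hmap.parent_gene.get(t)
            if gene is None:
                n_unannotated += 1
                continue
            support.setdefault(gene, set()).add(sp)
    if n_unannotated:
        logger.info(
            "%d significant transcripts lacked a parent-gene annotation", n_unannotated
        )
    out = pd.DataFrame(
        {"n_supporting_species": {g: len(s) for g, s in support.items()}}
    ).sort_index()
    out.index.name = "gene"
    out["member"] = out["n_supporting_species"] >= min_species
    return out


#: tissues excluded when deciding ovary enrichment in the reference atlas
#: (they were dissected separately in the comparative design)
OVARY_EXCLUDES = ("head", "brain", "eye")

ATLAS_PSEUDOCOUNT = 2.0


def reference_enrichment(
    atlas: pd.DataFrame,
    focal: str,
    whole_body_column: str = "whole_body",
) -> pd.DataFrame:
    """Tissue enrichment calls against a whole-body reference atlas.

    ``atlas`` is genes x tissues FPKM, including ``whole_body_column``;
    empty (NaN) cells receive a pseudocount of two counts before the
    ratio, so an all-empty gene gets enrichment 1 everywhere.  Enrichment
    is FPKM_tissue / FPKM_whole_body.  A gene is

    - ovary-enriched if ovary is the argmax enrichment across tissues
      excluding head, brain and eye;
    - head-enriched if the argmax, excluding the ovary, is head, brain or
      eye.

    Returns enrichment ratios plus an ``enriched`` flag for ``focal``
    ('ovary' or 'head').
    """
    if whole_body_column not in atlas.columns:
        raise ValueError(f"atlas lacks whole-body column {whole_body_column!r}")
    if focal not in ("ovary", "head"):
        raise ValueError("focal must be 'ovary' or 'head'")
    filled = atlas.fillna(ATLAS_PSEUDOCOUNT)
    whole = filled[whole_body_column]
    zero_whole = whole == 0
    if zero_whole.any():
        logger.warning(
            "skipping %d genes with zero whole-body FPKM", int(zero_whole.sum())
        )
    tissues = [c for c in atlas.columns if c != whole_body_column]
    enr = filled[tissues].div(whole, axis=0)[~zero_whole.to_numpy()]
    if focal == "ovary":
        candidates = [t for t in tissues if t not in OVARY_EXCLUDES]
        calls = enr[candidates].idxmax(axis=1) == "ovary"
    else:
        candidates = [t for t in tissues if t != "ovary"]
        calls = enr[candidates].idxmax(axis=1).isin(OVARY_EXCLUDES)
    enr = enr.copy()
    enr["enriched"] = calls
    return enr
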