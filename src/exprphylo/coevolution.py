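"""Evolutionary correlation of expression-bias changes between genes.

Genes represented across all species share the same set of tree branches,
so their per-branch scaled bias changes can be compared directly: for
every gene pair, a Pearson correlation coefficient over the 2n-2
equivalent branches.  The reported pairwise-comparison count follows the
ordered-pairs-including-self convention G^2 (the unordered distinct count
is also carried for transparency).

Because far more pairs are compared than there are branches, spurious
strong correlations are expected; two mitigations are provided: removing
genes whose changes contain outliers (beyond ``k_sd`` standard deviations
from the mean over all entries), and benchmarking the coefficient
distribution of annotated interaction partners against repeated random
samples of unknown pairs with two-sample t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import HomologyMap, InteractionTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "correlation_matrix",
    "remove_outliers",
    "compare_to_interactions",
    "extract_network",
]

NETWORK_THRESHOLD = 0.825
OUTLIER_K_SD = 2.0


@dataclass
class CorrelationMatrix:
    """Gene-gene Pearson coefficients over equivalent branches."""

    genes: list[str]
    matrix: pd.DataFrame  # genes x genes, NaN where undefined
    n_pairwise: int  # ordered pairs incl. self: G^2 (reported convention)
    n_unordered: int  # distinct unordered pairs: G*(G-1)/2
    n_branches: int

    def r(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])


def correlation_matrix(changes: pd.DataFrame) -> CorrelationMatrix:
    """Pearson correlation of scaled changes across equivalent branches.

    ``changes`` is genes x branch ids (from
    :func:`exprphylo.phyloexpr.scaled_changes`); only genes with a value
    on every branch — i.e. represented across all species — enter the
    matrix.  Genes whose changes have zero variance get NaN coefficients
    (undefined correlation) and are excluded from downstream tests.
    """
    full = changes.dropna(axis=0, how="any")
    n_dropped = len(changes) - len(full)
    if n_dropped:
        logger.info(
            "correlation restricted to %d full-representation genes "
            "(%d dropped)", len(full), n_dropped,
        )
    if full.empty:
        raise ValueError("no genes with full species representation")
    x = full.to_numpy(dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    genes = list(full.index)
    mat = pd.DataFrame(corr, index=genes, columns=genes)
    g = len(genes)
    return CorrelationMatrix(
        genes=genes,
        matrix=mat,
        n_pairwise=g * g,
        n_unordered=g * (g - 1) // 2,
        n_branches=changes.shape[1],
    )


def remove_outliers(changes: pd.DataFrame, k_sd: float = OUTLIER_K_SD) -> tuple[pd.DataFrame, list[str]]:
    """Drop genes whose scaled changes contain low-confidence outliers.

    The mean and sample standard deviation are taken over *all* finite
    entries of the matrix; any gene with an entry beyond ``k_sd`` standard
    deviations from that global mean is removed.  With zero global SD
    nothing is removed.  Returns (filtered matrix, removed gene ids).
    """
    flat = changes.to_numpy(dtype=float)
    finite = flat[np.isfinite(flat)]
    if finite.size == 0:
        raise ValueError("empty change matrix")
    mu = finite.mean()
    sd = finite.std(ddof=1) if finite.size > 1 else 0.0
    if sd == 0 or not np.isfinite(k_sd):
        return changes.copy(), []
    dev = np.abs(flat - mu)
    bad = np.nansum(dev > k_sd * sd, axis=1) > 0
    removed = list(changes.index[bad])
    if removed:
        logger.info("outlier filter removed %d of %d genes", len(removed), len(changes))
    return changes.loc[~bad], removed


def _offdiag_values(
    cm: CorrelationMatrix,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    iu = np.triu_indices(len(cm.genes), k=1)
    vals = cm.matrix.to_numpy()[iu]
    return iu[0], iu[1], vals


def _pairs_to_groups(
    interactions: InteractionTable, hmap: HomologyMap, cls: str
) -> list[tuple[str, str]]:
    """Resolve symbol pairs of one class to homology-group pairs; pairs
    whose two symbols fall in the same group are dropped (self-pairs after
    collapsing), as are pairs with unresolvable symbols."""
    rev = hmap.group_of_symbol()
    out = set()
    for a, b in interactions.pairs(cls):
        for ga in rev.get(a, ()):  # a symbol may map to several groups
            for gb in rev.get(b, ()):
                if ga != gb:
                    out.add((min(ga, gb), max(ga, gb)))
    return sorted(out)


def compare_to_interactions(
    cm: CorrelationMatrix,
    interactions: InteractionTable,
    hmap: HomologyMap,
    n_sample: int = 5000,
    n_repeats: int = 100,
    seed: int | np.random.Generator = 0,
    welch: bool = True,
) -> dict:
    """T-tests of interaction-class coefficients against unknown pairs.

    For each interaction class present, the Pearson coefficients of its
    annotated gene pairs are compared with a fresh random sample of
    ``n_sample`` coefficients from pairs with no annotation, using a
    two-sample t-test (Welch by default), repeated ``n_repeats`` times;
    the maximum p-value over repeats is reported.  Enhancement and
    suppression classes are additionally compared to each other once.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(cm.genes)}
    mat = cm.matrix.to_numpy()

    class_vals: dict[str, np.ndarray] = {}
    labeled: set[tuple[int, int]] = set()
    classes = sorted({e.interaction_class for e in interactions.entries})
    for cls in classes:
        vals = []
        for a, b in _pairs_to_groups(interactions, hmap, cls):
            if a in gene_pos and b in gene_pos:
                i, j = gene_pos[a], gene_pos[b]
                labeled.add((min(i, j), max(i, j)))
                r = mat[i, j]
                if np.isfinite(r):
                    vals.append(r)
        class_vals[cls] = np.asarray(vals)

    ii, jj, vals = _offdiag_values(cm)
    unlabeled_mask = np.array([(i, j) not in labeled for i, j in zip(ii, jj)])
    unknown = vals[unlabeled_mask & np.isfinite(vals)]
    if unknown.size == 0:
        raise ValueError("no unknown-pair coefficients to sample from")

    report: dict = {
        "n_repeats": n_repeats,
        "n_sample": n_sample,
        "n_unknown_pairs": int(unknown.size),
        "mean_r_unknown": float(unknown.mean()),
        "classes": {},
    }
    for cls, v in class_vals.items():
        if v.size < 2:
            logger.warning("class %s has < 2 mapped pairs; skipped", cls)
            continue
        ps, ts = [], []
        replace = n_sample > unknown.size
        for _ in range(n_repeats):
            samp = rng.choice(unknown, size=n_sample, replace=replace)
            t, p = stats.ttest_ind(v, samp, equal_var=not welch)
            ps.append(float(p))
            ts.append(float(t))
        report["classes"][cls] = {
            "n_pairs": int(v.size),
            "mean_r": float(v.mean()),
            "max_p": max(ps),
            "min_t": min(ts),
            "mean_t": float(np.mean(ts)),
        }
    enh, sup = class_vals.get("enhancement"), class_vals.get("suppression")
    if enh is not None and sup is not None and enh.size >= 2 and sup.size >= 2:
        t, p = stats.ttest_ind(enh, sup, equal_var=not welch)
        report["enhancement_vs_suppression"] = {"t": float(t), "p": float(p)}
    return report


def extract_network(
    cm: CorrelationMatrix,
    focus: str | list[str],
    threshold: float = NETWORK_THRESHOLD,
) -> pd.DataFrame:
    """Edges from focus gene(s) to all partners with |r| strictly above
    the threshold; the sign of the correlation is retained."""
    focus_list = [focus] if isinstance(focus, str) else list(focus)
    absent = [g for g in focus_list if g not in cm.matrix.index]
    if absent:
        preview = ", ".join(cm.genes[:10])
        raise KeyError(
            f"focus genes not in correlation matrix: {absent}; "
            f"available ids start with: {preview} ..."
        )
    rows = []
    for g in focus_list:
        r = cm.matrix.loc[g].drop(index=focus_list, errors="ignore")
        hits = r[np.abs(r) > threshold].dropna()
        for partner, val in hits.items():
            rows.append(
                {
                    "gene_a": g,
                    "gene_b": partner,
                    "r": float(val),
                    "sign": "positive" if val > 0 else "negative",
                }
            )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "sign"])
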