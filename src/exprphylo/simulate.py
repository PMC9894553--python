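"""Synthetic comparative-transcriptomics datasets with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a rooted ultrametric species tree; per-gene log expression bias
(ovary vs carcass) evolving by Brownian motion (BM) along the tree,
optionally as correlated bivariate BM for designated gene pairs;
per-library negative-binomial count noise around log-normally distributed
baseline abundances; and assembly fragmentation that splits a gene's
expected abundance across 2-4 transcript fragments.

Defaults mirror the sampling design the pipeline targets: 12 species,
three tissues (ovary / head / carcass), three replicate individuals per
species, with a minority of genes truly ovary-biased.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExpressionTable, HomologyMap, InteractionTable
from .tree import Phylogeny
from . import io as epio

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_tree",
    "simulate_bias_bm",
    "emit_counts",
    "simulate_dataset",
    "write_dataset",
]

#: ancestral reconstruction requires more than three tips with data
MIN_TIPS = 4


@dataclass
class SimConfig:
    """Parameters of the synthetic world.

    Attributes
    ----------
    n_species :
        Number of tree tips (>= 4; reconstruction needs more than three).
    tree_depth :
        Root-to-tip depth in relative time units.
    n_genes :
        Number of genes (homology groups).
    n_correlated_pairs :
        Number of disjoint gene pairs whose bias evolves as bivariate BM
        with per-branch increment correlation ``rho``.
    rho :
        BM cross-correlation for correlated pairs, in (-1, 1).
    sigma2 :
        BM rate: variance of the log-bias increment per unit branch length.
    baseline_log_mean, baseline_log_sd :
        Natural-log mean / sd of a gene's carcass expected abundance
        (log-normal across genes).
    nb_dispersion :
        NB dispersion phi with Var = mu + phi * mu**2; 0 means Poisson.
    n_replicates :
        Replicate individuals per species (each dissected into all tissues).
    fragmentation_prob :
        Probability a gene's transcript is split into 2-4 fragments.
    de_fraction :
        Fraction of genes with a true ovary bias at the root.
    bias_mean, bias_sd :
        Root log-bias of truly ovary-biased genes is drawn from
        N(bias_mean, bias_sd**2); unbiased genes start at 0.
    head_bias :
        If True, head libraries get their own independently evolving bias
        (mirroring the ovary model); by default heads are generated like
        carcass.
    n_decoy_interactions :
        Number of random enhancement and suppression pairs (each) written
        to the interaction table alongside the truly correlated pairs,
        which are labeled 'physical'.
    """

    n_species: int = 12
    tree_depth: float = 1.0
    n_genes: int = 500
    n_correlated_pairs: int = 20
    rho: float = 0.9
    sigma2: float = 0.5
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    fragmentation_prob: float = 0.2
    de_fraction: float = 0.1
    bias_mean: float = float(np.log(4.0))
    bias_sd: float = 0.25
    head_bias: bool = False
    n_decoy_interactions: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < MIN_TIPS:
            raise ValueError(
                "n_species must be >= 4: ancestral state reconstruction "
                "requires more than three tips with data"
            )
        if not (0 <= self.fragmentation_prob <= 1 and 0 <= self.de_fraction <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if 2 * self.n_correlated_pairs > self.n_genes:
            raise ValueError("too many correlated pairs for n_genes")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated dataset."""

    tip_bias: pd.DataFrame  # genes x species, true log ovary/carcass bias
    node_bias: pd.DataFrame  # genes x internal node names (root, nodeK)
    correlated_pairs: list[tuple[str, str]]
    rho: float
    biased_genes: list[str]
    fragment_parent: dict[str, str]  # transcript -> gene id

    def to_json(self) -> str:
        return json.dumps(
            {
                "rho": self.rho,
                "correlated_pairs": self.correlated_pairs,
                "biased_genes": self.biased_genes,
                "fragment_parent": self.fragment_parent,
                "tip_bias": self.tip_bias.to_dict(orient="index"),
                "node_bias": self.node_bias.to_dict(orient="index"),
            },
            indent=0,
            sort_keys=True,
        )


@dataclass
class SimDataset:
    config: SimConfig
    tree: Phylogeny
    expression: ExpressionTable
    hmap: HomologyMap
    interactions: InteractionTable
    truth: SimTruth
    head_truth: SimTruth | None = None


def _species_codes(n: int) -> list[str]:
    # four-character species codes, e.g. sp00 .. sp11
    return [f"sp{i:02d}" for i in range(n)]


def simulate_tree(n_tips: int, seed: int | np.random.Generator, depth: float = 1.0) -> Phylogeny:
    """Random rooted bifurcating ultrametric tree of the given depth.

    Node heights follow a Kingman-coalescent schedule (pairwise merging at
    exponential waiting times), then all heights are rescaled so the root
    sits at ``depth``.
    """
    if n_tips < MIN_TIPS:
        raise ValueError(
            "n_tips must be >= 4: ancestral state reconstruction requires "
            "more than three tips with data"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = _species_codes(n_tips)
    lineages: list[tuple[str, float]] = [(lab, 0.0) for lab in labels]
    height = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        height += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = lineages[i], lineages[j]
        merged = (
            f"({na}:{height - ha:.10f},{nb}:{height - hb:.10f})",
            height,
        )
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    newick, root_h = lineages[0]
    scale = depth / root_h
    # rescale by re-parsing: simpler to scale every length textually is
    # error-prone; build with scaled heights instead
    phylo = Phylogeny.from_newick(newick + ";")
    for node in phylo.nodes():
        if node.parent_node is not None:
            node.edge.length *= scale
    return Phylogeny.from_newick(phylo.to_newick())


def _gene_ids(n: int) -> list[str]:
    return [f"HG{i:04d}" for i in range(n)]


def simulate_bias_bm(
    tree: Phylogeny, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Evolve per-gene log expression bias along the tree by Brownian motion.

    Each gene starts at its root value (0 for unbiased genes; a draw from
    N(bias_mean, bias_sd^2) for the ovary-biased fraction) and accumulates
    independent Gaussian increments of variance ``sigma2 * branch_length``
    on every edge.  Genes in a correlated pair receive increments with
    cross-correlation ``rho`` on every edge.

    Returns the genes x species tip-value matrix and a :class:`SimTruth`
    carrying tip and internal-node values.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    n_g = config.n_genes

    order = rng.permutation(n_g)
    n_biased = int(round(config.de_fraction * n_g))
    biased_idx = np.sort(order[:n_biased])
    root = np.zeros(n_g)
    root[biased_idx] = rng.normal(config.bias_mean, config.bias_sd, size=n_biased)

    # disjoint correlated pairs drawn from the remaining order
    pair_idx = order[n_biased : n_biased + 2 * config.n_correlated_pairs]
    pairs = [
        (int(pair_idx[2 * i]), int(pair_idx[2 * i + 1]))
        for i in range(config.n_correlated_pairs)
    ]
    partner = {}
    for a, b in pairs:
        partner[a] = b
        partner[b] = a

    edges = [n for n in tree.nodes() if n.parent_node is not None]
    n_e = len(edges)
    z = rng.standard_normal((n_g, n_e))
    if pairs and config.rho != 0:
        a_idx = np.array([a for a, _ in pairs])
        b_idx = np.array([b for _, b in pairs])
        z[b_idx] = config.rho * z[a_idx] + np.sqrt(1 - config.rho**2) * z[b_idx]
    lens = np.array([e.edge.length for e in edges])
    incr = z * np.sqrt(config.sigma2 * lens)[None, :]

    values: dict[int, np.ndarray] = {id(next(iter(tree.nodes()))): root}
    node_cols: dict[str, np.ndarray] = {"root": root}
    tip_cols: dict[str, np.ndarray] = {}
    for k, node in enumerate(edges):
        v = values[id(node.parent_node)] + incr[:, k]
        values[id(node)] = v
        if node.is_leaf():
            tip_cols[node.taxon.label] = v
        else:
            node_cols[tree.node_name(node)] = v

    tip_bias = pd.DataFrame(tip_cols, index=genes)[sorted(tip_cols)]
    node_bias = pd.DataFrame(node_cols, index=genes)
    truth = SimTruth(
        tip_bias=tip_bias,
        node_bias=node_bias,
        correlated_pairs=[(genes[a], genes[b]) for a, b in pairs],
        rho=config.rho,
        biased_genes=[genes[i] for i in biased_idx],
        fragment_parent={},
    )
    return tip_bias, truth


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB draw with Var = mu + phi mu^2 (Poisson when phi == 0)."""
    mu = np.asarray(mu, dtype=float)
    if phi == 0:
        return rng.poisson(mu).astype(float)
    r = 1.0 / phi
    p = r / (r + mu)
    out = np.zeros_like(mu)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out.astype(float)


def fragmentation_plan(
    genes: list[str], config: SimConfig, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, np.ndarray, dict[str, str]]:
    """Split genes into transcript fragments.

    With probability ``fragmentation_prob`` a gene is split into 2-4
    fragments whose expectation weights are a Dirichlet draw (summing to
    one, so fragment expectations sum exactly to the parent expectation).
    Returns (transcript ids, flat weights, parent gene index per
    transcript, fragment -> parent map).
    """
    transcripts: list[str] = []
    frag_parent: dict[str, str] = {}
    weights: list[np.ndarray] = []
    parent_idx_parts: list[np.ndarray] = []
    for gi, g in enumerate(genes):
        if rng.random() < config.fragmentation_prob:
            n_frag = int(rng.integers(2, 5))
            w = rng.dirichlet(np.ones(n_frag))
        else:
            n_frag, w = 1, np.ones(1)
        ids = [f"{g}_t{j}" for j in range(n_frag)]
        transcripts.extend(ids)
        for t in ids:
            frag_parent[t] = g
        weights.append(w)
        parent_idx_parts.append(np.full(n_frag, gi))
    return (
        transcripts,
        np.concatenate(weights),
        np.concatenate(parent_idx_parts),
        frag_parent,
    )


def emit_counts(
    tip_bias: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    head_bias: pd.DataFrame | None = None,
) -> tuple[ExpressionTable, HomologyMap, dict[str, str]]:
    """Turn true tissue biases into a noisy TPM expression table.

    For each gene a carcass expected abundance mu_g is drawn log-normally;
    the ovary expectation is mu_g * exp(bias); heads are generated like
    carcass unless a head bias matrix is supplied.  Genes are optionally
    fragmented into 2-4 transcripts whose expectations are Dirichlet
    splits of the parent expectation.  Counts are NB-sampled per library
    and reported as TPM (library sums normalized to 1e6).

    Returns the expression table, the fragment-aware homology map, and
    the fragment -> parent-gene map.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if not np.isfinite(tip_bias.to_numpy()).all():
        raise ValueError("tip bias values must be finite")
    genes = list(tip_bias.index)
    species = list(tip_bias.columns)
    n_g = len(genes)

    mu = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_g))

    transcripts, w_flat, parent_idx, frag_parent = fragmentation_plan(
        genes, config, rng
    )

    tissues = ["carcass", "head", "ovary"]
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for s in species:
        bias_s = tip_bias[s].to_numpy()
        hb_s = head_bias[s].to_numpy() if head_bias is not None else None
        for rep in range(1, config.n_replicates + 1):
            ind = f"{s}_ind{rep}"
            for tissue in tissues:
                lam_gene = mu.copy()
                if tissue == "ovary":
                    lam_gene = mu * np.exp(bias_s)
                elif tissue == "head" and hb_s is not None:
                    lam_gene = mu * np.exp(hb_s)
                lam = lam_gene[parent_idx] * w_flat
                lam = lam * (1e6 / lam.sum())
                counts = _nb_sample(rng, lam, config.nb_dispersion)
                total = counts.sum()
                tpm = counts * (1e6 / total) if total > 0 else counts
                lib = f"{s}_{tissue}_{rep}"
                cols[lib] = tpm
                meta_rows.append((lib, s, ind, tissue))
    values = pd.DataFrame(cols, index=transcripts)
    meta = pd.DataFrame(
        meta_rows, columns=["library_id", "species", "individual", "tissue"]
    ).set_index("library_id")
    table = ExpressionTable(values, meta)
    hmap = HomologyMap(
        group_of=dict(frag_parent),
        symbols_of_group={
            g: frozenset({g.replace("HG", "GENE")}) for g in genes
        },
        parent_gene={t: g.replace("HG", "GENE") for t, g in frag_parent.items()},
    )
    return table, hmap, frag_parent


def _decoy_interactions(
    config: SimConfig, truth: SimTruth, rng: np.random.Generator
) -> InteractionTable:
    """Interaction labels: truly correlated pairs as 'physical', plus
    random decoy enhancement/suppression pairs among the other genes."""
    sym = lambda g: g.replace("HG", "GENE")
    rows = [(sym(a), sym(b), "physical") for a, b in truth.correlated_pairs]
    taken = {g for p in truth.correlated_pairs for g in p}
    free = [g for g in truth.tip_bias.index if g not in taken]
    for cls in ("enhancement", "suppression"):
        for _ in range(config.n_decoy_interactions):
            if len(free) < 2:
                break
            a, b = rng.choice(len(free), size=2, replace=False)
            rows.append((sym(free[a]), sym(free[b]), cls))
    return InteractionTable(rows)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Full generative run: tree, biases, counts, maps, interaction labels.

    Byte-identical for identical ``config`` (all randomness flows from
    ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, rng, config.tree_depth)
    tip_bias, truth = simulate_bias_bm(tree, config, rng)
    head_truth = None
    hb = None
    if config.head_bias:
        hb, head_truth = simulate_bias_bm(tree, config, rng)
    expr, hmap, frag_parent = emit_counts(tip_bias, config, rng, head_bias=hb)
    truth.fragment_parent = frag_parent
    interactions = _decoy_interactions(config, truth, rng)
    return SimDataset(config, tree, expr, hmap, interactions, truth, head_truth)


def write_dataset(ds: SimDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.tree.write(out / "tree.nwk")
    epio.write_expression_table(ds.expression, out / "expression.tsv", out / "meta.tsv")
    epio.write_homology_map(ds.hmap, out / "homology_map.tsv")
    epio.write_interactions(ds.interactions, out / "interactions.tsv")
    (out / "truth.json").write_text(ds.truth.to_json())
    cfg = dataclasses.asdict(ds.config)
    (out / "sim_config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
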