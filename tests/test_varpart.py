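"""Variance partitioning against explicit sum-of-squares oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from exprphylo.pipeline import nested_clades
from exprphylo.simulate import SimConfig, simulate_bias_bm, simulate_tree
from exprphylo.varpart import (
    RESIDUAL_RULE,
    STRICT_RULE,
    clade_sweep,
    class_counts,
    classify_genes,
    partition_variance,
)

TISSUES = ("ovary", "carcass")


def make_values(matrix, species, genes=None):
    """matrix: genes x (species x tissue) in (species major, ovary/carcass)"""
    cols = pd.MultiIndex.from_tuples(
        [(s, t) for s in species for t in TISSUES], names=["species", "tissue"]
    )
    genes = genes or [f"g{i}" for i in range(np.atleast_2d(matrix).shape[0])]
    return pd.DataFrame(np.atleast_2d(matrix), index=genes, columns=cols)


def anova_oracle(y, species, tissues):
    """Independent sequential-SS oracle via statsmodels type-I ANOVA."""
    df = pd.DataFrame(
        {
            "y": y,
            "tissue": [t for _ in species for t in tissues],
            "species": [s for s in species for _ in tissues],
        }
    )
    fit = smf.ols("y ~ C(tissue) + C(species)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    ss = tab["sum_sq"]
    total = ss.sum()
    return (
        ss["C(tissue)"] / total,
        ss["C(species)"] / total,
        ss["Residual"] / total,
    )


def groupmean_oracle(y, species, tissues):
    """Brute-force balanced decomposition from group means."""
    y = np.asarray(y, dtype=float)
    tiss = np.array([t for _ in species for t in tissues])
    spec = np.array([s for s in species for _ in tissues])
    gm = y.mean()
    ss_t = sum(
        (y[tiss == t].mean() - gm) ** 2 * (tiss == t).sum() for t in set(tiss)
    )
    ss_s = sum(
        (y[spec == s].mean() - gm) ** 2 * (spec == s).sum() for s in set(spec)
    )
    fitted = np.array(
        [y[tiss == t].mean() + y[spec == s].mean() - gm for s, t in zip(spec, tiss)]
    )
    ss_r = ((y - fitted) ** 2).sum()
    total = ((y - gm) ** 2).sum()
    return ss_t / total, ss_s / total, ss_r / total


class TestPartition:
    def test_pure_tissue_indicator(self):
        species = ["spaa", "spab", "spac"]
        y = [[1.0, 0.0] * 3]
        vp = partition_variance(make_values(y, species))
        row = vp.iloc[0]
        assert row["prop_tissue"] == pytest.approx(1.0)
        assert row["prop_species"] == pytest.approx(0.0, abs=1e-12)
        assert row["prop_residual"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_species_means(self):
        species = ["spaa", "spab", "spac"]
        y = [[1.0, 1.0, 5.0, 5.0, -2.0, -2.0]]
        row = partition_variance(make_values(y, species)).iloc[0]
        assert row["prop_species"] == pytest.approx(1.0)

    def test_matches_both_oracles(self):
        rng = np.random.default_rng(0)
        species = [f"sp{i:02d}" for i in range(4)]
        y = rng.normal(size=(20, 8))
        vp = partition_variance(make_values(y, species))
        for i in range(20):
            for oracle in (anova_oracle, groupmean_oracle):
                pt, ps, pr = oracle(y[i], species, TISSUES)
                assert vp.iloc[i]["prop_tissue"] == pytest.approx(pt, abs=1e-9)
                assert vp.iloc[i]["prop_species"] == pytest.approx(ps, abs=1e-9)
                assert vp.iloc[i]["prop_residual"] == pytest.approx(pr, abs=1e-9)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(5)
        species = [f"sp{i:02d}" for i in range(5)]
        vp = partition_variance(make_values(rng.normal(size=(50, 10)), species))
        sums = vp[["prop_tissue", "prop_species", "prop_residual"]].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_balanced_order_invariance(self):
        """Tissue-first sequential SS equals species-first on balanced data:
        swap the roles of the two factors and compare."""
        rng = np.random.default_rng(8)
        species = [f"sp{i:02d}" for i in range(4)]
        y = rng.normal(size=8)
        pt, ps, pr = groupmean_oracle(y, species, TISSUES)
        # swapped-role oracle: treat species as 'tissue' levels and vice versa
        df = pd.DataFrame(
            {
                "y": y,
                "tissue": [t for _ in species for t in TISSUES],
                "species": [s for s in species for _ in TISSUES],
            }
        )
        fit = smf.ols("y ~ C(species) + C(tissue)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        total = tab["sum_sq"].sum()
        assert tab["sum_sq"]["C(tissue)"] / total == pytest.approx(pt, abs=1e-9)
        assert tab["sum_sq"]["C(species)"] / total == pytest.approx(ps, abs=1e-9)

    def test_constant_gene_flagged(self):
        vp = partition_variance(make_values([[3.0] * 6], ["spaa", "spab", "spac"]))
        assert vp.iloc[0]["status"] == "constant"
        assert np.isnan(vp.iloc[0]["prop_tissue"])

    def test_missing_cell_excludes_gene(self):
        y = [[1.0, 2.0, np.nan, 0.5, 1.0, 2.0]]
        vp = partition_variance(make_values(y, ["spaa", "spab", "spac"]))
        assert vp.iloc[0]["status"] == "missing"


class TestClassify:
    @pytest.mark.parametrize(
        "props,expected",
        [
            ((0.80, 0.10, 0.10), "TVG"),
            ((0.10, 0.80, 0.10), "SVG"),
            ((0.40, 0.35, 0.25), "neither"),
        ],
    )
    def test_rules(self, props, expected):
        vp = pd.DataFrame(
            [dict(zip(["prop_tissue", "prop_species", "prop_residual"], props),
                  status="ok", n_observations=8)]
        )
        assert classify_genes(vp)["gene_class"].iloc[0] == expected

    def test_strict_rule_differs(self):
        # residual 0.20 but no single factor >= 0.75
        vp = pd.DataFrame(
            [{"prop_tissue": 0.60, "prop_species": 0.20, "prop_residual": 0.20,
              "status": "ok", "n_observations": 8}]
        )
        assert classify_genes(vp, rule=RESIDUAL_RULE)["gene_class"].iloc[0] == "TVG"
        assert classify_genes(vp, rule=STRICT_RULE)["gene_class"].iloc[0] == "neither"

    def test_tvg_svg_mutually_exclusive(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(3), size=200)
        vp = pd.DataFrame(
            p, columns=["prop_tissue", "prop_species", "prop_residual"]
        ).assign(status="ok", n_observations=8)
        out = classify_genes(vp)["gene_class"]
        assert set(out) <= {"TVG", "SVG", "neither"}


class TestCladeSweep:
    def test_pairwise_mode_counts(self, tree12):
        rng = np.random.default_rng(4)
        species = tree12.tip_labels
        values = make_values(rng.normal(size=(5, 24)), species)
        out = clade_sweep(values, tree12, pairwise=True)
        assert len(out) == 66  # C(12, 2)

    def test_two_species_clade_equals_pairwise_entry(self, tree12):
        rng = np.random.default_rng(6)
        species = tree12.tip_labels
        values = make_values(rng.normal(size=(8, 24)), species)
        pair = sorted(min((n.clade for n in tree12.nodes() if len(n.clade) == 2),
                          key=min))
        by_clade = clade_sweep(values, tree12, {"P": pair})["P"]
        pairwise = clade_sweep(values, tree12, pairwise=True)[f"{pair[0]}-{pair[1]}"]
        pd.testing.assert_frame_equal(by_clade, pairwise)

    def test_non_monophyletic_clade_rejected(self, tree12):
        species = tree12.tip_labels
        values = make_values(np.zeros((1, 24)), species)
        bad = [species[0], species[-1]]
        if tree12.is_monophyletic(bad):
            pytest.skip("unexpected topology")
        with pytest.raises(ValueError, match="monophyletic"):
            clade_sweep(values, tree12, {"bad": bad})

    def test_species_signal_grows_with_clade_depth(self):
        """With a fixed tissue effect and BM species divergence, the mean
        species-variance proportion rises along a nested clade ladder."""
        tree = simulate_tree(12, 3)
        cfg = SimConfig(n_species=12, n_genes=150, sigma2=1.0, de_fraction=0.0,
                        n_correlated_pairs=0, seed=3)
        species_effect, _ = simulate_bias_bm(tree, cfg)
        rng = np.random.default_rng(3)
        clades = nested_clades(tree)
        species = tree.tip_labels
        tissue_effect = {"ovary": 0.5, "carcass": 0.0}
        mat = np.empty((150, 24))
        for j, (s, t) in enumerate((s, t) for s in species for t in TISSUES):
            mat[:, j] = (
                tissue_effect[t]
                + species_effect[s].to_numpy()
                + rng.normal(0, 0.05, size=150)
            )
        sweep = clade_sweep(make_values(mat, species), tree, clades)
        counts = class_counts(sweep)
        means = counts["mean_prop_species"].to_numpy()
        assert (np.diff(means) >= -1e-6).all()
        assert counts["mean_prop_tissue"].is_monotonic_decreasing
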