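"""Bias ratios, BM ancestral reconstruction, branch changes and shifts."""

import numpy as np
import pandas as pd
import pytest

from exprphylo import parse_newick
from exprphylo.datamodel import HomologyMap
from exprphylo.phyloexpr import (
    ASRResult,
    _bm_ml_nodes,
    asr_all_genes,
    asr_bm,
    call_shifts,
    compute_bias,
    rank_swings,
    scaled_changes,
)
from exprphylo.simulate import SimConfig, simulate_bias_bm, simulate_tree
from conftest import make_table


def gls_oracle(tree, tip_values):
    """Dense solve of the normal equations of sum (dv)^2 / len."""
    nodes = list(tree.nodes())
    internal = [n for n in nodes if not n.is_leaf()]
    idx = {id(n): i for i, n in enumerate(internal)}
    A = np.zeros((len(internal), len(internal)))
    b = np.zeros(len(internal))
    for n in nodes:
        if n.parent_node is None:
            continue
        w = 1.0 / n.edge.length
        pi = idx[id(n.parent_node)]
        if n.is_leaf():
            A[pi, pi] += w
            b[pi] += w * tip_values[n.taxon.label]
        else:
            ci = idx[id(n)]
            A[pi, pi] += w
            A[ci, ci] += w
            A[pi, ci] -= w
            A[ci, pi] -= w
    sol = np.linalg.solve(A, b)
    return {tree.node_name(n): sol[idx[id(n)]] for n in internal}


class TestComputeBias:
    def _table(self, focal, reference):
        # one transcript, one species, one individual with both tissues
        return make_table([[focal, reference]], ["spaa"], ["ovary", "carcass"])

    @pytest.mark.parametrize(
        "focal,ref,expected",
        [
            (10.0, 10.0, 0.0),
            (0.0, 0.0, 0.0),
            (0.99, 0.0, np.log(100.0)),
        ],
    )
    def test_pseudocount_arithmetic(self, focal, ref, expected):
        table = self._table(focal, ref)
        table.unit = "TPM10k"
        hmap = HomologyMap(group_of={"t0": "g"})
        out = compute_bias(table, "ovary", "carcass", hmap)
        assert out.loc["g", "spaa"] == pytest.approx(expected, abs=1e-9)

    def test_ratio_before_averaging(self):
        """Per-individual ratios are averaged, not ratios of averages."""
        table = make_table(
            [[10.0, 1.0, 1.0, 10.0]], ["spaa"], ["ovary", "carcass"], n_rep=2
        )
        table.unit = "TPM10k"
        hmap = HomologyMap(group_of={"t0": "g"})
        out = compute_bias(table, "ovary", "carcass", hmap)
        expected = 0.5 * (np.log(10.01 / 1.01) + np.log(1.01 / 10.01))
        assert out.loc["g", "spaa"] == pytest.approx(expected)

    def test_species_without_pair_absent(self):
        cols = {"spaa_ovary_1": [1.0], "spaa_carcass_1": [1.0], "spab_ovary_1": [1.0]}
        values = pd.DataFrame(cols, index=["t0"])
        meta = pd.DataFrame(
            [
                ("spaa_ovary_1", "spaa", "i1", "ovary"),
                ("spaa_carcass_1", "spaa", "i1", "carcass"),
                ("spab_ovary_1", "spab", "i2", "ovary"),
            ],
            columns=["library_id", "species", "individual", "tissue"],
        ).set_index("library_id")
        from exprphylo.datamodel import ExpressionTable

        table = ExpressionTable(values, meta, unit="TPM10k")
        out = compute_bias(table, "ovary", "carcass", HomologyMap(group_of={"t0": "g"}))
        assert list(out.columns) == ["spaa"]


class TestAsr:
    def test_cherry_root_is_midpoint(self):
        tree = parse_newick("(A:1,B:1);")
        out = _bm_ml_nodes(tree, {"A": 1.0, "B": 3.0})
        assert out["root"] == pytest.approx(2.0)

    def test_constant_tips_constant_nodes(self, tree12):
        res = asr_bm(tree12, {t: 4.2 for t in tree12.tip_labels})
        assert all(v == pytest.approx(4.2) for v in res.node_values.values())

    def test_matches_gls_oracle(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(200):
            tree = simulate_tree(int(rng.integers(4, 9)), rng)
            vals = {t: float(rng.normal()) for t in tree.tip_labels}
            res = asr_bm(tree, vals)
            for name, v in gls_oracle(tree, vals).items():
                worst = max(worst, abs(v - res.node_values[name]))
        assert worst < 1e-8

    def test_convexity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tree = simulate_tree(int(rng.integers(4, 10)), rng)
            vals = {t: float(rng.normal()) for t in tree.tip_labels}
            res = asr_bm(tree, vals)
            lo, hi = min(vals.values()), max(vals.values())
            for v in res.node_values.values():
                assert lo - 1e-12 <= v <= hi + 1e-12

    def test_antisymmetry(self, tree12):
        """Swapping focal and reference negates biases, nodes and changes."""
        rng = np.random.default_rng(2)
        vals = {t: float(rng.normal()) for t in tree12.tip_labels}
        pos = asr_bm(tree12, vals, gene="g")
        neg = asr_bm(tree12, {k: -v for k, v in vals.items()}, gene="g")
        for k, v in pos.node_values.items():
            assert neg.node_values[k] == pytest.approx(-v)
        dpos = scaled_changes({"g": pos}, tree12)
        dneg = scaled_changes({"g": neg}, tree12)
        assert np.allclose(dpos.to_numpy(), -dneg.to_numpy())

    def test_too_few_tips_rejected(self, tree12):
        vals = {t: np.nan for t in tree12.tip_labels}
        for t in tree12.tip_labels[:3]:
            vals[t] = 1.0
        with pytest.raises(ValueError, match="more than three tips"):
            asr_bm(tree12, vals)

    def test_missing_tips_pruned(self, tree12):
        vals = {t: float(i) for i, t in enumerate(tree12.tip_labels)}
        dropped = tree12.tip_labels[0]
        vals[dropped] = np.nan
        res = asr_bm(tree12, vals)
        assert res.n_tips_used == 11
        assert dropped not in res.node_values

    def test_root_recovery_improves_with_smaller_rate(self, tree12):
        """Mean |reconstructed root - true root| shrinks as sigma2 shrinks."""
        errs = []
        for sigma2 in (2.0, 0.5, 0.05):
            cfg = SimConfig(n_species=12, n_genes=300, sigma2=sigma2,
                            de_fraction=0.0, n_correlated_pairs=0, seed=17)
            tips, truth = simulate_bias_bm(tree12, cfg)
            res = asr_all_genes(tree12, tips)
            err = np.mean(
                [abs(res[g].node_values["root"] - truth.node_bias.loc[g, "root"])
                 for g in tips.index]
            )
            errs.append(err)
        assert errs[0] > errs[1] > errs[2]


class TestScaledChanges:
    def _manual_result(self, tree, node_values):
        return ASRResult(
            gene="g",
            tree=tree,
            node_values=node_values,
            branch_map={b: b for b in tree.branch_ids},
            n_tips_used=tree.n_tips,
        )

    def test_difference_over_length(self):
        tree = parse_newick("((A:2,B:1):1,(C:1,D:1):1);")
        nv = {"root": 0.0, "node1": 0.0, "A": 1.0, "B": 0.0,
              "node4": 0.5, "C": 0.5, "D": 0.5}
        out = scaled_changes({"g": self._manual_result(tree, nv)}, tree)
        # branch 2 is node1 -> A: (1 - 0) / 2 = 0.5
        assert out.loc["g", 2] == pytest.approx(0.5)
        # parent == child -> zero change
        assert out.loc["g", 3] == 0.0
        assert out.loc["g", 5] == 0.0

    def test_full_gene_emits_22_changes(self, tree12):
        rng = np.random.default_rng(4)
        vals = {t: float(rng.normal()) for t in tree12.tip_labels}
        res = asr_bm(tree12, vals, gene="g")
        out = scaled_changes({"g": res}, tree12)
        assert out.shape == (1, 22)
        assert out.notna().all(axis=None)

    def test_pruned_gene_has_missing_branches(self, tree12):
        vals = {t: float(i) for i, t in enumerate(tree12.tip_labels)}
        vals[tree12.tip_labels[0]] = np.nan
        res = asr_bm(tree12, vals, gene="g")
        out = scaled_changes({"g": res}, tree12)
        assert out.shape == (1, 22)
        assert int(out.notna().sum(axis=1).iloc[0]) == 19


class TestShifts:
    def test_gain_loss_classification(self, tree4):
        # force node values via a manual ASRResult
        nv = {"root": -0.5, "node1": 0.2, "A": 0.3, "B": -0.1,
              "node4": -0.5, "C": -0.5, "D": -0.5}
        res = ASRResult("g", tree4, nv, {b: b for b in tree4.branch_ids}, 4)
        out = call_shifts({"g": res}, tree4)
        by_branch = out.set_index("branch_id")
        assert by_branch.loc[1, "direction"] == "gain"  # -0.5 -> 0.2
        assert by_branch.loc[3, "direction"] == "loss"  # 0.2 -> -0.1
        assert 2 not in by_branch.index  # 0.2 -> 0.3: no crossing

    def test_rank_swings(self, tree4):
        shifts = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3", "g4"],
                "branch_id": [1, 1, 1, 1],
                "direction": ["gain", "gain", "gain", "loss"],
                "ancestral": [-0.5, -0.25, -1.0, 0.2],
                "descendant": [0.5, 0.25, 1.0, -0.1],
                "swing": [1.0, 0.5, 2.0, 0.3],
            }
        )
        top = rank_swings(shifts, k=2)
        gains = top[top["direction"] == "gain"]["swing"].tolist()
        assert gains == [2.0, 1.0]
        assert (top[top["direction"] == "loss"]["swing"] == 0.3).all()

    def test_rank_swings_tie_break_and_bounds(self):
        shifts = pd.DataFrame(
            {
                "gene": ["gB", "gA"],
                "branch_id": [2, 1],
                "direction": ["gain", "gain"],
                "ancestral": [-1.0, -1.0],
                "descendant": [1.0, 1.0],
                "swing": [2.0, 2.0],
            }
        )
        top = rank_swings(shifts, k=1)
        assert top["gene"].tolist() == ["gA"]  # lexicographic tie break
        assert len(rank_swings(shifts, k=10)) == 2  # k beyond set -> whole set
        with pytest.raises(ValueError):
            rank_swings(shifts, k=0)

    def test_sign_changes_favor_long_branches(self):
        """Under null BM a zero crossing is more likely on a long branch."""
        from scipy import stats

        tree = simulate_tree(12, 19)
        cfg = SimConfig(n_species=12, n_genes=2000, sigma2=1.0, de_fraction=0.0,
                        n_correlated_pairs=0, seed=19)
        tips, _ = simulate_bias_bm(tree, cfg)
        res = asr_all_genes(tree, tips)
        shifts = call_shifts(res, tree)
        freq = shifts.groupby("branch_id").size().reindex(
            tree.branch_ids, fill_value=0
        )
        lengths = pd.Series(
            {r["branch_id"]: r["length"] for r in tree.branch_table()}
        )
        rho = stats.spearmanr(lengths, freq).statistic
        assert rho > 0.4
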