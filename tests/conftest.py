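import numpy as np
import pandas as pd
import pytest

from exprphylo import parse_newick
from exprphylo.datamodel import ExpressionTable
from exprphylo.simulate import SimConfig, simulate_dataset, simulate_tree

BALANCED4 = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def tree4():
    return parse_newick(BALANCED4)


@pytest.fixture(scope="session")
def tree12():
    """Balanced ultrametric 12-tip tree (depth 4)."""
    def cherry(a, b):
        return f"({a}:1,{b}:1)"
    tips = [f"t{i:02d}" for i in range(12)]
    c = [cherry(tips[i], tips[i + 1]) for i in range(0, 12, 2)]
    nwk = (
        f"((({c[0]}:1,{c[1]}:1):1,{c[2]}:2):1,"
        f"(({c[3]}:1,{c[4]}:1):1,{c[5]}:2):1);"
    )
    return parse_newick(nwk)


@pytest.fixture(scope="session")
def sim_small():
    """Small simulated dataset reused by read-only tests."""
    cfg = SimConfig(
        n_genes=80, n_correlated_pairs=6, n_decoy_interactions=8, seed=42
    )
    return simulate_dataset(cfg)


def make_table(values: np.ndarray, species, tissues, n_rep=1, prefix="t"):
    """Build an ExpressionTable with one library per (species, tissue,
    replicate); ``values`` is transcripts x libraries in that column order."""
    cols, meta = [], []
    for s in species:
        for r in range(1, n_rep + 1):
            for t in tissues:
                lib = f"{s}_{t}_{r}"
                cols.append(lib)
                meta.append((lib, s, f"{s}_i{r}", t))
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values, index=[f"{prefix}{i}" for i in range(values.shape[0])], columns=cols
    )
    meta_df = pd.DataFrame(
        meta, columns=["library_id", "species", "individual", "tissue"]
    ).set_index("library_id")
    return ExpressionTable(df, meta_df)
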