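"""Rooted species trees with stable branch identities.

A rooted bifurcating tree with n tips has 2n-2 edges.  Every edge is given
a stable integer id (1..2n-2) by a deterministic convention: a pre-order
traversal in which the children of every node are visited in alphabetical
order of their smallest descendant tip label.  Branch ids therefore depend
only on the topology and tip labels, not on the rotation of the newick
string.

Branch identity across genes is defined on the *full* species tree by the
(parent node, child node) pair of an edge, with nodes identified by their
descendant tip sets.  When tips are dropped for a gene (missing expression
data), the pruned tree's edges are matched back to full-tree edges only
where both endpoints survive: an edge created by collapsing a path through
a removed node has no full-tree equivalent and is excluded from cross-gene
comparison.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = ["Phylogeny", "read_tree", "parse_newick"]

ULTRAMETRIC_RTOL = 1e-6


class Phylogeny:
    """A rooted, strictly bifurcating tree with positive branch lengths.

    Wraps a :class:`dendropy.Tree`; every node carries

    ``clade``
        frozenset of descendant tip labels (a tip's clade is itself),
    ``branch_id``
        integer id of the edge above the node (``None`` for the root).
    """

    def __init__(self, tree: dendropy.Tree) -> None:
        self._tree = tree
        self._validate_and_number()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def _validate_and_number(self) -> None:
        tree = self._tree
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("unlabeled tip in tree")
        # postorder: clades, child ordering key, validation
        for node in tree.postorder_node_iter():
            children = node.child_nodes()
            if children and len(children) != 2:
                labels = sorted(
                    min(c.clade) for c in children
                ) if all(hasattr(c, "clade") for c in children) else []
                raise ValueError(
                    f"tree is not strictly bifurcating: node with "
                    f"{len(children)} children (subtrees led by {labels})"
                )
            if node.parent_node is not None:
                if node.edge.length is None:
                    raise ValueError("missing branch length in tree")
                if node.edge.length <= 0:
                    raise ValueError(
                        f"non-positive branch length {node.edge.length}"
                    )
            if children:
                node.clade = frozenset().union(*(c.clade for c in children))
            else:
                node.clade = frozenset({node.taxon.label})
        if len(tree.seed_node.clade) < 2:
            raise ValueError("tree must have at least 2 tips")
        # deterministic child order: by smallest descendant tip label
        for node in tree.preorder_node_iter():
            node._child_nodes.sort(key=lambda c: min(c.clade))
        # pre-order branch numbering, root edge excluded
        next_id = 1
        tree.seed_node.branch_id = None
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            node.branch_id = next_id
            next_id += 1
        self._by_clade = {n.clade: n for n in tree.preorder_node_iter()}
        # tip depths for ultrametricity
        depth: dict[int, float] = {id(tree.seed_node): 0.0}
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
        tip_depths = [depth[id(l)] for l in tree.leaf_node_iter()]
        self._node_depth = depth
        self.max_depth = max(tip_depths)
        self.is_ultrametric = (
            (max(tip_depths) - min(tip_depths)) / max(tip_depths)
            <= ULTRAMETRIC_RTOL
        )

    # -- basic queries ----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return sorted(l.taxon.label for l in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_branches(self) -> int:
        return 2 * self.n_tips - 2

    @property
    def branch_ids(self) -> list[int]:
        return list(range(1, self.n_branches + 1))

    def nodes(self) -> Iterable[dendropy.Node]:
        """Nodes in the deterministic pre-order."""
        return self._tree.preorder_node_iter()

    def node_name(self, node: dendropy.Node) -> str:
        """Stable printable name: tip label, 'root', or 'node<branch_id>'
        (the id of the edge above the node)."""
        if node.is_leaf():
            return node.taxon.label
        if node.parent_node is None:
            return "root"
        return f"node{node.branch_id}"

    def branch_table(self) -> list[dict]:
        """One row per branch: id, parent/child node names, length."""
        rows = []
        for node in self.nodes():
            if node.parent_node is None:
                continue
            rows.append(
                {
                    "branch_id": node.branch_id,
                    "parent": self.node_name(node.parent_node),
                    "child": self.node_name(node),
                    "length": node.edge.length,
                }
            )
        return rows

    def mrca(self, tips: Iterable[str]) -> dendropy.Node:
        """Most recent common ancestor of a set of tip labels."""
        tipset = frozenset(tips)
        unknown = tipset - frozenset(self.tip_labels)
        if unknown:
            raise KeyError(f"tips not in tree: {sorted(unknown)}")
        best = None
        for clade, node in self._by_clade.items():
            if tipset <= clade and (best is None or len(clade) < len(best.clade)):
                best = node
        assert best is not None
        return best

    def is_monophyletic(self, tips: Iterable[str]) -> bool:
        return self.mrca(tips).clade == frozenset(tips)

    def depth_of(self, node: dendropy.Node) -> float:
        return self._node_depth[id(node)]

    # -- pruning and branch equivalence -----------------------------------

    def prune_to(self, tips: Sequence[str]) -> tuple["Phylogeny", dict[int, int | None]]:
        """Restrict the tree to ``tips``.

        Returns the pruned :class:`Phylogeny` (unifurcations collapsed,
        path lengths summed) and a map from each pruned-tree branch id to
        the equivalent full-tree branch id, or ``None`` for pruned edges
        whose endpoints are not adjacent in the full tree.
        """
        keep = frozenset(tips)
        unknown = keep - frozenset(self.tip_labels)
        if unknown:
            raise KeyError(f"tips not in tree: {sorted(unknown)}")
        if len(keep) < 2:
            raise ValueError("cannot prune to fewer than 2 tips")
        sub = self._tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        pruned = Phylogeny(sub)
        branch_map: dict[int, int | None] = {}
        for node in pruned.nodes():
            if node.parent_node is None:
                continue
            full_child = self.mrca(node.clade)
            full_parent = self.mrca(node.parent_node.clade)
            if full_child.parent_node is full_parent:
                branch_map[node.branch_id] = full_child.branch_id
            else:
                branch_map[node.branch_id] = None
        return pruned, branch_map

    # -- serialization ----------------------------------------------------

    def to_newick(self, *, internal_labels: bool = False) -> str:
        def fmt(node: dendropy.Node) -> str:
            if node.is_leaf():
                name = node.taxon.label
            else:
                inner = ",".join(fmt(c) for c in node.child_nodes())
                name = f"({inner})"
                if internal_labels and node.parent_node is not None:
                    name += f"node{node.branch_id}"
            if node.parent_node is not None:
                name += f":{node.edge.length:.10g}"
            return name

        return fmt(self._tree.seed_node) + ";"

    def write(self, path, **kw) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    def __repr__(self) -> str:
        return f"<Phylogeny {self.n_tips} tips, {self.n_branches} branches>"


def parse_newick(newick: str) -> Phylogeny:
    return Phylogeny.from_newick(newick)


def read_tree(path) -> Phylogeny:
    """Read a rooted bifurcating tree with branch lengths from a newick file."""
    with open(path) as fh:
        return parse_newick(fh.read())
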