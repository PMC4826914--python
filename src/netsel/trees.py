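"""Species-tree handling: Newick IO (via dendropy) and a flat array form.

The likelihood and simulation engines both traverse the tree many times per
gene, so the dendropy tree is converted once into a postorder array
representation (`ArrayTree`) holding, for every node, its children and the
length of the branch above it.  Branch lengths are expected substitutions
per codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class ArrayTree:
    """Rooted tree in postorder arrays.

    Nodes 0..n_tips-1 are tips (in `tip_labels` order); internal nodes
    follow in postorder, the root last.  `branch_lengths[i]` is the length
    of the edge above node i (the root entry is 0 and unused).
    """

    tip_labels: list[str]
    children: list[list[int]]
    branch_lengths: np.ndarray
    postorder_internal: list[int] = field(default_factory=list)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.postorder_internal[-1]

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths[: self.n_nodes].sum())

    def scaled(self, total: float) -> "ArrayTree":
        """Return a copy with branch lengths rescaled to the given total."""
        cur = self.total_length
        if cur <= 0:
            raise ValueError("cannot rescale a zero-length tree")
        return ArrayTree(
            tip_labels=list(self.tip_labels),
            children=[list(c) for c in self.children],
            branch_lengths=self.branch_lengths * (total / cur),
            postorder_internal=list(self.postorder_internal),
        )

    def preorder_edges(self):
        """(parent, child, branch_length) triples, root first."""
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            for child in self.children[node]:
                order.append((node, child, float(self.branch_lengths[child])))
                stack.append(child)
        return order


def from_newick(newick: str) -> ArrayTree:
    """Parse a Newick string (or file content) into an ArrayTree.

    Missing branch lengths default to 0. The tree must have >= 2 leaves.
    """
    dtree = dendropy.Tree.get(data=newick, schema="newick")
    return from_dendropy(dtree)


def from_newick_file(path) -> ArrayTree:
    dtree = dendropy.Tree.get(path=str(path), schema="newick")
    return from_dendropy(dtree)


def from_dendropy(dtree: dendropy.Tree) -> ArrayTree:
    leaves = [lf for lf in dtree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    tip_labels = [lf.taxon.label if lf.taxon else str(i) for i, lf in enumerate(leaves)]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    nodes = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
    for k, nd in enumerate(nodes):
        index[id(nd)] = len(leaves) + k

    n_nodes = len(leaves) + len(nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    blens = np.zeros(n_nodes)
    for nd in dtree.postorder_node_iter():
        i = index[id(nd)]
        blens[i] = nd.edge.length if nd.edge.length is not None else 0.0
        if not nd.is_leaf():
            children[i] = [index[id(ch)] for ch in nd.child_nodes()]
    blens[index[id(dtree.seed_node)]] = 0.0
    return ArrayTree(
        tip_labels=tip_labels,
        children=children,
        branch_lengths=blens,
        postorder_internal=[index[id(nd)] for nd in nodes],
    )


def tip_path_lengths(tree: ArrayTree) -> np.ndarray:
    """Pairwise patristic distances between tips, shape (n_tips, n_tips)."""
    n = tree.n_nodes
    parent = np.full(n, -1)
    for node in range(n):
        for child in tree.children[node]:
            parent[child] = node
    depth = np.zeros(n)
    order = [tree.root]
    while order:
        node = order.pop()
        for child in tree.children[node]:
            depth[child] = depth[node] + tree.branch_lengths[child]
            order.append(child)
    ancestors = []
    for tip in range(tree.n_tips):
        path = {}
        node = tip
        while node != -1:
            path[node] = depth[node]
            node = parent[node]
        ancestors.append(path)
    out = np.zeros((tree.n_tips, tree.n_tips))
    for i in range(tree.n_tips):
        for j in range(i + 1, tree.n_tips):
            common = max(
                ancestors[i][a] for a in ancestors[i].keys() & ancestors[j].keys()
            )
            out[i, j] = out[j, i] = depth[i] + depth[j] - 2 * common
    return out


def to_newick(tree: ArrayTree) -> str:
    def fmt(node: int) -> str:
        if node < tree.n_tips:
            label = tree.tip_labels[node]
        else:
            label = ""
        if tree.children[node]:
            inner = ",".join(
                f"{fmt(ch)}:{tree.branch_lengths[ch]:.6f}" for ch in tree.children[node]
            )
            return f"({inner}){label}"
        return label

    return fmt(tree.root) + ";"


def default_tree(n_taxa: int, total_length: float = 2.0) -> ArrayTree:
    """A ladder-shaped reference phylogeny for 5 or 6 taxa.

    The shape mimics a clade of closely related species (a species ladder
    with progressively longer external branches); total tree length is a
    free parameter and defaults to 2 expected substitutions per codon.
    """
    if n_taxa == 5:
        newick = "((((t1:0.10,t2:0.10):0.05,t3:0.18):0.06,t4:0.28):0.08,t5:0.40);"
    elif n_taxa == 6:
        newick = "(((((t1:0.08,t2:0.08):0.04,t3:0.14):0.05,t4:0.22):0.06,t5:0.32):0.07,t6:0.42);"
    else:
        raise ValueError("default trees are provided for 5 or 6 taxa")
    return from_newick(newick).scaled(total_length)
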