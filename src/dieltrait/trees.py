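"""Phylogenetic tree utilities.

Newick I/O goes through dendropy; numerical work (likelihoods, branch-length
transforms, patristic distances) uses a flat array representation so the
optimiser can re-transform branch lengths thousands of times cheaply.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

ULTRAMETRIC_TOL = 1e-9


@dataclass(frozen=True)
class TreeArrays:
    """Rooted tree as arrays.

    Nodes are indexed 0..n_nodes-1 in a postorder; tips occupy indices
    0..n_tips-1 in label order of ``labels``. ``parent[i]`` is the parent
    index (-1 for the root, which is the last node in postorder);
    ``edge_length[i]`` is the branch above node i (0 for the root).
    """

    labels: tuple[str, ...]
    parent: np.ndarray
    edge_length: np.ndarray
    postorder: np.ndarray

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    def is_tip(self) -> np.ndarray:
        out = np.zeros(self.n_nodes, dtype=bool)
        out[: self.n_tips] = True
        return out

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        depth = np.zeros(self.n_nodes)
        for i in self.postorder[::-1]:
            if self.parent[i] >= 0:
                depth[i] = depth[self.parent[i]] + self.edge_length[i]
        return depth

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        tip_depths = self.depths()[: self.n_tips]
        return float(tip_depths.max() - tip_depths.min()) <= tol

    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())


def from_dendropy(tree: dendropy.Tree) -> TreeArrays:
    nodes = list(tree.postorder_node_iter())
    tips = [nd for nd in nodes if nd.is_leaf()]
    labels = tuple(sorted(nd.taxon.label for nd in tips))
    tip_index = {lab: i for i, lab in enumerate(labels)}
    internal = [nd for nd in nodes if not nd.is_leaf()]
    index: dict[int, int] = {}
    for nd in tips:
        index[id(nd)] = tip_index[nd.taxon.label]
    for j, nd in enumerate(internal):
        index[id(nd)] = len(labels) + j
    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    edge = np.zeros(n)
    post = np.empty(n, dtype=np.int64)
    for k, nd in enumerate(nodes):
        i = index[id(nd)]
        post[k] = i
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            edge[i] = nd.edge.length if nd.edge.length is not None else 0.0
    return TreeArrays(labels=labels, parent=parent, edge_length=edge, postorder=post)


def to_dendropy(tree: TreeArrays) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(list(tree.labels))
    nodes = [dendropy.Node() for _ in range(tree.n_nodes)]
    for i, lab in enumerate(tree.labels):
        nodes[i].taxon = taxa.get_taxon(lab)
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            nodes[p].add_child(nodes[i])
            nodes[i].edge.length = float(tree.edge_length[i])
    out = dendropy.Tree(taxon_namespace=taxa)
    out.seed_node = nodes[tree.root]
    return out


def to_newick(tree: TreeArrays) -> str:
    return to_dendropy(tree).as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(path) -> list[TreeArrays]:
    """Read a (multi-)tree Newick file, one tree per line."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    return [from_dendropy(t) for t in trees]


def write_newick(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(to_newick(t) + "\n")


def children_lists(tree: TreeArrays) -> list[list[int]]:
    kids: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            kids[p].append(i)
    return kids


def patristic_distances(tree: TreeArrays) -> np.ndarray:
    """Tip-to-tip path-length matrix, rows/cols in ``tree.labels`` order."""
    n = tree.n_tips
    depth = tree.depths()
    kids = children_lists(tree)
    tipsets: dict[int, np.ndarray] = {}
    D = np.zeros((n, n))
    for i in tree.postorder:
        if i < n:
            tipsets[i] = np.array([i], dtype=np.int64)
            continue
        groups = [tipsets.pop(c) for c in kids[i]]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ga, gb = groups[a], groups[b]
                d = depth[ga][:, None] + depth[gb][None, :] - 2.0 * depth[i]
                D[np.ix_(ga, gb)] = d
                D[np.ix_(gb, ga)] = d.T
        tipsets[i] = np.concatenate(groups)
    return D
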