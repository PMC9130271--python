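"""Rooted, time-calibrated phylogenetic trees and phylogenetic covariance.

Trees are stored as flat parent/branch-length arrays for fast likelihood and
simulation code; dendropy handles all Newick/NEXUS parsing and writing.
Branch lengths are in million years (My) throughout the package.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeParseError",
    "UltrametryReport",
    "CovarianceStructure",
    "read_tree",
    "write_tree",
    "check_ultrametric",
    "mrca_depth_matrix",
    "bm_covariance",
]

#: default relative tolerance for ultrametricity checks; dated trees from
#: Bayesian samplers carry rounding noise at this level.
ULTRAMETRIC_RTOL = 1e-6


class TreeParseError(ValueError):
    """Raised when a tree file cannot be parsed or violates input contracts."""


class PhyloTree:
    """A rooted phylogenetic tree with branch lengths.

    Nodes are integers ``0 .. n_nodes-1``. ``parent[i]`` is the parent of node
    ``i`` (``-1`` for the root) and ``lengths[i]`` is the length of the branch
    subtending node ``i`` (``0`` for the root). Tips carry string labels.

    Parameters
    ----------
    parent : array of int
        Parent index per node, -1 for the single root.
    lengths : array of float
        Branch length (My) subtending each node; all >= 0.
    labels : sequence of str or None
        Per-node labels; every tip (childless node) must be labelled and tip
        labels must be unique. Labels are whitespace-trimmed.
    """

    def __init__(self, parent, lengths, labels):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = [str(l).strip() if l is not None else None for l in labels]
        n = self.parent.size
        if self.lengths.size != n or len(self.labels) != n:
            raise ValueError("parent, lengths and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeParseError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if np.any(self.lengths < 0):
            raise TreeParseError("negative branch length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        self.tips = np.array([i for i in range(n) if not self.children[i]], dtype=np.int64)
        tip_labels = [self.labels[i] for i in self.tips]
        if any(l is None or l == "" for l in tip_labels):
            raise TreeParseError("all tips must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            raise TreeParseError("tip labels must be unique")
        self.tip_labels: list[str] = tip_labels
        self._tip_index = {l: k for k, l in enumerate(tip_labels)}
        # postorder: children before parents
        order: list[int] = []
        stack = [self.root]
        while stack:
            u = stack.pop()
            order.append(u)
            stack.extend(self.children[u])
        self.preorder = np.array(order, dtype=np.int64)
        self.postorder = self.preorder[::-1].copy()
        self.depths = np.zeros(n)
        for u in self.preorder:
            if u != self.root:
                self.depths[u] = self.depths[self.parent[u]] + self.lengths[u]

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return self.tips.size

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth (tree height, My)."""
        return float(self.depths[self.tips].max())

    def tip_index(self, label: str) -> int:
        """Position of `label` in :attr:`tip_labels` (the covariance order)."""
        try:
            return self._tip_index[label.strip()]
        except KeyError:
            raise KeyError(f"unknown tip label {label!r}") from None

    def tip_depths(self) -> np.ndarray:
        return self.depths[self.tips]

    def path_to_tip(self, tip_node: int) -> list[int]:
        """Nodes from (just below) the root down to `tip_node`, inclusive."""
        path = []
        u = tip_node
        while u != self.root:
            path.append(u)
            u = self.parent[u]
        return path[::-1]

    # ------------------------------------------------------------- conversion
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label and nd.is_leaf():
                labels[i] = nd.label
        return cls(parent, lengths, labels)

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)
        dnodes = {self.root: dtree.seed_node}
        for u in self.preorder:
            if u == self.root:
                continue
            ch = dnodes[self.parent[u]].new_child(edge_length=float(self.lengths[u]))
            dnodes[u] = ch
        for u in self.tips:
            dnodes[u].taxon = tns.require_taxon(label=self.labels[u])
        dtree.is_rooted = True
        return dtree

    def prune_to(self, keep_labels) -> "PhyloTree":
        """Restrict the tree to `keep_labels`, suppressing unifurcations.

        The stem above the MRCA of the retained tips is dropped, so the new
        root is that MRCA (the convention of standard pruning tools).
        """
        keep = [l.strip() for l in keep_labels]
        missing = set(keep) - set(self.tip_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        dtree = self.to_dendropy()
        dtree2 = dtree.extract_tree_with_taxa_labels(labels=keep)
        # drop a dangling root edge left by the extraction
        if dtree2.seed_node.edge.length:
            dtree2.seed_node.edge.length = None
        return PhyloTree.from_dendropy(dtree2)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree {self.n_tips} tips, height {self.height:.4g} My>"


# ---------------------------------------------------------------------- I/O
def read_tree(path, format: str = "newick") -> PhyloTree:
    """Read a rooted tree from a Newick or NEXUS file.

    Trees without an explicit rooting token are treated as rooted (dated trees
    are rooted by construction); an explicit ``[&U]`` flag raises an error.
    """
    if format not in ("newick", "nexus"):
        raise ValueError(f"format must be 'newick' or 'nexus', got {format!r}")
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema=format, suppress_internal_node_taxa=True,
            rooting='default-rooted',
        )
    except Exception as exc:  # dendropy raises various error classes
        raise TreeParseError(f"could not parse {path} as {format}: {exc}") from exc
    if dtree.is_rooted is False:
        raise TreeParseError("input tree is explicitly unrooted; a rooted tree is required")
    return PhyloTree.from_dendropy(dtree)


def read_trees(path, format: str = "newick") -> list[PhyloTree]:
    """Read every tree in a file (e.g. a posterior sample)."""
    tl = dendropy.TreeList.get(path=str(path), schema=format, rooting='default-rooted')
    return [PhyloTree.from_dendropy(t) for t in tl]


def write_tree(tree: PhyloTree, path, format: str = "newick") -> None:
    """Write a tree; branch lengths use 17 significant digits (round-trip safe)."""
    dtree = tree.to_dendropy()
    kwargs = {"real_value_format_specifier": ".17g"}
    if format == "newick":
        dtree.write(path=str(path), schema="newick", suppress_rooting=True, **kwargs)
    elif format == "nexus":
        dtree.write(path=str(path), schema="nexus", **kwargs)
    else:
        raise ValueError(f"format must be 'newick' or 'nexus', got {format!r}")


def newick_string(tree: PhyloTree) -> str:
    buf = io.StringIO()
    tree.to_dendropy().write(file=buf, schema="newick", suppress_rooting=True,
                             real_value_format_specifier=".17g")
    return buf.getvalue().strip()


def tree_from_newick(s: str) -> PhyloTree:
    dtree = dendropy.Tree.get(data=s, schema="newick", rooting='default-rooted',
                              suppress_internal_node_taxa=True)
    return PhyloTree.from_dendropy(dtree)


# ------------------------------------------------------------- ultrametricity
@dataclass(frozen=True)
class UltrametryReport:
    is_ultrametric: bool
    max_deviation: float
    height: float
    rtol: float


def check_ultrametric(tree: PhyloTree, rtol: float = ULTRAMETRIC_RTOL) -> UltrametryReport:
    """Check that all root-to-tip depths agree within ``rtol * height``."""
    if tree.n_tips < 2:
        raise ValueError("ultrametricity is only defined for trees with >= 2 tips")
    d = tree.tip_depths()
    height = float(d.max())
    dev = float(d.max() - d.min())
    return UltrametryReport(dev <= rtol * height, dev, height, rtol)


# ----------------------------------------------------------------- covariance
@dataclass
class CovarianceStructure:
    """A species-by-species trait covariance implied by an evolutionary model."""

    kind: str                      # "BM" or "OU"
    parameters: dict
    matrix: np.ndarray             # (n_tips, n_tips), order = labels
    labels: list[str] = field(default_factory=list)

    def is_psd(self, rtol: float = 1e-8) -> bool:
        w = np.linalg.eigvalsh(self.matrix)
        return bool(w[0] >= -rtol * max(w[-1], 1.0))


def mrca_depth_matrix(tree: PhyloTree) -> np.ndarray:
    """Shared root-to-MRCA path length for every tip pair.

    Entry (i, i) is the depth of tip i. Order follows ``tree.tip_labels``.
    """
    n = tree.n_tips
    C = np.zeros((n, n))
    tip_pos = {int(t): k for k, t in enumerate(tree.tips)}
    below: dict[int, list[int]] = {}
    for u in tree.postorder:
        if not tree.children[u]:
            below[u] = [tip_pos[u]]
            C[tip_pos[u], tip_pos[u]] = tree.depths[u]
        else:
            kids = [below.pop(c) for c in tree.children[u]]
            d = tree.depths[u]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        C[i, kids[b]] = d
                        C[kids[b], i] = d
            merged = [i for k in kids for i in k]
            below[u] = merged
    return C


def bm_covariance(tree: PhyloTree, sigma2: float = 1.0) -> CovarianceStructure:
    """Brownian-motion trait covariance: sigma2 x shared path length."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    C = sigma2 * mrca_depth_matrix(tree)
    return CovarianceStructure("BM", {"sigma2": sigma2}, C, list(tree.tip_labels))
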