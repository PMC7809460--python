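"""Trees and the phylogenetic correlation structure.

Provides 50% majority-rule consensus over a sample of rooted trees,
seeded random resolution of polytomies with epsilon-length branches, and
conversion of an (approximately) ultrametric tree into the species
correlation matrix expected under Brownian motion: the correlation
between two tips is their shared root-to-MRCA path length divided by the
tree depth.  Newick reading/writing is delegated to dendropy.
"""

from __future__ import annotations

import itertools
import random
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeSample",
    "PhyloCorrelation",
    "read_tree",
    "read_tree_sample",
    "write_tree",
    "majority_consensus",
    "resolve_polytomies",
    "tree_to_correlation",
]


def read_tree(path: str, preserve_underscores: bool = True) -> dendropy.Tree:
    """Read a single rooted Newick tree from a file.

    ``preserve_underscores`` keeps unquoted underscores in labels verbatim
    instead of translating them to spaces (the Newick convention); species
    tables in this package use underscore-joined binomials.
    """
    return dendropy.Tree.get(
        path=path,
        schema="newick",
        rooting="default-rooted",
        preserve_underscores=preserve_underscores,
    )


def read_tree_sample(path: str, preserve_underscores: bool = True) -> "TreeSample":
    """Read a multi-tree Newick file (one tree per line) as a TreeSample."""
    trees = dendropy.TreeList.get(
        path=path,
        schema="newick",
        rooting="default-rooted",
        preserve_underscores=preserve_underscores,
    )
    return TreeSample(trees=list(trees))


def write_tree(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True, unquoted_underscores=True)


def _tip_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


@dataclass
class TreeSample:
    """An ordered collection of rooted trees over one common tip set."""

    trees: list[dendropy.Tree]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.trees) < 1:
            raise ValueError("a tree sample needs at least one tree")
        tips = _tip_labels(self.trees[0])
        for t in self.trees[1:]:
            if _tip_labels(t) != tips:
                raise ValueError("tip-set mismatch across trees in the sample")
        if self.weights is None:
            self.weights = np.ones(len(self.trees))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.trees),):
                raise ValueError("one weight per tree required")
            if np.any(self.weights <= 0):
                raise ValueError("tree weights must be positive")

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def tip_labels(self) -> frozenset[str]:
        return _tip_labels(self.trees[0])


def _clades_with_lengths(tree: dendropy.Tree) -> dict[frozenset[str], float | None]:
    """Map every clade (tip-label set, including singletons) to its edge length."""
    out: dict[frozenset[str], float | None] = {}
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clade = frozenset([node.taxon.label])
        else:
            clade = frozenset(itertools.chain.from_iterable(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = clade
        out[clade] = node.edge.length
    return out


def majority_consensus(sample: TreeSample, threshold: float = 0.5) -> dendropy.Tree:
    """Majority-rule consensus tree of a sample of rooted trees.

    Retains exactly the clades whose (weight-) frequency across the sample
    strictly exceeds ``threshold``; the branch length of a retained clade
    is the mean of its lengths over the trees that contain it.  The
    default threshold of 0.5 is the classical 50% majority rule, which
    guarantees the retained clades are mutually compatible.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    weights = sample.weights
    total = float(weights.sum())
    tips = sorted(sample.tip_labels)
    all_tips = frozenset(tips)

    freq: dict[frozenset[str], float] = {}
    len_sum: dict[frozenset[str], float] = {}
    len_cnt: dict[frozenset[str], float] = {}
    for tree, w in zip(sample.trees, weights):
        for clade, length in _clades_with_lengths(tree).items():
            freq[clade] = freq.get(clade, 0.0) + w
            if length is not None:
                len_sum[clade] = len_sum.get(clade, 0.0) + w * length
                len_cnt[clade] = len_cnt.get(clade, 0.0) + w

    def mean_length(clade: frozenset[str]) -> float | None:
        if len_cnt.get(clade, 0.0) > 0:
            return len_sum[clade] / len_cnt[clade]
        return None

    retained = [
        c
        for c in freq
        if 1 < len(c) < len(tips) and freq[c] / total > threshold
    ]
    # Sanity: at threshold >= 0.5 retained clades are automatically compatible.
    for a, b in itertools.combinations(retained, 2):
        if a & b and not (a <= b or b <= a):
            raise ValueError("retained clades are incompatible; raise the threshold")

    taxon_ns = dendropy.TaxonNamespace(tips)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    nodes: dict[frozenset[str], dendropy.Node] = {all_tips: tree.seed_node}

    # Attach each clade under the smallest strict superset already placed.
    for clade in sorted(retained, key=len, reverse=True):
        parents = [c for c in nodes if clade < c]
        parent = min(parents, key=len)
        node = dendropy.Node()
        node.edge.length = mean_length(clade)
        nodes[parent].add_child(node)
        nodes[clade] = node
    for tip in tips:
        clade = frozenset([tip])
        parents = [c for c in nodes if clade < c]
        parent = min(parents, key=len)
        node = dendropy.Node(taxon=taxon_ns.get_taxon(tip))
        node.edge.length = mean_length(clade)
        nodes[parent].add_child(node)
    return tree


def resolve_polytomies(
    tree: dendropy.Tree, epsilon: float = 1e-8, seed: int | None = None
) -> dendropy.Tree:
    """Randomly resolve multifurcations into bifurcations.

    Repeatedly groups two randomly chosen children of each polytomy under
    a new internal node whose branch gets length ``epsilon`` (default
    1e-8, a negligible distance that merely breaks the tie).  A binary
    tree is returned unchanged (as a copy).  The resolution is
    deterministic for a fixed ``seed``.
    """
    rng = random.Random(seed)
    out = tree.clone(depth=1)
    for node in list(out.preorder_node_iter()):
        children = node.child_nodes()
        while len(children) > 2:
            pair = rng.sample(range(len(children)), 2)
            a, b = (children[i] for i in sorted(pair))
            for c in (a, b):
                node.remove_child(c)
            merged = dendropy.Node()
            merged.edge.length = epsilon
            merged.add_child(a)
            merged.add_child(b)
            node.add_child(merged)
            children = node.child_nodes()
    return out


@dataclass(frozen=True)
class PhyloCorrelation:
    """Species-by-species correlation matrix with a label-keyed index."""

    labels: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh((m + m.T) / 2).min() < -1e-8:
            raise ValueError("correlation matrix is not positive semidefinite")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def loc(self, labels: Sequence[str]) -> "PhyloCorrelation":
        """Submatrix restricted to (and reordered by) the given labels."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"species not in correlation matrix: {missing}")
        idx = np.array([index[lab] for lab in labels])
        return PhyloCorrelation(tuple(labels), self.matrix[np.ix_(idx, idx)])

    def expand(self, labels: Sequence[str]) -> np.ndarray:
        """Correlation matrix among (possibly repeated) species labels."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        idx = np.array([index[str(lab)] for lab in labels])
        return self.matrix[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def tree_to_correlation(tree: dendropy.Tree) -> PhyloCorrelation:
    """Brownian-motion correlation matrix implied by a rooted tree.

    Entry (i, j) is the root-to-MRCA path length of tips i and j divided
    by the tree depth; the diagonal is exactly one.  For inputs that are
    not exactly ultrametric the per-pair denominator is the mean of the
    two root-to-tip depths, and a warning is emitted.
    """
    depth: dict[int, float] = {}
    tip_depth: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        length = node.edge.length
        if length is None:
            length = 0.0
        if length < 0:
            raise ValueError("negative branch length")
        parent = node.parent_node
        depth[id(node)] = (depth[id(parent)] if parent is not None else 0.0) + length
        if node.is_leaf():
            tip_depth[node.taxon.label] = depth[id(node)]

    labels = sorted(tip_depth)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two tips")
    index = {lab: i for i, lab in enumerate(labels)}
    depths = np.array([tip_depth[lab] for lab in labels])
    dmax = depths.max()
    if dmax <= 0:
        raise ValueError("tree has zero depth")
    if (depths.max() - depths.min()) / dmax > 1e-6:
        warnings.warn(
            "tree is not ultrametric; using per-pair mean root-to-tip depth",
            stacklevel=2,
        )

    shared = np.zeros((n, n))
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = np.array([index[node.taxon.label]])
            continue
        kids = [below[id(c)] for c in node.child_nodes()]
        d = depth[id(node)]
        for a, b in itertools.combinations(kids, 2):
            shared[np.ix_(a, b)] = d
            shared[np.ix_(b, a)] = d
        below[id(node)] = np.concatenate(kids)

    denom = (depths[:, None] + depths[None, :]) / 2.0
    with np.errstate(invalid="ignore"):
        corr = np.where(denom > 0, shared / denom, 0.0)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip((corr + corr.T) / 2.0, 0.0, 1.0)
    return PhyloCorrelation(tuple(labels), corr)
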