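"""Rooted phylogenies and comparative-method primitives.

The container is deliberately small: a rooted tree stored as parent-pointer
arrays in topological order (every node's parent has a smaller index, the
root is node 0).  Newick reading and writing is delegated to dendropy; all
comparative computations -- Grafen branch lengths, pruning, patristic
(cophenetic) distances and the Brownian-motion variance-covariance matrix --
operate directly on the arrays.

Branch lengths are either present for every non-root branch or absent for
the whole tree (the form delivered by topology-only tree subsetting, from
which Grafen lengths are then computed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import dendropy


class NewickError(ValueError):
    """Raised for malformed or unsupported Newick input."""


class PhyloTree:
    """Rooted tree with labelled tips and optional branch lengths.

    Parameters
    ----------
    parent
        Integer array of length ``n_nodes``; ``parent[0] == -1`` (the root)
        and ``parent[i] < i`` for every other node.
    labels
        One entry per node; tips (nodes without children) carry unique,
        non-empty strings, internal nodes ``None``.
    lengths
        Branch length of the edge above each node (ignored for the root), or
        ``None`` if the tree carries no branch lengths.  All lengths must be
        non-negative.
    """

    __slots__ = ("parent", "labels", "lengths", "_children")

    def __init__(
        self,
        parent: Sequence[int],
        labels: Sequence[Optional[str]],
        lengths: Optional[Sequence[float]] = None,
    ):
        parent = np.asarray(parent, dtype=np.intp)
        if parent.ndim != 1 or parent.size < 3:
            raise ValueError("a tree needs at least a root and two tips")
        if parent[0] != -1:
            raise ValueError("node 0 must be the root (parent -1)")
        if np.any(parent[1:] < 0) or np.any(parent[1:] >= np.arange(1, parent.size)):
            raise ValueError("nodes must be in topological order (parent index < node index)")
        self.parent = parent
        self.parent.setflags(write=False)

        labels = tuple(labels)
        if len(labels) != parent.size:
            raise ValueError("labels must have one entry per node")
        self.labels = labels

        children: list[list[int]] = [[] for _ in range(parent.size)]
        for i in range(1, parent.size):
            children[parent[i]].append(i)
        self._children = tuple(tuple(c) for c in children)

        tip_labels = []
        for i, kids in enumerate(self._children):
            if not kids:
                lab = labels[i]
                if not lab:
                    raise ValueError(f"empty label on tip node {i}")
                tip_labels.append(lab)
        if len(tip_labels) < 2:
            raise ValueError("a tree needs at least 2 tips")
        dupes = {x for x in tip_labels if tip_labels.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate tip label(s): {sorted(dupes)}")

        if lengths is not None:
            lengths = np.array(lengths, dtype=float)
            if lengths.shape != parent.shape:
                raise ValueError("lengths must have one entry per node")
            lengths[0] = 0.0
            if not np.all(np.isfinite(lengths)) or np.any(lengths < 0):
                raise ValueError("branch lengths must be finite and non-negative")
            lengths.setflags(write=False)
        self.lengths = lengths

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    def children(self, i: int) -> tuple[int, ...]:
        return self._children[i]

    @property
    def tip_indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.n_nodes) if not self._children[i])

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.tip_indices)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def has_branch_lengths(self) -> bool:
        return self.lengths is not None

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths (requires branch lengths)."""
        self._require_lengths()
        depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.lengths[i]
        return depth

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        return PhyloTree(self.parent, self.labels, lengths)

    def _require_lengths(self) -> None:
        if self.lengths is None:
            raise ValueError("tree has no branch lengths (compute Grafen lengths first)")

    def __repr__(self) -> str:  # pragma: no cover
        bl = "with" if self.has_branch_lengths else "without"
        return f"<PhyloTree {self.n_tips} tips, {self.n_nodes} nodes, {bl} branch lengths>"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative matrix with a zero diagonal, keyed by tip labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("diagonal must be zero")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion covariance structure of a rooted tree.

    ``matrix[i, j]`` is the root-to-MRCA path length shared by tips ``i`` and
    ``j``; the diagonal holds root-to-tip depths.  Positive semi-definite by
    construction, which is validated on creation.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if c.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        scale = max(1.0, float(np.max(np.diag(c))))
        if np.any(np.diag(c)[:, None] + 1e-10 * scale < c):
            raise ValueError("diagonal must dominate each row")
        w = np.linalg.eigvalsh((c + c.T) / 2.0)
        if w[0] < -1e-8 * scale:
            raise ValueError("covariance must be positive semi-definite")
        object.__setattr__(self, "matrix", c)
        object.__setattr__(self, "labels", tuple(self.labels))


# ---------------------------------------------------------------------------
# Newick I/O (dendropy backend)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Polytomies are accepted.  Branch lengths must annotate all branches or
    none.  Explicitly unrooted input (``[&U]``) is rejected because node
    heights and the Brownian covariance require a root.
    """
    if not isinstance(text, str) or ";" not in text:
        raise NewickError("Newick string must be terminated by ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="default-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except NewickError:
        raise
    except Exception as exc:
        raise NewickError(f"malformed Newick: {exc}") from None
    if not dtree.is_rooted:
        raise NewickError("unrooted Newick input ([&U]) is not supported; supply a rooted tree")

    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = [-1] * len(nodes)
    labels: list[Optional[str]] = [None] * len(nodes)
    raw_lengths: list[Optional[float]] = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            raw_lengths[i] = nd.edge.length
        if nd.is_leaf():
            labels[i] = nd.taxon.label if nd.taxon is not None else (nd.label or None)

    non_root = raw_lengths[1:]
    if all(x is None for x in non_root):
        lengths = None
    elif any(x is None for x in non_root):
        raise NewickError("branch lengths must be present on all branches or none")
    else:
        lengths = np.array([0.0] + [float(x) for x in non_root])

    try:
        return PhyloTree(parent, labels, lengths)
    except ValueError as exc:
        raise NewickError(str(exc)) from None


def write_newick(tree: PhyloTree, precision: int = 10) -> str:
    """Serialize to Newick; lengths written to ``precision`` significant digits."""
    dtree = _to_dendropy(tree)
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_edge_lengths=not tree.has_branch_lengths,
        unquoted_underscores=True,
        real_value_format_specifier=f".{precision}g",
    )
    return text.strip()


def _to_dendropy(tree: PhyloTree) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    dnodes = [dendropy.Node() for _ in range(tree.n_nodes)]
    for i in range(1, tree.n_nodes):
        dnodes[tree.parent[i]].add_child(dnodes[i])
        if tree.has_branch_lengths:
            dnodes[i].edge.length = float(tree.lengths[i])
    for i in tree.tip_indices:
        dnodes[i].taxon = tns.require_taxon(label=tree.labels[i])
    dtree = dendropy.Tree(taxon_namespace=tns)
    dtree.seed_node = dnodes[0]
    dtree.is_rooted = True
    return dtree


# ---------------------------------------------------------------------------
# Comparative primitives
# ---------------------------------------------------------------------------

def grafen_branch_lengths(tree: PhyloTree, rho: float = 1.0) -> PhyloTree:
    """Assign Grafen branch lengths from topology alone.

    Each node gets height ``((t_v - 1)/(n - 1)) ** rho`` where ``t_v`` counts
    its tip descendants and ``n`` is the total tip count; a branch's length is
    the height difference between its endpoints.  The result is ultrametric
    with root height exactly 1.  Existing branch lengths are ignored.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    n = tree.n_tips
    if n < 2:
        raise ValueError("need at least 2 tips")
    tip_count = np.zeros(tree.n_nodes)
    for i in range(tree.n_nodes - 1, 0, -1):
        if not tree.children(i):
            tip_count[i] = 1.0
        tip_count[tree.parent[i]] += tip_count[i]
    if not tree.children(0):
        tip_count[0] = 1.0  # unreachable for valid trees; kept for safety
    height = ((tip_count - 1.0) / (n - 1.0)) ** rho
    lengths = np.zeros(tree.n_nodes)
    lengths[1:] = height[tree.parent[1:]] - height[1:]
    return tree.with_lengths(lengths)


def prune_to_taxa(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Restrict the tree to ``keep`` tips.

    Internal nodes left with a single child are suppressed and their incident
    branch lengths summed, so root-to-tip path lengths of retained tips are
    unchanged.  A root left with one child is retained (dropping it would
    shorten every retained root-to-tip path).
    """
    keep = set(keep)
    tip_set = set(tree.tip_labels)
    unknown = keep - tip_set
    if unknown:
        raise ValueError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 tips to keep")

    n = tree.n_nodes
    kept_below = np.zeros(n, dtype=np.intp)  # kept tips in/below each node
    for i in range(n - 1, 0, -1):
        if not tree.children(i):
            kept_below[i] = 1 if tree.labels[i] in keep else 0
        kept_below[tree.parent[i]] += kept_below[i]

    survive = np.zeros(n, dtype=bool)
    survive[0] = True
    for i in range(1, n):
        if kept_below[i] == 0:
            continue
        kids = tree.children(i)
        if not kids:
            survive[i] = True
        else:
            live_kids = sum(1 for c in kids if kept_below[c] > 0)
            survive[i] = live_kids >= 2
    # walk each surviving node up to its nearest surviving ancestor,
    # accumulating suppressed branch lengths
    new_index = np.cumsum(survive) - 1
    parent_new: list[int] = []
    labels_new: list[Optional[str]] = []
    lengths_new: list[float] = []
    for i in range(n):
        if not survive[i]:
            continue
        if i == 0:
            parent_new.append(-1)
            lengths_new.append(0.0)
        else:
            acc = tree.lengths[i] if tree.has_branch_lengths else 0.0
            j = tree.parent[i]
            while not survive[j]:
                if tree.has_branch_lengths:
                    acc += tree.lengths[j]
                j = tree.parent[j]
            parent_new.append(int(new_index[j]))
            lengths_new.append(float(acc))
        labels_new.append(tree.labels[i])
    return PhyloTree(
        parent_new,
        labels_new,
        np.array(lengths_new) if tree.has_branch_lengths else None,
    )


def patristic_distances(tree: PhyloTree) -> DistanceMatrix:
    """Cophenetic matrix: path-length sums between every pair of tips."""
    tree._require_lengths()
    tips = tree.tip_indices
    n = len(tips)
    # per-tip ancestor -> distance-from-tip map, walking to the root
    anc: list[dict[int, float]] = []
    for t in tips:
        d: dict[int, float] = {t: 0.0}
        j, acc = t, 0.0
        while j != 0:
            acc += tree.lengths[j]
            j = tree.parent[j]
            d[j] = acc
        anc.append(d)
    out = np.zeros((n, n))
    for a in range(n):
        da = anc[a]
        for b in range(a + 1, n):
            # first ancestor-of-b that is also an ancestor-of-a is the MRCA
            j, acc = tips[b], 0.0
            while j not in da:
                acc += tree.lengths[j]
                j = tree.parent[j]
            out[a, b] = out[b, a] = acc + da[j]
    return DistanceMatrix(tree.tip_labels, out)


def phylo_vcv(tree: PhyloTree) -> PhyloCovariance:
    """Brownian-motion covariance: shared root-to-MRCA path length per pair."""
    tree._require_lengths()
    tips = tree.tip_indices
    n = len(tips)
    # indicator of branches on the root-to-tip path; C = B diag(len) B'
    b = np.zeros((n, tree.n_nodes))
    for k, t in enumerate(tips):
        j = t
        while j != 0:
            b[k, j] = 1.0
            j = tree.parent[j]
    c = (b * tree.lengths) @ b.T
    c = (c + c.T) / 2.0
    return PhyloCovariance(tree.tip_labels, c)


def is_ultrametric(tree: PhyloTree, tol: float = 1e-8) -> bool:
    """True when all root-to-tip depths agree within ``tol``."""
    depths = tree.node_depths()[list(tree.tip_indices)]
    return bool(depths.max() - depths.min() <= tol)
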