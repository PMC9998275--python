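"""Phylogeny container and tree operations.

Trees are held in a flat array representation (parent pointers, branch
lengths, labels) that keeps traversals iterative — important for the
deep, ~1,000-tip time trees this package targets, where recursive
algorithms would overflow the interpreter stack.  Newick and NEXUS
parsing and serialization are delegated to dendropy.

Branch lengths are in millions of years (Myr) throughout; node ages are
measured backwards from the present, defined as the maximum root-to-tip
depth.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import DomainError, FormatError

__all__ = [
    "Phylogeny",
    "read_trees",
    "bipartition_lengths",
    "bsd_distance",
    "bsd_matrix",
    "centroid_tree",
    "node_ages",
]


class Phylogeny:
    """A rooted tree with branch lengths, unique tip labels and stable
    internal-node identifiers.

    Nodes are indexed ``0 .. n_nodes-1`` with the root at index 0 and a
    preorder-compatible ordering (every parent precedes its children).
    Tips carry their taxon label; internal nodes get identifiers
    ``N1, N2, ...`` assigned in preorder (root = ``N1``) unless labels
    were supplied.
    """

    def __init__(
        self,
        parent: Sequence[int],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        n = len(self.parent)
        if len(self.lengths) != n or len(labels) != n:
            raise ValueError("parent, lengths and labels must have equal size")
        if self.parent[0] != -1 or np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("nodes must be ordered with every parent before its children")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        if not np.all(self.lengths[1:] >= 0):
            raise FormatError("negative branch length")
        # stable identifiers: tip label for tips, N<k> in preorder otherwise
        self.node_id: list[str] = []
        counter = 0
        for i in range(n):
            if self.is_tip[i]:
                if labels[i] is None:
                    raise FormatError(f"tip node {i} has no label")
                self.node_id.append(str(labels[i]))
            else:
                counter += 1
                self.node_id.append(
                    str(labels[i]) if labels[i] not in (None, "") else f"N{counter}"
                )
        tips = [self.node_id[i] for i in np.flatnonzero(self.is_tip)]
        if len(set(tips)) != len(tips):
            raise FormatError("tip labels are not unique")

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def internal_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_tip)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_labels(self) -> list[str]:
        return [self.node_id[i] for i in self.tip_indices]

    def preorder(self) -> range:
        return range(self.n_nodes)  # construction guarantees preorder

    def postorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node, in branch-length units."""
        depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.lengths[i]
        return depth

    def node_ages(self) -> dict[str, float]:
        """Age of every node in Myr before the present.

        The present is the maximum root-to-tip depth, so tips of an
        ultrametric tree get age 0 exactly.  Non-ultrametric trees are
        accepted with a warning; their shallower tips get positive ages.
        """
        depth = self.node_depths()
        height = depth[self.is_tip].max()
        tip_ages = height - depth[self.is_tip]
        if tip_ages.max() > 1e-6 * max(height, 1.0):
            warnings.warn(
                "tree is not ultrametric; node ages measured from the deepest tip",
                stacklevel=2,
            )
        return {self.node_id[i]: float(height - depth[i]) for i in range(self.n_nodes)}

    def tip_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """All pairwise tip-to-tip path lengths (for exact checks)."""
        depth = self.node_depths()
        tips = self.tip_indices
        # ancestor sets per tip
        anc: list[set[int]] = []
        for t in tips:
            s, u = set(), int(t)
            while u != -1:
                s.add(u)
                u = int(self.parent[u])
            anc.append(s)
        m = len(tips)
        out = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                mrca_depth = max(depth[u] for u in anc[a] & anc[b])
                out[a, b] = out[b, a] = depth[tips[a]] + depth[tips[b]] - 2 * mrca_depth
        return [self.node_id[t] for t in tips], out

    def clade_tips(self) -> list[frozenset[str]]:
        """For every node, the set of tip labels in its subtree."""
        below: list[set[str] | None] = [None] * self.n_nodes
        for i in self.postorder():
            if self.is_tip[i]:
                below[i] = {self.node_id[i]}
            else:
                acc: set[str] = set()
                for c in self.children[i]:
                    acc |= below[c]  # type: ignore[arg-type]
                below[i] = acc
        return [frozenset(s) for s in below]  # type: ignore[arg-type]

    # ------------------------------------------------------------------
    # conversion
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        for i, nd in enumerate(nodes):
            if i == 0:
                parent.append(-1)
                lengths.append(0.0)
            else:
                parent.append(index[id(nd.parent_node)])
                if nd.edge.length is None:
                    raise FormatError(
                        "tree has a branch without a length; time-calibrated "
                        "branch lengths are required"
                    )
                lengths.append(float(nd.edge.length))
            if nd.is_leaf():
                if nd.taxon is not None:
                    labels.append(nd.taxon.label)
                else:
                    labels.append(nd.label)
            else:
                labels.append(nd.label)
        return cls(parent, lengths, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="default-rooted",
            preserve_underscores=True,
        )
        return cls.from_dendropy(dtree)

    def to_dendropy(
        self, taxon_namespace: dendropy.TaxonNamespace | None = None
    ) -> dendropy.Tree:
        ns = taxon_namespace or dendropy.TaxonNamespace()
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.is_tip[i]:
                dnodes[i].taxon = ns.require_taxon(label=self.node_id[i])
            if i > 0:
                dnodes[self.parent[i]].add_child(dnodes[i])
                dnodes[i].edge.length = float(self.lengths[i])
        tree = dendropy.Tree(taxon_namespace=ns)
        tree.seed_node = dnodes[0]
        tree.is_rooted = True
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # ------------------------------------------------------------------
    # pruning
    # ------------------------------------------------------------------
    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        """Induced subtree on the tip set ``keep``.

        Degree-2 nodes created by the removal are suppressed, with their
        incident branch lengths summed, so path lengths between every
        retained tip pair are preserved exactly.  The new root is the
        most recent common ancestor of the kept tips.
        """
        keep = set(keep)
        tip_set = set(self.tip_labels)
        unknown = keep - tip_set
        if unknown:
            raise DomainError(f"labels not in tree: {sorted(unknown)[:5]}")
        if len(keep) < 2:
            raise DomainError("need at least 2 tips to prune to")

        # postorder: surviving subtree per node as (kind, payload, pending_len)
        surv: list[tuple | None] = [None] * self.n_nodes
        for i in self.postorder():
            if self.is_tip[i]:
                if self.node_id[i] in keep:
                    surv[i] = ("tip", self.node_id[i], float(self.lengths[i]))
            else:
                kids = [surv[c] for c in self.children[i] if surv[c] is not None]
                if not kids:
                    surv[i] = None
                elif len(kids) == 1:
                    kind, payload, plen = kids[0]
                    surv[i] = (kind, payload, plen + float(self.lengths[i]))
                else:
                    surv[i] = ("node", kids, float(self.lengths[i]))
        root_s = surv[0]
        assert root_s is not None
        # new root carries no branch; rebuild arrays in preorder
        parent: list[int] = []
        lengths: list[float] = []
        labels: list[str | None] = []
        stack = [(root_s[0], root_s[1], 0.0, -1)]
        while stack:
            kind, payload, plen, par = stack.pop()
            idx = len(parent)
            parent.append(par)
            lengths.append(plen)
            labels.append(payload if kind == "tip" else None)
            if kind == "node":
                for child in reversed(payload):
                    stack.append((child[0], child[1], child[2], idx))
        return Phylogeny(parent, lengths, labels)


def read_trees(path: str | Path, schema: str | None = None) -> list[Phylogeny]:
    """Read one or more rooted trees from a Newick or NEXUS file.

    The format is inferred from the extension when ``schema`` is None
    (``.nex``/``.nexus`` → NEXUS, anything else → Newick).  NEXUS
    translate tables are resolved transparently.  A tree explicitly
    flagged unrooted, or one with missing branch lengths, is rejected.
    """
    path = Path(path)
    if schema is None:
        schema = "nexus" if path.suffix.lower() in (".nex", ".nexus", ".nxs") else "newick"
    if schema not in ("newick", "nexus"):
        raise FormatError(f"unsupported tree format {schema!r}")
    try:
        tlist = dendropy.TreeList.get(
            path=str(path),
            schema=schema,
            rooting="default-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"could not parse {path}: {exc}") from exc
    trees = []
    for dtree in tlist:
        if dtree.is_rooted is False:
            raise FormatError(f"{path}: tree explicitly flagged unrooted")
        trees.append(Phylogeny.from_dendropy(dtree))
    if not trees:
        raise FormatError(f"{path}: no trees found")
    return trees


# ----------------------------------------------------------------------
# branch score distance
# ----------------------------------------------------------------------
def bipartition_lengths(
    tree: Phylogeny, merge_root_edges: bool = True
) -> dict[frozenset[str], float]:
    """Map each edge's bipartition (canonical form) to its branch length.

    Bipartitions are canonicalized against a fixed tip ordering: the
    side *not* containing the alphabetically first tip represents the
    split.  Under this unrooted convention the two child edges of a
    bifurcating root collapse onto the same bipartition and their
    lengths are summed (``merge_root_edges=True``, the default, which
    matches unrooted branch score distance conventions).  With
    ``merge_root_edges=False`` edges are keyed by their raw subtree tip
    set, so the root's two edges stay distinct.
    """
    all_tips = frozenset(tree.tip_labels)
    ref = min(all_tips)
    below = tree.clade_tips()
    out: dict[frozenset[str], float] = {}
    for i in range(1, tree.n_nodes):
        side = below[i]
        if merge_root_edges:
            key = side if ref not in side else all_tips - side
        else:
            key = side
        if not key or key == all_tips:
            continue
        out[key] = out.get(key, 0.0) + float(tree.lengths[i])
    return out


def bsd_distance(
    t1: Phylogeny, t2: Phylogeny, merge_root_edges: bool = True
) -> float:
    """Branch score distance between two trees on the same tip set.

    The square root of the sum of squared branch-length differences over
    the union of bipartitions; a bipartition absent from one tree
    contributes length 0 there.  Symmetric, zero iff the two trees have
    identical bipartition→length maps.
    """
    if set(t1.tip_labels) != set(t2.tip_labels):
        raise DomainError("branch score distance requires identical tip sets")
    m1 = bipartition_lengths(t1, merge_root_edges)
    m2 = bipartition_lengths(t2, merge_root_edges)
    total = 0.0
    for key in m1.keys() | m2.keys():
        diff = m1.get(key, 0.0) - m2.get(key, 0.0)
        total += diff * diff
    return float(np.sqrt(total))


def bsd_matrix(
    trees: Sequence[Phylogeny], merge_root_edges: bool = True
) -> np.ndarray:
    """Symmetric matrix of pairwise branch score distances."""
    maps = [bipartition_lengths(t, merge_root_edges) for t in trees]
    tipsets = [set(t.tip_labels) for t in trees]
    if any(ts != tipsets[0] for ts in tipsets[1:]):
        raise DomainError("all trees must share one tip set")
    n = len(trees)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            total = 0.0
            mi, mj = maps[i], maps[j]
            for key in mi.keys() | mj.keys():
                diff = mi.get(key, 0.0) - mj.get(key, 0.0)
                total += diff * diff
            out[i, j] = out[j, i] = np.sqrt(total)
    return out


def centroid_tree(
    trees: Sequence[Phylogeny], merge_root_edges: bool = True
) -> tuple[int, np.ndarray]:
    """Index of the tree minimizing summed distance to all others.

    Computes the full pairwise branch score distance matrix, sums it
    column-wise and returns the 0-based index of the minimizing tree
    (ties broken by lowest index) along with the matrix.
    """
    if len(trees) < 2:
        raise DomainError("centroid selection needs at least 2 trees")
    matrix = bsd_matrix(trees, merge_root_edges)
    sums = matrix.sum(axis=0)
    return int(np.argmin(sums)), matrix


def node_ages(tree: Phylogeny) -> dict[str, float]:
    """Ages of all nodes in Myr before present (see Phylogeny.node_ages)."""
    return tree.node_ages()
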