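"""Rooted phylogenies and the topology-processing stages of the pipeline.

The central object is :class:`PhyloTree`, a compact array-backed rooted tree
with uniquely labeled tips and non-negative branch lengths.  Nodes are stored
in preorder (every node's parent has a smaller index, the root is node 0), so
pre- and postorder traversals are plain index sweeps and whole-tree copies are
array copies.  Newick reading and writing is delegated to dendropy.

On top of the structure this module provides patristic distances,
Robinson–Foulds (symmetric) topology distances, ranking of posterior topology
samples against a family-level backbone, random selection, and clade
(bipartition) support frequencies.

A bipartition/split is represented canonically as a ``frozenset`` of the two
``frozenset`` sides, which makes it independent of side order and hashable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "NewickError",
    "PhyloTree",
    "TopologySet",
    "parse_newick",
    "write_newick",
    "patristic_distances",
    "bipartitions",
    "rf_distance",
    "condensed_splits",
    "rf_to_backbone",
    "rank_and_select",
    "random_select",
    "clade_support",
    "read_family_map",
]

Split = frozenset  # frozenset({frozenset(side_a), frozenset(side_b)})


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tip labels."""


class PhyloTree:
    """A rooted phylogenetic tree with labeled tips.

    Parameters
    ----------
    parent
        Integer array of length ``m``; ``parent[0] == -1`` (root) and
        ``parent[i] < i`` for all other nodes (preorder storage).
    children
        Sequence of index tuples, one per node (empty for tips).
    lengths
        Branch length of the edge subtending each node (``lengths[0]`` is
        ignored and kept at 0).  Must be non-negative.
    labels
        One entry per node; tips must carry unique non-empty labels,
        internal nodes may be ``None``.
    """

    __slots__ = ("parent", "children", "lengths", "labels", "_tips", "_lab2idx")

    def __init__(self, parent, children, lengths, labels, validate=True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = tuple(tuple(c) for c in children)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        self.labels = tuple(labels)
        self._tips = np.array(
            [i for i, c in enumerate(self.children) if not c], dtype=np.int64
        )
        self._lab2idx = {self.labels[i]: i for i in self._tips}
        if validate:
            self._validate()

    def _validate(self):
        m = self.n_nodes
        if m == 0 or self.parent[0] != -1:
            raise ValueError("node 0 must be the root (parent -1)")
        if m > 1 and not np.all(self.parent[1:] < np.arange(1, m)):
            raise ValueError("nodes must be stored in preorder (parent[i] < i)")
        if np.any(self.lengths[1:] < 0):
            raise ValueError("negative branch length")
        for i, p in enumerate(self.parent[1:], start=1):
            if i not in self.children[p]:
                raise ValueError("children/parent arrays inconsistent")
        seen = set()
        for i in self._tips:
            lab = self.labels[i]
            if not lab:
                raise NewickError("tip without label")
            if lab in seen:
                raise NewickError(f"duplicate tip label: {lab!r}")
            seen.add(lab)

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_indices(self) -> np.ndarray:
        return self._tips

    @property
    def tip_labels(self) -> tuple:
        return tuple(self.labels[i] for i in self._tips)

    @property
    def taxon_set(self) -> frozenset:
        return frozenset(self._lab2idx)

    def tip_index(self, label: str) -> int:
        try:
            return self._lab2idx[label]
        except KeyError:
            raise KeyError(f"tip label not in tree: {label!r}") from None

    @property
    def total_length(self) -> float:
        return float(self.lengths[1:].sum())

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        par, ln = self.parent, self.lengths
        for i in range(1, self.n_nodes):
            d[i] = d[par[i]] + ln[i]
        return d

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = self.node_depths()[self._tips]
        h = d.max()
        return h == 0 or (d.max() - d.min()) <= rel_tol * h

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.parent.copy(), self.children, self.lengths.copy(), self.labels,
            validate=False,
        )

    def with_lengths(self, lengths) -> "PhyloTree":
        """Same topology, new branch lengths (cheap constructor)."""
        t = PhyloTree(self.parent, self.children, lengths, self.labels,
                      validate=False)
        if np.any(t.lengths[1:] < 0):
            raise ValueError("negative branch length")
        return t

    # -- construction -----------------------------------------------------

    @classmethod
    def from_links(cls, root, children_of: Mapping[int, Sequence[int]],
                   length_of: Mapping[int, float],
                   label_of: Mapping[int, str]) -> "PhyloTree":
        """Build from arbitrarily-indexed parent/child links (re-indexes
        the nodes in preorder)."""
        order = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(children_of.get(v, ())))
        new = {v: i for i, v in enumerate(order)}
        m = len(order)
        parent = np.full(m, -1, dtype=np.int64)
        lengths = np.zeros(m)
        children: list[list[int]] = [[] for _ in range(m)]
        labels: list = [None] * m
        for v in order:
            i = new[v]
            labels[i] = label_of.get(v)
            if v != root:
                lengths[i] = length_of.get(v, 0.0)
            for c in children_of.get(v, ()):
                children[i].append(new[c])
                parent[new[c]] = i
        return cls(parent, children, lengths, labels)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree,
                      default_length: float | None = None) -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        m = len(nodes)
        parent = np.full(m, -1, dtype=np.int64)
        lengths = np.zeros(m)
        children: list[list[int]] = [[] for _ in range(m)]
        labels: list = [None] * m
        missing = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = idx[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                if nd.edge.length is None:
                    missing += 1
                    lengths[i] = 0.0
                else:
                    lengths[i] = nd.edge.length
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon is not None else nd.label
        if missing and default_length is None:
            warnings.warn(
                f"{missing} branch length(s) missing in Newick input; "
                "defaulting to 0", stacklevel=3,
            )
        return cls(parent, children, lengths, labels)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None
                    ) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=tns)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            nd = nodes[i]
            if i > 0:
                nodes[self.parent[i]].add_child(nd)
                nd.edge.length = float(self.lengths[i])
            if not self.children[i]:
                nd.taxon = tns.require_taxon(label=self.labels[i])
        dtree.seed_node = nodes[0]
        return dtree

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        trees = parse_newick(text)
        if len(trees) != 1:
            raise NewickError(f"expected exactly one tree, found {len(trees)}")
        return trees[0]

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True
        ).strip()

    def __repr__(self):
        return f"<PhyloTree {self.n_tips} tips, {self.n_nodes} nodes>"


# -- Newick I/O -----------------------------------------------------------


def parse_newick(source: str | Path) -> list[PhyloTree]:
    """Parse one or more Newick trees from a string or file.

    Multi-tree input is supported (one tree per ';'-terminated statement).
    Missing branch lengths default to 0 with a warning; duplicate tip labels
    or malformed syntax raise :class:`NewickError` naming the offender.
    """
    if isinstance(source, Path):
        kwargs = {"path": str(source)}
    elif "(" in source or ";" in source:
        kwargs = {"data": source}
    else:
        kwargs = {"path": source}
    try:
        tl = dendropy.TreeList.get(
            schema="newick", suppress_internal_node_taxa=True, **kwargs
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # dendropy raises assorted error classes
        raise NewickError(f"malformed Newick input: {exc}") from exc
    return [PhyloTree.from_dendropy(t) for t in tl]


def write_newick(trees: PhyloTree | Iterable[PhyloTree], path: str | Path) -> None:
    """Write one or several trees to a Newick file, one per line."""
    if isinstance(trees, PhyloTree):
        trees = [trees]
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


# -- distances ------------------------------------------------------------


def _patristic(tree: PhyloTree):
    """Tip × tip path-length matrix, ordered as ``tree.tip_indices``.

    Uses the identity d(i, j) = depth_i + depth_j - 2 * depth_mrca(i, j) and
    fills the matrix one internal node at a time (each node is the MRCA of
    the tip pairs split across its child subtrees).
    """
    depths = tree.node_depths()
    tips = tree.tip_indices
    pos = np.full(tree.n_nodes, -1, dtype=np.int64)
    pos[tips] = np.arange(len(tips))
    tiplists: list = [None] * tree.n_nodes
    for i in range(tree.n_nodes - 1, -1, -1):
        ch = tree.children[i]
        if not ch:
            tiplists[i] = np.array([pos[i]])
        else:
            tiplists[i] = np.concatenate([tiplists[c] for c in ch])
    td = depths[tips]
    n = len(tips)
    D = np.zeros((n, n))
    for i in range(tree.n_nodes):
        ch = tree.children[i]
        for a in range(len(ch)):
            for b in range(a + 1, len(ch)):
                A, B = tiplists[ch[a]], tiplists[ch[b]]
                block = td[A][:, None] + td[B][None, :] - 2.0 * depths[i]
                D[np.ix_(A, B)] = block
                D[np.ix_(B, A)] = block.T
    return D


def patristic_distances(tree: PhyloTree) -> "pandas.DataFrame":
    """Symmetric tip × tip patristic distance matrix as a DataFrame."""
    import pandas as pd

    D = _patristic(tree)
    labels = list(tree.tip_labels)
    return pd.DataFrame(D, index=labels, columns=labels)


def _clades(tree: PhyloTree) -> list:
    """Tip-label set below each node (index-aligned list of frozensets)."""
    out: list = [None] * tree.n_nodes
    for i in range(tree.n_nodes - 1, -1, -1):
        ch = tree.children[i]
        if not ch:
            out[i] = frozenset((tree.labels[i],))
        else:
            s = set()
            for c in ch:
                s |= out[c]
            out[i] = frozenset(s)
    return out


def bipartitions(tree: PhyloTree) -> set:
    """Non-trivial unrooted bipartitions (splits) of the tree's tip set.

    Each split is ``frozenset({side_a, side_b})`` with both sides of size
    ≥ 2; the rooted position of the tree does not affect the result.
    """
    full = tree.taxon_set
    clades = _clades(tree)
    out = set()
    for i in range(1, tree.n_nodes):
        c = clades[i]
        if len(c) < 2 or len(c) > len(full) - 2:
            continue
        out.add(frozenset((c, full - c)))
    return out


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson–Foulds symmetric distance (unrooted, non-trivial splits)."""
    s1, s2 = t1.taxon_set, t2.taxon_set
    if s1 != s2:
        raise ValueError(
            "trees have different tip sets; only in first: "
            f"{sorted(s1 - s2)}, only in second: {sorted(s2 - s1)}"
        )
    return len(bipartitions(t1) ^ bipartitions(t2))


# -- family-level backbone comparison -------------------------------------


def read_family_map(path: str | Path) -> dict:
    """Read a two-column species,family CSV into a dict."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("family map CSV needs two columns (species, family)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def condensed_splits(tree: PhyloTree, family_map: Mapping[str, str]) -> set:
    """Family-level splits induced by the species tree.

    Each internal edge splits the species set in two; the split is kept if no
    family straddles both sides ("clean" split) and is then expressed on the
    family label set.  A species tree in which every family is monophyletic
    and arranged as in a family backbone yields exactly the backbone's
    splits; non-monophyletic families produce fewer clean splits and hence a
    larger symmetric distance.
    """
    missing = tree.taxon_set - set(family_map)
    if missing:
        raise KeyError(f"species missing from family map: {sorted(missing)[:5]}")
    fams = frozenset(family_map[s] for s in tree.taxon_set)
    clades = _clades(tree)
    out = set()
    for i in range(1, tree.n_nodes):
        side = frozenset(family_map[s] for s in clades[i])
        other = frozenset(
            family_map[s] for s in tree.taxon_set - clades[i]
        )
        if side & other:
            continue  # some family straddles the split
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(frozenset((side, other)))
    return out


def rf_to_backbone(tree: PhyloTree, backbone: PhyloTree,
                   family_map: Mapping[str, str] | None = None) -> int:
    """Symmetric distance between a (species) tree and a backbone topology.

    With ``family_map`` the species tree is condensed to family-level splits
    first; without it this is the plain RF distance.
    """
    if family_map is None:
        return rf_distance(tree, backbone)
    sp = condensed_splits(tree, family_map)
    fams = frozenset(family_map[s] for s in tree.taxon_set)
    if fams != backbone.taxon_set:
        raise ValueError(
            "family set of tree does not match backbone tips; difference: "
            f"{sorted(fams ^ backbone.taxon_set)}"
        )
    return len(sp ^ bipartitions(backbone))


# -- topology sets --------------------------------------------------------


@dataclass
class TopologySet:
    """An ordered collection of trees over a common tip set.

    ``condition`` carries the barcode/backbone indicators of the supermatrix
    the trees were inferred from; ``rf_backbone`` (when set) holds each
    tree's symmetric distance to the family backbone, aligned with ``trees``.
    """

    trees: list
    condition: "Condition | None" = None
    rf_backbone: list | None = field(default=None)

    def __post_init__(self):
        if not self.trees:
            raise ValueError("TopologySet needs at least one tree")
        ts = self.trees[0].taxon_set
        for i, t in enumerate(self.trees[1:], start=1):
            if t.taxon_set != ts:
                raise ValueError(f"tree {i} has a different tip set")

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @property
    def taxon_set(self):
        return self.trees[0].taxon_set


def rank_and_select(trees: Sequence[PhyloTree], backbone: PhyloTree,
                    k: int, family_map: Mapping[str, str] | None = None,
                    condition=None) -> TopologySet:
    """Keep the ``k`` trees closest to the backbone by symmetric distance.

    Ordering is stable: ties at the cutoff are broken by original input
    position.  The returned set records each kept tree's distance.
    """
    if k < 1 or k > len(trees):
        raise ValueError(f"k={k} outside 1..{len(trees)}")
    dists = [rf_to_backbone(t, backbone, family_map) for t in trees]
    order = sorted(range(len(trees)), key=lambda i: dists[i])[:k]
    return TopologySet(
        trees=[trees[i] for i in order],
        condition=condition,
        rf_backbone=[dists[i] for i in order],
    )


def random_select(trees: Sequence[PhyloTree], k: int, seed,
                  condition=None) -> TopologySet:
    """Sample ``k`` trees uniformly without replacement (seed-deterministic)."""
    if k < 1 or k > len(trees):
        raise ValueError(f"k={k} outside 1..{len(trees)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(trees), size=k, replace=False)
    return TopologySet(trees=[trees[i] for i in idx], condition=condition)


def clade_support(ts: TopologySet) -> dict:
    """Frequency of every observed bipartition across the set's trees.

    The analogue of node posterior probabilities over a posterior topology
    sample: a split present in 250 of 500 trees has support 0.5.
    """
    counts: dict = {}
    for t in ts.trees:
        for split in bipartitions(t):
            counts[split] = counts.get(split, 0) + 1
    n = len(ts.trees)
    return {s: c / n for s, c in counts.items()}
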