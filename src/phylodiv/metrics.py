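"""Community phylogenetic diversity metrics.

Seven metrics are computed per plot on a given tree:

* **PD** — Faith's phylogenetic diversity: total branch length of the
  subtree spanning the community's species, including the path to the tree
  root (root-inclusive, so a single-lineage community is still defined).
* **MPD / MPD_ed** — mean pairwise patristic distance among the community's
  species; the ``_ed`` variant weights each unordered pair (i, j), i ≠ j, by
  the abundance product n_i·n_j.
* **MNTD / MNTD_ed** — mean nearest-taxon distance; the weighted variant
  averages each species' nearest-neighbour distance with weights n_i.
* **PAE** — phylogenetic-abundance evenness,
  ``[PD + Σ T_i (n_i − 1)] / [PD + (N/S − 1) Σ T_i]`` with T_i the terminal
  branch length of species i on the community subtree, N the total number of
  individuals and S the species richness; 1 when abundances are even.
* **IAC** — imbalance of abundances among clades: ``Σ |n_i − n̂_i| / v``
  where n̂_i is the abundance expected when N is split equally among the
  daughter lineages at every node of the community subtree (rooted at the
  MRCA of the community) and v is the number of nodes with ≥ 2 daughters.

Communities with fewer than two species yield NaN (flagged, logged) rather
than raising, so pipelines survive degenerate plots.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .trees import PhyloTree, TopologySet, _patristic

__all__ = [
    "CommunityMatrix",
    "faith_pd",
    "mpd",
    "mntd",
    "pae",
    "iac",
    "compute_diversity_table",
    "ALL_METRICS",
]

logger = logging.getLogger(__name__)

ALL_METRICS = ("PD", "MPD", "MPD_ed", "MNTD", "MNTD_ed", "PAE", "IAC")

#: diversity-table columns, long format
TABLE_COLUMNS = (
    "metric", "value", "tree_index",
    "rbcL", "matK", "ITS", "ITS2", "backbone", "plot",
)


class CommunityMatrix:
    """Plot × species abundance table (non-negative integers).

    Thin wrapper over a pandas DataFrame whose index holds plot identifiers
    and whose columns are species labels.
    """

    def __init__(self, table: pd.DataFrame):
        if table.columns.duplicated().any():
            raise ValueError("duplicate species columns")
        vals = table.to_numpy()
        if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
            raise ValueError("abundances must be non-negative integers")
        self.table = table.astype(int)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CommunityMatrix":
        """First column = plot id, remaining columns = species abundances."""
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="plot")

    @property
    def plots(self) -> list:
        return list(self.table.index)

    @property
    def species(self) -> list:
        return list(self.table.columns)

    def abundances(self, plot) -> pd.Series:
        """Abundances of the species present (n ≥ 1) in one plot."""
        row = self.table.loc[plot]
        return row[row > 0]

    def richness(self, plot) -> int:
        return int((self.table.loc[plot] > 0).sum())


# -- helpers ---------------------------------------------------------------


def _present_and_counts(community) -> tuple[list, np.ndarray]:
    """Normalize a community argument to (labels, counts).

    Accepts a mapping species -> abundance (entries with n <= 0 treated as
    absent) or a bare iterable of present species (abundance 1 each).
    """
    if isinstance(community, Mapping):
        items = [(str(k), int(v)) for k, v in community.items() if v > 0]
    elif isinstance(community, pd.Series):
        items = [(str(k), int(v)) for k, v in community.items() if v > 0]
    else:
        items = [(str(k), 1) for k in community]
    labels = [k for k, _ in items]
    counts = np.array([v for _, v in items], dtype=np.int64)
    return labels, counts


def _tip_nodes(tree: PhyloTree, labels: Sequence[str]) -> np.ndarray:
    missing = [s for s in labels if s not in tree._lab2idx]
    if missing:
        raise KeyError(f"species not on tree: {missing}")
    return np.array([tree.tip_index(s) for s in labels], dtype=np.int64)


def _live_counts(tree: PhyloTree, nodes: np.ndarray) -> np.ndarray:
    """Number of present tips at or below each node."""
    live = np.zeros(tree.n_nodes, dtype=np.int64)
    live[nodes] = 1
    par = tree.parent
    for i in range(tree.n_nodes - 1, 0, -1):
        live[par[i]] += live[i]
    return live


# -- single-metric operations ---------------------------------------------


def faith_pd(tree: PhyloTree, community) -> float:
    """Root-inclusive Faith's PD of the species present in ``community``."""
    labels, _ = _present_and_counts(community)
    if not labels:
        raise ValueError("community has no present species")
    nodes = _tip_nodes(tree, labels)
    live = _live_counts(tree, nodes)
    return float(tree.lengths[1:][live[1:] > 0].sum())


def _pairwise_sub(tree: PhyloTree, nodes: np.ndarray,
                  D: np.ndarray | None) -> np.ndarray:
    """Patristic submatrix for the given tip nodes."""
    if D is None:
        D = _patristic(tree)
    pos = {t: i for i, t in enumerate(tree.tip_indices)}
    idx = np.array([pos[t] for t in nodes])
    return D[np.ix_(idx, idx)]


def mpd(tree: PhyloTree, community, abundance_weighted: bool = False,
        _D: np.ndarray | None = None) -> float:
    """Mean pairwise distance; abundance-weighted over unordered i < j pairs."""
    labels, counts = _present_and_counts(community)
    if len(labels) < 2:
        logger.warning("MPD undefined for <2 species; returning NaN")
        return float("nan")
    d = _pairwise_sub(tree, _tip_nodes(tree, labels), _D)
    iu = np.triu_indices(len(labels), k=1)
    if not abundance_weighted:
        return float(d[iu].mean())
    w = (counts[:, None] * counts[None, :])[iu].astype(float)
    return float((w * d[iu]).sum() / w.sum())


def mntd(tree: PhyloTree, community, abundance_weighted: bool = False,
         _D: np.ndarray | None = None) -> float:
    """Mean nearest-taxon distance; weighted version averages with n_i."""
    labels, counts = _present_and_counts(community)
    if len(labels) < 2:
        logger.warning("MNTD undefined for <2 species; returning NaN")
        return float("nan")
    d = _pairwise_sub(tree, _tip_nodes(tree, labels), _D).copy()
    np.fill_diagonal(d, np.inf)
    nearest = d.min(axis=1)
    if not abundance_weighted:
        return float(nearest.mean())
    return float((counts * nearest).sum() / counts.sum())


def _pendant_lengths(tree: PhyloTree, nodes: np.ndarray,
                     live: np.ndarray) -> np.ndarray:
    """Terminal branch length of each present tip on the community subtree
    (pass-through nodes suppressed, i.e. pendant edges absorb ancestors with
    a single surviving daughter)."""
    par, ln = tree.parent, tree.lengths
    out = np.empty(len(nodes))
    for k, tip in enumerate(nodes):
        cur = tip
        T = ln[cur]
        while par[cur] != -1 and live[par[cur]] == 1:
            cur = par[cur]
            T += ln[cur]
        out[k] = T
    return out


def pae(tree: PhyloTree, community) -> float:
    """Phylogenetic-abundance evenness (1 = perfectly even abundances)."""
    if isinstance(community, (Mapping, pd.Series)):
        bad = [k for k, v in dict(community).items() if int(v) < 1]
        if bad:
            raise ValueError(
                f"present species must have abundance >= 1; offending: {bad}"
            )
    labels, counts = _present_and_counts(community)
    if len(labels) < 2:
        logger.warning("PAE undefined for <2 species; returning NaN")
        return float("nan")
    nodes = _tip_nodes(tree, labels)
    live = _live_counts(tree, nodes)
    pd_val = float(tree.lengths[1:][live[1:] > 0].sum())
    T = _pendant_lengths(tree, nodes, live)
    N, S = counts.sum(), len(labels)
    num = pd_val + float((T * (counts - 1)).sum())
    den = pd_val + (N / S - 1.0) * float(T.sum())
    return num / den


def iac(tree: PhyloTree, community) -> float:
    """Imbalance of abundances among clades (0 = perfectly balanced)."""
    if isinstance(community, (Mapping, pd.Series)):
        bad = [k for k, v in dict(community).items() if int(v) < 1]
        if bad:
            raise ValueError(
                f"present species must have abundance >= 1; offending: {bad}"
            )
    labels, counts = _present_and_counts(community)
    if len(labels) < 2:
        logger.warning("IAC undefined for <2 species; returning NaN")
        return float("nan")
    nodes = _tip_nodes(tree, labels)
    live = _live_counts(tree, nodes)
    S = len(labels)
    # root of the community subtree = MRCA of the present tips
    mrca = 0
    while True:
        live_children = [c for c in tree.children[mrca] if live[c] > 0]
        if len(live_children) == 1 and live[live_children[0]] == live[mrca]:
            mrca = live_children[0]
        else:
            break
    # split N equally among live daughters at every junction, root -> tips
    expected = np.zeros(tree.n_nodes)
    expected[mrca] = float(counts.sum())
    v = 0
    stack = [mrca]
    while stack:
        nd = stack.pop()
        live_children = [c for c in tree.children[nd] if live[c] > 0]
        if not live_children:
            continue
        if len(live_children) >= 2:
            v += 1
        share = expected[nd] / len(live_children)
        for c in live_children:
            expected[c] = share
            stack.append(c)
    return float(np.abs(counts - expected[nodes]).sum() / v)


# -- table computation -----------------------------------------------------


def compute_diversity_table(topology_sets: Iterable[TopologySet],
                            cm: CommunityMatrix,
                            metrics: Sequence[str] = ALL_METRICS,
                            ) -> pd.DataFrame:
    """Evaluate the requested metrics for every tree × plot combination.

    Returns the long-format diversity table with one row per
    (metric, tree, plot): columns ``metric, value, tree_index, rbcL, matK,
    ITS, ITS2, backbone, plot``.  Each value equals what the corresponding
    single-metric function returns for that tree and plot.
    """
    metrics = tuple(metrics)
    unknown = set(metrics) - set(ALL_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    need_pairwise = bool({"MPD", "MPD_ed", "MNTD", "MNTD_ed"} & set(metrics))

    plot_info = []
    for plot in cm.plots:
        ab = cm.abundances(plot)
        plot_info.append((plot, list(ab.index), ab.to_numpy(dtype=np.int64)))

    rows = []
    for ts in topology_sets:
        if ts.condition is None:
            raise ValueError("every TopologySet needs a condition")
        ind = ts.condition.indicators
        # validate species once per set (trees share a tip set)
        tipset = ts.taxon_set
        missing = [
            s for _, labels, _ in plot_info for s in labels if s not in tipset
        ]
        if missing:
            raise KeyError(
                f"species not on trees of condition {ts.condition}: "
                f"{sorted(set(missing))}"
            )
        for tree_index, tree in enumerate(ts.trees):
            D = _patristic(tree) if need_pairwise else None
            for plot, labels, counts in plot_info:
                comm = dict(zip(labels, counts))
                for metric in metrics:
                    try:
                        if metric == "PD":
                            val = faith_pd(tree, comm)
                        elif metric == "MPD":
                            val = mpd(tree, comm, False, _D=D)
                        elif metric == "MPD_ed":
                            val = mpd(tree, comm, True, _D=D)
                        elif metric == "MNTD":
                            val = mntd(tree, comm, False, _D=D)
                        elif metric == "MNTD_ed":
                            val = mntd(tree, comm, True, _D=D)
                        elif metric == "PAE":
                            val = pae(tree, comm)
                        else:
                            val = iac(tree, comm)
                    except Exception as exc:
                        raise type(exc)(
                            f"{metric} failed for tree {tree_index} "
                            f"(condition {ts.condition}), plot {plot}: {exc}"
                        ) from exc
                    rows.append(
                        (metric, val, tree_index, ind["rbcL"], ind["matK"],
                         ind["ITS"], ind["ITS2"], ind["backbone"], plot)
                    )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
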