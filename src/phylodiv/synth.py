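"""Synthetic study generator.

Emulates the statistical structure the pipeline consumes when the empirical
data (posterior topology samples per barcode supermatrix, a family backbone,
and a two-plot abundance table) are not available:

* a **true phylogeny** — an ultrametric Yule (pure-birth) tree for the
  species pool (default 114 species, mirroring the pooled richness of the
  two forest plots the design is modeled on);
* a **family assignment** obtained by cutting the true tree at the age where
  it has ``n_families`` lineages, and the family-level **backbone** tree
  obtained by condensing the true tree to those families;
* per-condition **posterior topology sets**: each tree is the truth hit by a
  Poisson number of random NNI rearrangements (topology channel) with every
  branch length scaled by a condition multiplier times lognormal jitter
  (branch-length channel).  Barcode combinations with more phylogenetic
  information receive proportionally fewer NNI moves.  Backbone-constrained
  conditions restrict NNI moves to edges inside single-family clades, so
  their family-level splits always match the backbone (RF-to-backbone = 0
  at family level);
* a **community matrix**: two plots with fixed richness and overlap
  (defaults 75 and 73 sharing 34 species) and abundances drawn from a
  geometric distribution (all ≥ 1).

All randomness flows from one root seed through named substreams, so every
output is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .conditions import Condition, enumerate_conditions
from .metrics import CommunityMatrix
from .trees import PhyloTree, TopologySet

__all__ = [
    "SynthConfig",
    "SynthData",
    "simulate_true_tree",
    "assign_families",
    "condense_to_families",
    "simulate_topology_set",
    "simulate_communities",
    "simulate_dataset",
]


@dataclass
class SynthConfig:
    """Knobs of the synthetic study; defaults are the emulated design."""

    n_species: int = 114
    plot_richness: tuple = (75, 73)
    shared_species: int = 34
    abundance_geom_p: float = 0.3          # geometric success prob (mean ~3.3)
    trees_per_condition: int = 500         # analysis-set size (top-k)
    posterior_size: int = 1000             # raw topologies sampled per condition
    base_nni_intensity: float = 4.0        # expected moves / sum of barcode info
    barcode_information: dict = field(default_factory=lambda: {
        "rbcL": 1.0, "matK": 1.5, "ITS": 2.0, "ITS2": 1.0,
    })
    length_multipliers: dict = field(default_factory=lambda: {
        "rbcL": 1.0, "matK": 1.0, "ITS": 1.0, "ITS2": 1.0,
    })
    jitter_sigma: float = 0.15             # lognormal sd of branch jitter
    n_families: int = 25
    birth_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        r1, r2 = self.plot_richness
        if self.shared_species > min(r1, r2):
            raise ValueError("shared species exceed a plot's richness")
        if r1 + r2 - self.shared_species > self.n_species:
            raise ValueError("plot richness incompatible with species pool")
        if self.base_nni_intensity < 0 or self.jitter_sigma < 0:
            raise ValueError("intensities must be >= 0")
        if any(v <= 0 for v in self.length_multipliers.values()):
            raise ValueError("length multipliers must be > 0")

    def nni_intensity(self, condition: Condition) -> float:
        """Expected NNI moves per tree: base intensity divided by the summed
        information content of the barcodes in the supermatrix."""
        info = sum(self.barcode_information[b] for b in condition.barcodes)
        return self.base_nni_intensity / info if info > 0 else 0.0

    def length_multiplier(self, condition: Condition) -> float:
        mult = 1.0
        for b in condition.barcodes:
            mult *= self.length_multipliers[b]
        return mult

    def to_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "plot_richness": list(self.plot_richness),
            "shared_species": self.shared_species,
            "abundance_geom_p": self.abundance_geom_p,
            "trees_per_condition": self.trees_per_condition,
            "posterior_size": self.posterior_size,
            "base_nni_intensity": self.base_nni_intensity,
            "barcode_information": dict(self.barcode_information),
            "length_multipliers": dict(self.length_multipliers),
            "jitter_sigma": self.jitter_sigma,
            "n_families": self.n_families,
            "birth_rate": self.birth_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        if "plot_richness" in d:
            d["plot_richness"] = tuple(d["plot_richness"])
        return cls(**d)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# -- true tree -------------------------------------------------------------


def simulate_true_tree(n_species: int, seed, birth_rate: float = 1.0
                       ) -> PhyloTree:
    """Ultrametric Yule (pure-birth) tree with ``n_species`` labeled tips.

    Forward simulation: starting from the root's two daughter lineages,
    exponential waiting times (rate = #lineages × birth_rate) separate
    speciation events; a final waiting period gives the youngest pendant
    branches positive length.  All tips end at the same time, so the tree is
    exactly ultrametric.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = _rng(seed)
    birth: dict = {1: 0.0, 2: 0.0}
    children = {0: [1, 2]}
    active = [1, 2]
    nxt = 3
    t = 0.0
    end: dict = {}
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        lin = active[i]
        end[lin] = t
        children[lin] = [nxt, nxt + 1]
        birth[nxt] = birth[nxt + 1] = t
        active[i] = nxt
        active.append(nxt + 1)
        nxt += 2
    t_end = t + rng.exponential(1.0 / (n_species * birth_rate))
    for lin in active:
        end[lin] = t_end
    width = len(str(n_species))
    labels = {
        lin: f"sp{idx + 1:0{width}d}" for idx, lin in enumerate(sorted(active))
    }
    lengths = {lin: end[lin] - birth[lin] for lin in birth}
    return PhyloTree.from_links(0, children, lengths, labels)


# -- families and backbone -------------------------------------------------


def _node_ages(tree: PhyloTree) -> np.ndarray:
    d = tree.node_depths()
    return d[tree.tip_indices].max() - d


def assign_families(tree: PhyloTree, n_families: int) -> dict:
    """Group tips into families by cutting the tree at the age where it has
    ``n_families`` lineages; returns species -> family label."""
    if n_families < 2:
        return {lab: "fam01" for lab in tree.tip_labels}
    ages = _node_ages(tree)
    internal_ages = sorted(
        (ages[i] for i in range(tree.n_nodes) if tree.children[i]),
        reverse=True,
    )
    if n_families >= tree.n_tips:
        cut = 0.0  # every tip its own family
    else:
        below = internal_ages[n_families - 1] if n_families - 1 < len(internal_ages) else 0.0
        cut = 0.5 * (internal_ages[n_families - 2] + below)
    width = len(str(max(n_families, 2)))
    fam_of_node = np.full(tree.n_nodes, -1, dtype=np.int64)
    counter = 0
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if ages[i] < cut and (p == -1 or ages[p] >= cut):
            fam_of_node[i] = counter
            counter += 1
        elif p != -1 and fam_of_node[p] >= 0:
            fam_of_node[i] = fam_of_node[p]
    out = {}
    for i in tree.tip_indices:
        f = fam_of_node[i]
        if f < 0:  # tip older than the cut (cannot happen for ultrametric)
            f = counter
            counter += 1
        out[tree.labels[i]] = f"fam{f + 1:0{width}d}"
    return out


def condense_to_families(tree: PhyloTree, family_map: Mapping[str, str]
                         ) -> PhyloTree:
    """Collapse monophyletic families to single tips (the backbone tree).

    Every family must be monophyletic on ``tree``; the family tip's branch
    extends to the present so the backbone stays ultrametric.
    """
    clades: list = [None] * tree.n_nodes
    for i in range(tree.n_nodes - 1, -1, -1):
        if not tree.children[i]:
            clades[i] = {family_map[tree.labels[i]]}
        else:
            clades[i] = set().union(*(clades[c] for c in tree.children[i]))
    ages = _node_ages(tree)
    children: dict = {}
    lengths: dict = {}
    labels: dict = {}

    def build(i):
        if len(clades[i]) == 1:
            fam = next(iter(clades[i]))
            # verify monophyly: no tips of this family elsewhere
            labels[i] = fam
            lengths[i] = tree.lengths[i] + ages[i]
            return
        children[i] = list(tree.children[i])
        lengths[i] = tree.lengths[i]
        for c in tree.children[i]:
            build(c)

    fams = set(family_map.values())
    build(0)
    got = set(labels.values())
    if got != fams or len(labels) != len(fams):
        raise ValueError("families are not monophyletic on this tree")
    return PhyloTree.from_links(0, children, lengths, labels)


# -- posterior topology sets ----------------------------------------------


def simulate_topology_set(truth: PhyloTree, condition: Condition,
                          n_trees: int, intensity: float,
                          length_multiplier: float,
                          jitter_sigma: float = 0.15,
                          seed=None,
                          family_map: Mapping[str, str] | None = None,
                          ) -> TopologySet:
    """Posterior-like topology sample around the true tree.

    Each tree receives ``Poisson(intensity)`` random NNI moves and branch
    lengths multiplied by ``length_multiplier`` × lognormal jitter with unit
    mean.  When ``condition.has_backbone`` and a family map is given, moves
    are restricted to edges whose parent node lies inside a single family
    clade, so family-level splits stay identical to the truth's.
    """
    rng = _rng(seed)
    m = truth.n_nodes
    constrained = condition.has_backbone and family_map is not None
    fam_id = None
    if constrained:
        fam_id = np.full(m, -1, dtype=np.int64)
        fams = {f: j for j, f in enumerate(sorted(set(family_map.values())))}
        for i in range(m - 1, -1, -1):
            ch = truth.children[i]
            if not ch:
                fam_id[i] = fams[family_map[truth.labels[i]]]
            else:
                ids = {fam_id[c] for c in ch}
                fam_id[i] = ids.pop() if len(ids) == 1 and -1 not in ids else -1

    base_children = [list(c) for c in truth.children]
    internal = [i for i in range(1, m) if truth.children[i]]
    trees = []
    for _ in range(n_trees):
        moves = int(rng.poisson(intensity)) if intensity > 0 else 0
        if moves == 0:
            jit = rng.lognormal(
                -0.5 * jitter_sigma ** 2, jitter_sigma, size=m
            ) if jitter_sigma > 0 else np.ones(m)
            lengths = truth.lengths * length_multiplier * jit
            lengths[0] = 0.0
            trees.append(truth.with_lengths(lengths))
            continue
        children = [list(c) for c in base_children]
        parent = truth.parent.copy()
        for _ in range(moves):
            if constrained:
                eligible = [v for v in internal if fam_id[parent[v]] >= 0]
            else:
                eligible = internal
            if not eligible:
                break
            v = eligible[int(rng.integers(len(eligible)))]
            u = parent[v]
            sibs = [w for w in children[u] if w != v]
            if not sibs:
                continue
            w = sibs[int(rng.integers(len(sibs)))]
            c = children[v][int(rng.integers(len(children[v])))]
            children[v][children[v].index(c)] = w
            children[u][children[u].index(w)] = c
            parent[c], parent[w] = u, v
        jit = rng.lognormal(
            -0.5 * jitter_sigma ** 2, jitter_sigma, size=m
        ) if jitter_sigma > 0 else np.ones(m)
        lengths = truth.lengths * length_multiplier * jit
        tr = PhyloTree.from_links(
            0,
            {i: ch for i, ch in enumerate(children) if ch},
            {i: float(lengths[i]) for i in range(1, m)},
            {int(i): truth.labels[i] for i in truth.tip_indices},
        )
        trees.append(tr)
    return TopologySet(trees=trees, condition=condition)


# -- communities -----------------------------------------------------------


def simulate_communities(tree: PhyloTree, cfg: SynthConfig, seed=None
                         ) -> CommunityMatrix:
    """Two plots with configured richness/overlap and geometric abundances.

    Plot ids are ``600m`` (mountain, first richness entry) and ``100m``
    (valley); all realized abundances are >= 1.
    """
    rng = _rng(seed if seed is not None else cfg.seed)
    r1, r2 = cfg.plot_richness
    shared = cfg.shared_species
    total = r1 + r2 - shared
    tips = sorted(tree.tip_labels)
    if total > len(tips):
        raise ValueError(
            f"need {total} species but tree has only {len(tips)} tips"
        )
    pick = rng.choice(len(tips), size=total, replace=False)
    chosen = [tips[i] for i in pick]
    both = chosen[:shared]
    only1 = chosen[shared: shared + (r1 - shared)]
    only2 = chosen[shared + (r1 - shared):]
    table = pd.DataFrame(0, index=["600m", "100m"], columns=chosen)
    for sp in both + only1:
        table.loc["600m", sp] = rng.geometric(cfg.abundance_geom_p)
    for sp in both + only2:
        table.loc["100m", sp] = rng.geometric(cfg.abundance_geom_p)
    return CommunityMatrix(table)


# -- full bundle -----------------------------------------------------------


@dataclass
class SynthData:
    """Everything the pipeline consumes, generated from one seed."""

    config: SynthConfig
    truth: PhyloTree
    family_map: dict
    backbone: PhyloTree
    community: CommunityMatrix
    sets: list                      # 14 TopologySets (posterior pools)

    @property
    def conditions(self) -> list:
        return [s.condition for s in self.sets]


def simulate_dataset(cfg: SynthConfig,
                     pool_size: int | None = None) -> SynthData:
    """Generate the complete synthetic study.

    ``pool_size`` overrides the per-condition number of raw topologies
    (default ``cfg.posterior_size``); the pipeline's selection stage reduces
    these pools to ``cfg.trees_per_condition`` analysis trees.
    """
    conditions = enumerate_conditions()
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(2 + len(conditions))
    truth = simulate_true_tree(
        cfg.n_species, np.random.default_rng(streams[0]), cfg.birth_rate
    )
    family_map = assign_families(truth, cfg.n_families)
    backbone = condense_to_families(truth, family_map)
    community = simulate_communities(
        truth, cfg, np.random.default_rng(streams[1])
    )
    n = pool_size if pool_size is not None else cfg.posterior_size
    sets = []
    for cond, stream in zip(conditions, streams[2:]):
        sets.append(simulate_topology_set(
            truth, cond, n,
            intensity=cfg.nni_intensity(cond),
            length_multiplier=cfg.length_multiplier(cond),
            jitter_sigma=cfg.jitter_sigma,
            seed=np.random.default_rng(stream),
            family_map=family_map,
        ))
    return SynthData(
        config=cfg, truth=truth, family_map=family_map, backbone=backbone,
        community=community, sets=sets,
    )
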