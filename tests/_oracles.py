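"""Independent reference implementations used as test oracles.

Everything here is deliberately written against different machinery than the
package uses: dendropy for tree distances, explicit path/recursion logic for
the diversity metrics, grid search plus local polish for the rate-smoothing
objective, and statsmodels for the mixed-model fits (in the test modules).
"""

import itertools

import dendropy
import numpy as np
from scipy.optimize import minimize

from phylodiv.chronos import profiled_rates, smoothing_objective
from phylodiv.trees import PhyloTree


# -- random trees ----------------------------------------------------------


def random_binary_tree(rng, n_tips, labels=None, max_len=2.0):
    """Random rooted binary tree via sequential random joins."""
    if labels is None:
        labels = [f"t{i}" for i in range(n_tips)]
    nodes = list(range(n_tips))
    children = {}
    lengths = {}
    label_of = dict(enumerate(labels))
    nxt = n_tips
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        children[nxt] = [a, b]
        nodes = [v for v in nodes if v not in (a, b)] + [nxt]
        nxt += 1
    for v in range(nxt):
        if v != nodes[0]:
            lengths[v] = float(rng.uniform(0.05, max_len))
    return PhyloTree.from_links(nodes[0], children, lengths, label_of)


# -- dendropy-based distance oracles --------------------------------------


def dendropy_rf(t1: PhyloTree, t2: PhyloTree) -> int:
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                           taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                           taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


def dendropy_patristic(tree: PhyloTree):
    """Dict (label_a, label_b) -> path length, from dendropy's PDM."""
    dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    pdm = dt.phylogenetic_distance_matrix()
    out = {}
    for ta, tb in itertools.combinations(dt.taxon_namespace, 2):
        out[(ta.label, tb.label)] = pdm.patristic_distance(ta, tb)
        out[(tb.label, ta.label)] = out[(ta.label, tb.label)]
    return out


# -- metric oracles (path enumeration on the raw arrays) -------------------


def _root_path_edges(tree: PhyloTree, node: int):
    edges = set()
    while tree.parent[node] != -1:
        edges.add(node)
        node = tree.parent[node]
    return edges


def brute_faith_pd(tree: PhyloTree, present) -> float:
    """Union of root-to-tip edge paths over the present species."""
    edges = set()
    for lab in present:
        edges |= _root_path_edges(tree, tree.tip_index(lab))
    return float(sum(tree.lengths[e] for e in edges))


def brute_pairwise(tree: PhyloTree, a: str, b: str) -> float:
    ea = _root_path_edges(tree, tree.tip_index(a))
    eb = _root_path_edges(tree, tree.tip_index(b))
    return float(sum(tree.lengths[e] for e in ea ^ eb))


def brute_mpd(tree, counts: dict, weighted: bool) -> float:
    labs = [k for k, v in counts.items() if v > 0]
    num = den = 0.0
    for a, b in itertools.combinations(labs, 2):
        d = brute_pairwise(tree, a, b)
        w = counts[a] * counts[b] if weighted else 1.0
        num += w * d
        den += w
    return num / den


def brute_mntd(tree, counts: dict, weighted: bool) -> float:
    labs = [k for k, v in counts.items() if v > 0]
    num = den = 0.0
    for a in labs:
        nd = min(brute_pairwise(tree, a, b) for b in labs if b != a)
        w = counts[a] if weighted else 1.0
        num += w * nd
        den += w
    return num / den


def brute_pae(tree: PhyloTree, counts: dict) -> float:
    """Direct formula evaluation with pendant lengths from MRCA depths:
    T_i = depth_i - max_j depth(mrca(i, j)) over other present tips."""
    labs = [k for k, v in counts.items() if v > 0]
    depths = tree.node_depths()
    pd_val = brute_faith_pd(tree, labs)

    T = {}
    for a in labs:
        da = depths[tree.tip_index(a)]
        best = 0.0
        for b in labs:
            if b == a:
                continue
            ea = _root_path_edges(tree, tree.tip_index(a))
            eb = _root_path_edges(tree, tree.tip_index(b))
            diverge = min(
                (depths[tree.parent[e]] for e in ea - eb),
            )
            best = max(best, diverge)
        T[a] = da - best
    n = np.array([counts[a] for a in labs], float)
    Tv = np.array([T[a] for a in labs])
    N, S = n.sum(), len(labs)
    return float(
        (pd_val + (Tv * (n - 1)).sum())
        / (pd_val + (N / S - 1.0) * Tv.sum())
    )


def brute_iac(tree: PhyloTree, counts: dict) -> float:
    """Independent recursive equal-split expectation on label sets."""
    labs = {k for k, v in counts.items() if v > 0}

    def live(node):
        if not tree.children[node]:
            return {tree.labels[node]} & labs
        out = set()
        for c in tree.children[node]:
            out |= live(c)
        return out

    # MRCA: deepest node whose live set is all labs
    mrca = 0
    while True:
        nxt = [c for c in tree.children[mrca] if live(c) == labs]
        if nxt:
            mrca = nxt[0]
        else:
            break
    expected = {}
    internal_count = 0

    def walk(node, amount):
        nonlocal internal_count
        kids = [c for c in tree.children[node] if live(c)]
        if not kids:
            expected[tree.labels[node]] = amount
            return
        if len(kids) >= 2:
            internal_count += 1
        for c in kids:
            walk(c, amount / len(kids))

    walk(mrca, float(sum(counts[a] for a in labs)))
    dev = sum(abs(counts[a] - expected[a]) for a in labs)
    return dev / internal_count


# -- smoothing oracle ------------------------------------------------------


def brute_smoothing_optimum(tree: PhyloTree, lam: float, grid: int = 10
                            ) -> float:
    """Dense grid over internal node ages (rates profiled exactly) followed
    by Nelder-Mead polish; returns the best objective value found."""
    m = tree.n_nodes
    par = tree.parent
    internal = [i for i in range(1, m) if tree.children[i]]
    gridvals = np.linspace(0.05, 0.95, grid)
    best_f, best_ages = np.inf, None
    for combo in itertools.product(gridvals, repeat=len(internal)):
        ages = np.zeros(m)
        ages[0] = 1.0
        for v, s in zip(internal, combo):
            ages[v] = ages[par[v]] * s
        r = profiled_rates(tree, ages, lam)
        f = smoothing_objective(tree, ages, r, lam)
        if f < best_f:
            best_f, best_ages = f, ages.copy()

    iv = np.array(internal)

    def obj(a):
        ages = np.zeros(m)
        ages[0] = 1.0
        ages[iv] = a
        for v in internal:
            if ages[v] <= 0 or ages[v] >= ages[par[v]]:
                return 1e6 + float(abs(ages[v]))
        r = profiled_rates(tree, ages, lam)
        return smoothing_objective(tree, ages, r, lam)

    res = minimize(
        obj, best_ages[iv], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 20000},
    )
    return float(min(best_f, res.fun))
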