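"""Penalized rate-smoothing: transform a phylogram into an ultrametric tree.

The model assigns every node an age (tips at 0, root normalized to 1) and
every branch its own substitution rate.  The objective traded off is

    F(ages, rates) = sum_b (x_b - r_b * d_b)^2
                     + lambda * sum_(b,p) (r_b - r_p)^2

where ``x_b`` is the observed branch length, ``d_b = age(parent) - age(child)``
the branch duration implied by the ages, and the penalty runs over every
ancestor–descendant branch pair.  Large ``lambda`` forces near-clock-like
rates (the pipeline default is 1000, i.e. an almost strict clock); small
``lambda`` lets rates vary freely along the tree.

Numerically, the rates are profiled out: for fixed ages the objective is a
positive-definite quadratic in the rates, solved exactly by one linear
solve.  The remaining problem over node ages uses a monotonicity-preserving
parametrization (each internal node's age is a sigmoid-squashed fraction of
its parent's age, so ages always decrease root→tip and the output is
ultrametric by construction) and is minimized with L-BFGS-B using analytic
gradients (envelope theorem: at the profiled rates, only the direct age
dependence contributes).  Because the root age is fixed at 1, the returned
branch lengths are on a relative-time scale.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize

from .trees import PhyloTree

__all__ = ["make_ultrametric", "smoothing_objective", "profiled_rates"]


def _sigmoid(u):
    return 1.0 / (1.0 + np.exp(-u))


def smoothing_objective(tree: PhyloTree, ages: np.ndarray,
                        rates: np.ndarray, lam: float) -> float:
    """Evaluate the penalized lack-of-fit objective at given ages/rates.

    ``ages`` is indexed by node (tips must be 0), ``rates`` by node for every
    non-root node (entry 0 unused).  Exposed separately so that independent
    optimizers can score the same objective.
    """
    par = tree.parent
    x = tree.lengths
    d = ages[par[1:]] - ages[1:]
    fit = float(np.sum((x[1:] - rates[1:] * d) ** 2))
    pen = 0.0
    for b in range(1, tree.n_nodes):
        p = par[b]
        if p != 0:
            pen += (rates[b] - rates[p]) ** 2
    return fit + lam * pen


def profiled_rates(tree: PhyloTree, ages: np.ndarray, lam: float,
                   x: np.ndarray | None = None) -> np.ndarray:
    """Exact minimizer of the objective over the rates for fixed ages
    (clipped at 0).  Indexed by node; entry 0 is NaN."""
    m = tree.n_nodes
    par = tree.parent
    if x is None:
        x = tree.lengths
    d = ages[par[1:]] - ages[1:]
    A = np.zeros((m - 1, m - 1))
    idx = np.arange(m - 1)
    A[idx, idx] = 2.0 * d ** 2
    b = 2.0 * d * x[1:]
    for node in range(1, m):
        p = par[node]
        if p != 0:
            i, j = node - 1, p - 1
            A[i, i] += 2.0 * lam
            A[j, j] += 2.0 * lam
            A[i, j] -= 2.0 * lam
            A[j, i] -= 2.0 * lam
    r = np.linalg.solve(A, b)
    rates = np.empty(m)
    rates[0] = np.nan
    rates[1:] = np.clip(r, 0.0, None)
    return rates


def _initial_ages(tree: PhyloTree) -> np.ndarray:
    """Mean node-to-descendant-tip path lengths, normalized to root age 1."""
    m = tree.n_nodes
    tot = np.zeros(m)
    cnt = np.zeros(m)
    for i in range(m - 1, -1, -1):
        if not tree.children[i]:
            cnt[i] = 1.0
        else:
            for c in tree.children[i]:
                tot[i] += tot[c] + tree.lengths[c] * cnt[c]
                cnt[i] += cnt[c]
    age = np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)
    root_age = age[0] if age[0] > 0 else 1.0
    age = age / root_age
    age[0] = 1.0
    # repair (only) monotonicity violations root -> tips
    for i in range(1, m):
        if tree.children[i]:
            pa = age[tree.parent[i]]
            if age[i] >= pa:
                age[i] = (1.0 - 1e-7) * pa
            elif age[i] <= 0:
                age[i] = 1e-7 * pa
    return age


def make_ultrametric(tree: PhyloTree, lam: float = 1000.0, *,
                     max_iter: int = 5000, n_starts: int = 1,
                     seed: int = 0) -> PhyloTree:
    """Smooth branch lengths into relative-time (ultrametric) lengths.

    Parameters
    ----------
    tree
        Rooted tree with strictly positive branch lengths (zero-length
        branches are raised to 1e-8 of tree height with a warning).
    lam
        Smoothing penalty weight; default 1000.
    n_starts
        Extra randomly-perturbed restarts (the best optimum is kept).

    Returns
    -------
    PhyloTree
        Same topology; root-to-tip depths all equal 1 exactly.

    Raises
    ------
    RuntimeError
        If the optimizer exhausts its iteration budget (the message carries
        the objective trace); ValueError for negative input lengths.
    """
    if np.any(tree.lengths[1:] < 0):
        raise ValueError("negative branch length")
    m = tree.n_nodes
    if tree.n_tips < 2:
        raise ValueError("need at least two tips")
    x = tree.lengths.copy()
    height = tree.node_depths().max()
    if height <= 0:
        raise ValueError("tree has no positive branch lengths")
    zero = x[1:] <= 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-length branch(es) raised to 1e-8 of "
            "tree height before smoothing"
        )
        x[1:][zero] = 1e-8 * height

    par = tree.parent
    internal = np.array(
        [i for i in range(1, m) if tree.children[i]], dtype=np.int64
    )  # internal non-root nodes, preorder
    children = tree.children
    is_tip = np.array([not c for c in children])
    work = tree.with_lengths(x)

    if len(internal) == 0:
        # no free node ages (e.g. a two-tip tree): tips at 0, root at 1
        new_lengths = np.zeros(m)
        new_lengths[1:] = 1.0
        return tree.with_lengths(new_lengths)

    age0 = _initial_ages(tree)
    s0 = np.empty(len(internal))
    for j, v in enumerate(internal):
        s0[j] = np.clip(age0[v] / age0[par[v]], 1e-7, 1.0 - 1e-7)
    u0 = np.log(s0 / (1.0 - s0))

    def ages_from(u):
        s = _sigmoid(np.clip(u, -35, 35))
        t = np.zeros(m)
        t[0] = 1.0
        for j, v in enumerate(internal):
            t[v] = t[par[v]] * s[j]
        return s, t

    def fun_and_grad(u):
        s, t = ages_from(u)
        r = profiled_rates(work, t, lam)
        d = t[par[1:]] - t[1:]
        resid = x[1:] - r[1:] * d
        F = float(resid @ resid)
        pc = par[1:]
        inner = pc != 0
        dr = r[1:][inner] - r[pc[inner]]
        F += lam * float(dr @ dr)
        # envelope theorem: rates are optimal (or clipped), so only the
        # direct dependence of F on the ages contributes to the gradient
        g_d = np.zeros(m)
        g_d[1:] = -2.0 * r[1:] * resid
        direct = np.zeros(m)
        for v in internal:
            acc = -g_d[v]
            for c in children[v]:
                acc += g_d[c]
            direct[v] = acc
        a = np.zeros(m)
        sv = np.zeros(m)
        sv[internal] = s
        for j in range(len(internal) - 1, -1, -1):
            v = internal[j]
            acc = direct[v]
            for c in children[v]:
                if not is_tip[c]:
                    acc += a[c] * sv[c]
            a[v] = acc
        gu = a[internal] * t[par[internal]] * s * (1.0 - s)
        return F, gu

    rng = np.random.default_rng(seed)
    best = None
    trace: list = []
    for start in range(max(1, n_starts)):
        u = u0.copy()
        if start > 0:
            if start % 2:
                # fresh random age fractions (escapes distant local optima)
                s = rng.uniform(0.1, 0.9, size=len(internal))
                u = np.log(s / (1.0 - s))
            else:
                u = u0 + rng.normal(0.0, 1.0, size=len(internal))
        res = minimize(
            fun_and_grad, u, jac=True, method="L-BFGS-B",
            bounds=[(-35.0, 35.0)] * len(internal),
            options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-8},
        )
        trace.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    # status 1 == iteration budget exhausted (status 2, precision loss at the
    # optimum, is routine for L-BFGS-B and accepted)
    if best.status == 1:
        raise RuntimeError(
            f"rate smoothing did not converge within {max_iter} iterations; "
            f"objective trace: {trace}"
        )

    _, t = ages_from(best.x)
    new_lengths = np.zeros(m)
    new_lengths[1:] = t[par[1:]] - t[1:]
    return tree.with_lengths(new_lengths)
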