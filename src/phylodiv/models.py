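"""Multi-model mixed-effects inference for diversity estimates.

Every candidate model has the form

    log(diversity) = alpha + delta_plot + rbcL*b1 + matK*b2
                     + (ITS | ITS2)*b3 + backbone*b4 + eps

with a global intercept, a random intercept per plot, and any subset of the
five 0/1 condition indicators as fixed effects (ITS and ITS2 never co-occur).
That yields 24 model specifications including the intercept-only model.

Fits are exact maximum-likelihood fits of the Gaussian random-intercept
model, obtained by profiling the fixed effects and the residual variance out
of the likelihood and optimizing the single remaining variance ratio
numerically (ML, not REML, because models differing in fixed effects are
compared by AICc).  Model support is summarized by AICc, Akaike weights,
marginal/conditional R² (variance partition over fixed, plot and residual
components), and per-term standardized coefficients (beta/SE) averaged
across models with AICc weights renormalized over the models containing the
term.  A stratified bootstrap rerunning the whole comparison provides 95%
confidence intervals and a model-rank stability check.

:class:`DiversityModelSet` bundles the procedure statsmodels-style: build it
from a long-format diversity table, call :meth:`~DiversityModelSet.fit`, and
read the comparison table / averaged coefficients off the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .conditions import TERM_LETTER, TERM_ORDER

__all__ = [
    "ModelSpec",
    "LMMFit",
    "enumerate_models",
    "fit_lmm",
    "aicc",
    "akaike_weights",
    "r2_nakagawa",
    "averaged_std_coefs",
    "bootstrap_inference",
    "DiversityModelSet",
    "DiversityModelSetResults",
]


# -- model specifications --------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect terms of one candidate model (intercept and plot random
    intercept are always present and implicit)."""

    terms: frozenset

    def __post_init__(self):
        bad = set(self.terms) - set(TERM_ORDER)
        if bad:
            raise ValueError(f"unknown terms: {sorted(bad)}")
        if {"ITS", "ITS2"} <= set(self.terms):
            raise ValueError("ITS and ITS2 cannot co-occur in a model")

    @property
    def ordered_terms(self) -> tuple:
        return tuple(t for t in TERM_ORDER if t in self.terms)

    @property
    def label(self) -> str:
        if not self.terms:
            return "~ 1"
        return "~" + " + ".join(TERM_LETTER[t] for t in self.ordered_terms)

    def __str__(self):
        return self.label


def enumerate_models() -> list:
    """All 24 candidate specifications: subsets of {rbcL, matK} × {none,
    ITS, ITS2} × {backbone, none}, including the intercept-only model."""
    out = []
    for rm, its, bb in product(
        ((), ("rbcL",), ("matK",), ("rbcL", "matK")),
        ((), ("ITS",), ("ITS2",)),
        ((), ("backbone",)),
    ):
        out.append(ModelSpec(frozenset(rm + its + bb)))
    return out


# -- exact profiled-ML random-intercept fit --------------------------------


def _group_stats(y: np.ndarray, X: np.ndarray, codes: np.ndarray, q: int):
    """Sufficient statistics for the profiled likelihood."""
    p = X.shape[1]
    SX = np.zeros((q, p))
    Sy = np.zeros(q)
    np.add.at(SX, codes, X)
    np.add.at(Sy, codes, y)
    nj = np.bincount(codes, minlength=q).astype(float)
    return {
        "XtX": X.T @ X, "Xty": X.T @ y, "yty": float(y @ y),
        "SX": SX, "Sy": Sy, "nj": nj, "n": len(y),
    }


def _profile_ll(gamma: float, st: Mapping) -> tuple:
    """Profiled log-likelihood at variance ratio gamma = s2_group/s2_resid.

    Returns (llf, beta, A, sigma2_resid) where A = X' V*^-1 X with
    V* = I + gamma Z Z' (so cov(beta) = sigma2_resid * A^-1).
    """
    nj, n = st["nj"], st["n"]
    w = gamma / (1.0 + gamma * nj)                      # per-group shrinkage
    A = st["XtX"] - (st["SX"].T * w) @ st["SX"]
    c = st["Xty"] - st["SX"].T @ (w * st["Sy"])
    beta = np.linalg.solve(A, c)
    Q = st["yty"] - float(w @ st["Sy"] ** 2) - float(beta @ c)
    Q = max(Q, 1e-300)
    s2 = Q / n
    llf = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0) \
          - 0.5 * float(np.sum(np.log1p(gamma * nj)))
    return llf, beta, A, s2


def _ml_solve(st: Mapping) -> dict:
    """Maximize the profiled likelihood over the variance ratio."""
    def neg(loggamma):
        return -_profile_ll(np.exp(loggamma), st)[0]

    res = minimize_scalar(neg, bounds=(-30.0, 20.0), method="bounded",
                          options={"xatol": 1e-10})
    ll_hat = -res.fun
    gamma = float(np.exp(res.x))
    ll0 = _profile_ll(0.0, st)[0]
    if ll0 >= ll_hat:                                   # boundary optimum
        gamma, ll_hat = 0.0, ll0
    llf, beta, A, s2 = _profile_ll(gamma, st)
    cov = s2 * np.linalg.inv(A)
    xbar = st["SX"].sum(axis=0) / st["n"]
    var_fixed = float(beta @ st["XtX"] @ beta) / st["n"] - float(beta @ xbar) ** 2
    return {
        "beta": beta, "cov": cov, "llf": llf, "sigma2_resid": s2,
        "sigma2_group": gamma * s2, "gamma": gamma,
        "var_fixed": max(var_fixed, 0.0),
    }


@dataclass
class LMMFit:
    """Maximum-likelihood fit of one random-intercept model."""

    spec: ModelSpec
    terms: tuple                      # design columns, "Intercept" first
    params: np.ndarray
    bse: np.ndarray
    llf: float
    sigma2_resid: float
    sigma2_group: float
    var_fixed: float
    n: int
    k_fixed: int

    @property
    def k(self) -> int:
        """Parameter count for AICc: fixed coefficients + 2 variance
        components (random-intercept and residual)."""
        return self.k_fixed + 2

    @property
    def zscores(self) -> dict:
        """Standardized coefficients beta/SE for the non-intercept terms."""
        return {
            t: float(self.params[i] / self.bse[i])
            for i, t in enumerate(self.terms) if t != "Intercept"
        }


def _log_response(values: np.ndarray, eps: float | None = None) -> np.ndarray:
    """Natural-log transform; non-positive values are offset by ``eps``
    (default: half the smallest positive value) with a warning."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError(
            "negative diversity values cannot be log-transformed"
        )
    if np.any(v == 0):
        if eps is None:
            pos = v[v > 0]
            if pos.size == 0:
                raise ValueError("all response values are zero")
            eps = 0.5 * float(pos.min())
        warnings.warn(
            f"response contains zeros; offsetting all values by {eps:g} "
            "before the log transform"
        )
        v = v + eps
    return np.log(v)


def _design(data: pd.DataFrame, spec: ModelSpec):
    """Intercept + indicator design matrix; constant terms are dropped."""
    cols = ["Intercept"]
    X = [np.ones(len(data))]
    for t in spec.ordered_terms:
        col = data[t].to_numpy(dtype=float)
        if col.std() == 0:
            warnings.warn(
                f"term {t!r} is constant in the data and was dropped"
            )
            continue
        cols.append(t)
        X.append(col)
    return np.column_stack(X), tuple(cols)


def fit_lmm(data: pd.DataFrame, spec: ModelSpec, *,
            response: str = "value", group: str = "plot",
            log_transform: bool = True, eps: float | None = None) -> LMMFit:
    """Fit one candidate model to a single metric's diversity table.

    ``data`` must hold the indicator columns named by the spec's terms, the
    grouping column and the response.  The response is log-transformed
    unless ``log_transform=False`` (in which case it is used as-is).
    """
    y = data[response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if log_transform:
        y = _log_response(y, eps)
    codes, uniques = pd.factorize(data[group])
    if len(uniques) < 2:
        raise ValueError("need at least two plots for a random intercept")
    X, cols = _design(data, spec)
    st = _group_stats(y, X, codes, len(uniques))
    sol = _ml_solve(st)
    return LMMFit(
        spec=spec, terms=cols, params=sol["beta"],
        bse=np.sqrt(np.diag(sol["cov"])), llf=sol["llf"],
        sigma2_resid=sol["sigma2_resid"], sigma2_group=sol["sigma2_group"],
        var_fixed=sol["var_fixed"], n=len(y), k_fixed=X.shape[1],
    )


# -- information-theoretic machinery ---------------------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    """Model probabilities w_i = exp(-d_i/2) / sum_j exp(-d_j/2)."""
    a = np.asarray(aiccs, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    rel = np.exp(-0.5 * (a - a.min()))
    return rel / rel.sum()


def r2_nakagawa(fit: LMMFit) -> tuple:
    """Marginal and conditional R² (percent).

    Rm² is the share of variance attributable to the fixed-effect linear
    predictor, Rc² adds the plot random-intercept variance; the denominator
    is fixed + plot + residual variance.
    """
    den = fit.var_fixed + fit.sigma2_group + fit.sigma2_resid
    if den <= 0:
        raise ValueError("total variance is zero; R2 undefined")
    rm = 100.0 * fit.var_fixed / den
    rc = 100.0 * (fit.var_fixed + fit.sigma2_group) / den
    return rm, rc


def averaged_std_coefs(fits: Sequence[LMMFit],
                       weights: Sequence[float]) -> dict:
    """Weight-averaged standardized coefficients per term.

    For every term, the AICc weights are renormalized to sum to 1 over the
    models in which the term appears, then beta/SE is averaged with those
    weights.  Terms present in no fitted model are absent from the result.
    """
    if len(fits) != len(weights):
        raise ValueError("fits and weights must align")
    out: dict = {}
    for term in TERM_ORDER:
        num = den = 0.0
        for f, w in zip(fits, weights):
            z = f.zscores.get(term)
            if z is not None:
                num += w * z
                den += w
        if den > 0:
            out[term] = num / den
    return out


# -- the model-set object --------------------------------------------------


class DiversityModelSet:
    """The 24-model comparison for one diversity metric.

    Parameters
    ----------
    data
        Long-format diversity table (one row per tree × plot estimate) with
        the indicator columns ``rbcL, matK, ITS, ITS2, backbone``, a
        ``plot`` column and a ``value`` column.  If a ``metric`` column is
        present the table is filtered to ``metric``.
    metric
        Metric name used for filtering and reporting.
    eps
        Offset applied before the log transform when zeros occur in the
        response (default: half the smallest positive value).
    """

    def __init__(self, data: pd.DataFrame, metric: str | None = None,
                 specs: Sequence[ModelSpec] | None = None,
                 eps: float | None = None):
        if metric is not None and "metric" in data.columns:
            data = data[data["metric"] == metric]
        if data.empty:
            raise ValueError(f"no rows for metric {metric!r}")
        self.metric = metric
        self.specs = list(specs) if specs is not None else enumerate_models()
        self.data = data.reset_index(drop=True)
        self._y = _log_response(self.data["value"].to_numpy(float), eps)
        self._codes, self._groups = pd.factorize(self.data["plot"])
        if len(self._groups) < 2:
            raise ValueError("need at least two plots for a random intercept")
        self._q = len(self._groups)
        # master design: intercept + all five indicators
        self._master_cols = ("Intercept",) + TERM_ORDER
        self._Xm = np.column_stack(
            [np.ones(len(self.data))]
            + [self.data[t].to_numpy(float) for t in TERM_ORDER]
        )
        # per-spec column indices into the master design (constant terms drop)
        nonconst = {
            t for j, t in enumerate(TERM_ORDER)
            if self._Xm[:, j + 1].std() > 0
        }
        dropped = set().union(*(s.terms for s in self.specs)) - nonconst
        if dropped:
            warnings.warn(
                f"terms constant in the data dropped from all models: "
                f"{sorted(dropped)}"
            )
        self._spec_cols = []
        for s in self.specs:
            cols = [0] + [
                1 + TERM_ORDER.index(t)
                for t in s.ordered_terms if t in nonconst
            ]
            self._spec_cols.append(np.array(cols, dtype=np.int64))
        # stratification cells for the bootstrap: condition × plot
        cell_keys = self.data[list(TERM_ORDER) + ["plot"]].astype(str).agg(
            "|".join, axis=1
        )
        cell_codes, _ = pd.factorize(cell_keys)
        self._cells = [
            np.flatnonzero(cell_codes == c) for c in range(cell_codes.max() + 1)
        ]

    # -- internals ---------------------------------------------------------

    def _fit_all(self, y: np.ndarray, idx: np.ndarray | None = None):
        """Fit every spec on response ``y`` (optionally row-resampled)."""
        X = self._Xm if idx is None else self._Xm[idx]
        codes = self._codes if idx is None else self._codes[idx]
        st_full = _group_stats(y, X, codes, self._q)
        fits = []
        for spec, cols in zip(self.specs, self._spec_cols):
            st = {
                "XtX": st_full["XtX"][np.ix_(cols, cols)],
                "Xty": st_full["Xty"][cols],
                "yty": st_full["yty"],
                "SX": st_full["SX"][:, cols],
                "Sy": st_full["Sy"],
                "nj": st_full["nj"],
                "n": st_full["n"],
            }
            sol = _ml_solve(st)
            fits.append(LMMFit(
                spec=spec,
                terms=tuple(self._master_cols[c] for c in cols),
                params=sol["beta"], bse=np.sqrt(np.diag(sol["cov"])),
                llf=sol["llf"], sigma2_resid=sol["sigma2_resid"],
                sigma2_group=sol["sigma2_group"],
                var_fixed=sol["var_fixed"], n=st["n"], k_fixed=len(cols),
            ))
        return fits

    def _comparison(self, fits):
        a = np.array([aicc(f.llf, f.k, f.n) for f in fits])
        w = akaike_weights(a)
        return a, w

    # -- public API --------------------------------------------------------

    def fit(self, n_boot: int = 100, seed=None) -> "DiversityModelSetResults":
        """Run the full comparison; ``n_boot`` bootstrap replicates add
        percentile CIs and the model-rank stability check (0 disables)."""
        fits = self._fit_all(self._y)
        aiccs, weights = self._comparison(fits)
        order = np.argsort(aiccs, kind="stable")
        rows = []
        for i in order:
            f = fits[i]
            rm, rc = r2_nakagawa(f)
            rows.append({
                "model": f.spec.label, "k": f.k, "loglik": f.llf,
                "AICc": aiccs[i], "dAICc": aiccs[i] - aiccs.min(),
                "wAICc": weights[i], "Rm2": rm, "Rc2": rc,
            })
        table = pd.DataFrame(rows)
        avg = averaged_std_coefs(fits, weights)

        boot_z = None
        stability = None
        ci = {}
        if n_boot:
            if n_boot < 2:
                raise ValueError("need at least 2 bootstrap replicates")
            rng = np.random.default_rng(seed)
            if any(len(c) == 0 for c in self._cells):
                raise ValueError("empty condition × plot cell")
            top_spec = fits[order[0]].spec
            zrows = []
            top_hits = 0
            for _ in range(n_boot):
                idx = np.concatenate([
                    c[rng.integers(0, len(c), size=len(c))]
                    for c in self._cells
                ])
                bfits = self._fit_all(self._y[idx], idx)
                ba, bw = self._comparison(bfits)
                if bfits[int(np.argmin(ba))].spec == top_spec:
                    top_hits += 1
                zrows.append(averaged_std_coefs(bfits, bw))
            boot_z = pd.DataFrame(zrows)
            stability = top_hits / n_boot
            for term in boot_z.columns:
                col = boot_z[term].to_numpy(float)
                ci[term] = (
                    float(np.mean(col)),
                    float(np.percentile(col, 2.5)),
                    float(np.percentile(col, 97.5)),
                )

        coef_rows = []
        for term, z in avg.items():
            row = {"term": term, "z": z}
            if term in ci:
                row.update(zip(("boot_mean", "ci_low", "ci_high"), ci[term]))
            coef_rows.append(row)
        coefs = pd.DataFrame(coef_rows)
        return DiversityModelSetResults(
            metric=self.metric, model_table=table, averaged_coefs=coefs,
            fits=[fits[i] for i in order], bootstrap_z=boot_z,
            top_model_stability=stability,
        )


@dataclass
class DiversityModelSetResults:
    """Fitted multi-model comparison for one metric."""

    metric: str | None
    model_table: pd.DataFrame
    averaged_coefs: pd.DataFrame
    fits: list = field(repr=False)
    bootstrap_z: pd.DataFrame | None = field(default=None, repr=False)
    top_model_stability: float | None = None

    @property
    def top_model(self) -> LMMFit:
        return self.fits[0]

    def summary(self, n_models: int = 5) -> str:
        lines = [
            f"Multi-model inference for {self.metric or 'response'}",
            f"  models fitted: {len(self.fits)}, n = {self.fits[0].n}",
        ]
        if self.top_model_stability is not None:
            lines.append(
                "  top model stable in "
                f"{100 * self.top_model_stability:.0f}% of bootstrap replicates"
            )
        lines.append("")
        sub = self.model_table.head(n_models)
        lines.append(
            sub.to_string(
                index=False,
                formatters={
                    "AICc": "{:.1f}".format, "dAICc": "{:.1f}".format,
                    "wAICc": "{:.3f}".format, "loglik": "{:.1f}".format,
                    "Rm2": "{:.2f}".format, "Rc2": "{:.2f}".format,
                },
            )
        )
        lines.append("")
        lines.append("Averaged standardized coefficients (beta/SE):")
        lines.append(self.averaged_coefs.to_string(index=False))
        return "\n".join(lines)


def bootstrap_inference(data: pd.DataFrame, metric: str | None = None,
                        B: int = 100, seed=None,
                        specs: Sequence[ModelSpec] | None = None,
                        ) -> DiversityModelSetResults:
    """Resampling robustness check: rerun the full multi-model comparison on
    ``B`` stratified (condition × plot) resamples of the diversity table."""
    return DiversityModelSet(data, metric=metric, specs=specs).fit(
        n_boot=B, seed=seed
    )
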