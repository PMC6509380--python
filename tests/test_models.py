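"""Mixed-effects fits, AICc machinery, model averaging and the bootstrap."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from phylodiv.models import (
    DiversityModelSet, LMMFit, ModelSpec, aicc, akaike_weights,
    averaged_std_coefs, enumerate_models, fit_lmm, r2_nakagawa,
)

TERMS = ("backbone", "matK", "rbcL", "ITS", "ITS2")


def _synth_table(rng, n_per_cell=30, beta=None, plot_sd=0.4, noise=0.25,
                 plots=("600m", "100m")):
    """Balanced indicator design over the 14 conditions × plots."""
    from phylodiv.conditions import enumerate_conditions

    beta = beta or {}
    rows = []
    plot_eff = {p: rng.normal(0, plot_sd) for p in plots}
    for cond in enumerate_conditions():
        ind = cond.indicators
        mu = 1.0 + sum(beta.get(t, 0.0) * ind[t] for t in TERMS)
        for p in plots:
            vals = np.exp(mu + plot_eff[p] + rng.normal(0, noise, n_per_cell))
            for v in vals:
                rows.append({**ind, "plot": p, "value": v, "metric": "PD"})
    return pd.DataFrame(rows)


class TestEnumeration:
    def test_24_specs_with_intercept_only(self):
        specs = enumerate_models()
        assert len(specs) == 24
        assert len(set(specs)) == 24
        assert ModelSpec(frozenset()) in specs

    def test_contains_full_table_top_model(self):
        specs = enumerate_models()
        target = ModelSpec(frozenset({"backbone", "matK", "rbcL", "ITS"}))
        assert target in specs
        assert target.label == "~B + M + R + I"

    def test_no_its_its2_cooccurrence(self):
        for s in enumerate_models():
            assert not ({"ITS", "ITS2"} <= s.terms)
        with pytest.raises(ValueError):
            ModelSpec(frozenset({"ITS", "ITS2"}))


class TestFitLMM:
    def test_matches_statsmodels_ml(self, rng):
        df = _synth_table(rng, n_per_cell=10,
                          beta={"rbcL": 0.3, "ITS": -0.2}, plot_sd=0.5)
        spec = ModelSpec(frozenset({"rbcL", "ITS", "backbone"}))
        mine = fit_lmm(df, spec)
        df = df.assign(logv=np.log(df["value"]))
        ref = smf.mixedlm(
            "logv ~ backbone + rbcL + ITS", df, groups=df["plot"]
        ).fit(reml=False)
        assert mine.llf == pytest.approx(ref.llf, abs=1e-5)
        assert np.allclose(
            np.sort(mine.params), np.sort(ref.fe_params.values), atol=1e-5
        )
        assert np.allclose(
            np.sort(mine.bse), np.sort(ref.bse_fe.values), atol=1e-3
        )
        assert mine.sigma2_resid == pytest.approx(ref.scale, rel=1e-4)

    def test_zero_between_plot_variance_matches_ols(self, rng):
        df = _synth_table(rng, n_per_cell=8, beta={"matK": 0.4}, plot_sd=0.0)
        spec = ModelSpec(frozenset({"matK"}))
        fit = fit_lmm(df, spec)
        y = np.log(df["value"].to_numpy())
        X = np.column_stack([np.ones(len(df)), df["matK"].to_numpy(float)])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.sigma2_group == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(fit.params, beta_ols, atol=1e-6)

    def test_intercept_only_constant_response(self):
        df = pd.DataFrame({
            "plot": ["a", "a", "b", "b"] * 3,
            "value": [np.e ** 2.0] * 12,
            **{t: [0, 1] * 6 for t in TERMS},
        })
        fit = fit_lmm(df, ModelSpec(frozenset()))
        assert fit.params[0] == pytest.approx(2.0)
        assert fit.sigma2_resid == pytest.approx(0.0, abs=1e-10)

    def test_loglik_nondecreasing_in_nested_models(self, rng):
        df = _synth_table(rng, n_per_cell=6, beta={"ITS": 0.3})
        prev = fit_lmm(df, ModelSpec(frozenset())).llf
        chain = [{"ITS"}, {"ITS", "rbcL"}, {"ITS", "rbcL", "matK"},
                 {"ITS", "rbcL", "matK", "backbone"}]
        for terms in chain:
            cur = fit_lmm(df, ModelSpec(frozenset(terms))).llf
            assert cur >= prev - 1e-6
            prev = cur

    def test_parameter_recovery_backbone_effect(self, rng):
        """Injected backbone effect of 0.5 is recovered within 3 SE."""
        hits = 0
        spec = ModelSpec(frozenset({"backbone"}))
        for _ in range(100):
            df = _synth_table(rng, n_per_cell=5, beta={"backbone": 0.5},
                              plot_sd=0.3, noise=0.3)
            fit = fit_lmm(df, spec)
            i = fit.terms.index("backbone")
            if abs(fit.params[i] - 0.5) <= 3 * fit.bse[i]:
                hits += 1
        assert hits >= 95

    def test_nonpositive_response_policy(self, rng):
        df = _synth_table(rng, n_per_cell=2)
        df.loc[0, "value"] = -1.0
        with pytest.raises(ValueError, match="log"):
            fit_lmm(df, ModelSpec(frozenset({"rbcL"})))

    def test_constant_term_dropped_with_warning(self, rng):
        df = _synth_table(rng, n_per_cell=2)
        df["ITS2"] = 0
        with pytest.warns(UserWarning, match="ITS2"):
            fit = fit_lmm(df, ModelSpec(frozenset({"ITS2", "rbcL"})))
        assert "ITS2" not in fit.terms


class TestAICcMachinery:
    def test_aicc_closed_form(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7, abs=1e-9)
        with pytest.raises(ValueError):
            aicc(0.0, 9, 10)

    def test_aicc_large_n_limit(self):
        k = 5
        assert aicc(-100.0, k, 10 ** 9) == pytest.approx(
            200 + 2 * k, abs=1e-6
        )

    def test_weights_closed_form(self):
        w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-9)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_weights_uniform_and_shift_invariant(self, rng):
        a = rng.normal(size=6) * 10
        assert np.allclose(akaike_weights(a), akaike_weights(a + 1234.5))
        assert np.allclose(akaike_weights([3.0] * 4), 0.25)

    def test_r2_arithmetic(self):
        fit = LMMFit(
            spec=ModelSpec(frozenset()), terms=("Intercept",),
            params=np.array([0.0]), bse=np.array([1.0]), llf=0.0,
            sigma2_resid=1.0, sigma2_group=2.0, var_fixed=1.0, n=10, k_fixed=1,
        )
        rm, rc = r2_nakagawa(fit)
        assert (rm, rc) == (pytest.approx(25.0), pytest.approx(75.0))

    def test_r2_no_group_variance(self):
        fit = LMMFit(
            spec=ModelSpec(frozenset()), terms=("Intercept",),
            params=np.array([0.0]), bse=np.array([1.0]), llf=0.0,
            sigma2_resid=1.0, sigma2_group=0.0, var_fixed=3.0, n=10, k_fixed=1,
        )
        rm, rc = r2_nakagawa(fit)
        assert rm == pytest.approx(rc)

    def test_intercept_only_rm2_zero(self, rng):
        df = _synth_table(rng, n_per_cell=4)
        fit = fit_lmm(df, ModelSpec(frozenset()))
        rm, rc = r2_nakagawa(fit)
        assert rm == pytest.approx(0.0, abs=1e-12)
        assert 0 <= rm <= rc <= 100


def _fake_fit(terms_z: dict, n=100) -> LMMFit:
    terms = ("Intercept",) + tuple(terms_z)
    params = np.array([1.0] + [z for z in terms_z.values()], float)
    bse = np.ones(len(terms))
    return LMMFit(
        spec=ModelSpec(frozenset(terms_z)), terms=terms, params=params,
        bse=bse, llf=0.0, sigma2_resid=1.0, sigma2_group=0.0,
        var_fixed=0.0, n=n, k_fixed=len(terms),
    )


class TestAveraging:
    def test_term_in_every_model(self):
        fits = [_fake_fit({"rbcL": 2.0, "matK": 1.0}),
                _fake_fit({"rbcL": 2.0})]
        out = averaged_std_coefs(fits, [0.3, 0.7])
        assert out["rbcL"] == pytest.approx(2.0)

    def test_single_model_term_ignores_global_weight(self):
        fits = [_fake_fit({"rbcL": 2.0}), _fake_fit({"matK": 5.0})]
        out = averaged_std_coefs(fits, [0.99, 0.01])
        assert out["matK"] == pytest.approx(5.0)

    def test_renormalized_two_model_average(self):
        fits = [_fake_fit({"ITS": 2.0}), _fake_fit({"ITS": 3.0}),
                _fake_fit({"rbcL": 1.0})]
        # global weights 0.3/0.2/0.5 -> renormalized over ITS models 0.6/0.4
        out = averaged_std_coefs(fits, [0.3, 0.2, 0.5])
        assert out["ITS"] == pytest.approx(0.6 * 2.0 + 0.4 * 3.0)

    def test_absent_term_absent_from_output(self):
        out = averaged_std_coefs([_fake_fit({"rbcL": 1.0})], [1.0])
        assert "ITS2" not in out


class TestDiversityModelSet:
    def test_comparison_invariants(self, rng):
        df = _synth_table(rng, n_per_cell=5, beta={"ITS": 0.4})
        res = DiversityModelSet(df, metric="PD").fit(n_boot=0)
        t = res.model_table
        assert len(t) == 24
        assert t["dAICc"].iloc[0] == 0.0
        assert (t["dAICc"] >= 0).all()
        assert t["wAICc"].sum() == pytest.approx(1.0, abs=1e-12)
        assert ((t["Rm2"] >= 0) & (t["Rm2"] <= t["Rc2"])
                & (t["Rc2"] <= 100)).all()
        assert t["AICc"].is_monotonic_increasing

    def test_true_model_top_ranked_large_effect(self, rng):
        df = _synth_table(rng, n_per_cell=10, beta={"ITS": 1.0},
                          plot_sd=0.2, noise=0.15)
        res = DiversityModelSet(df, metric="PD").fit(n_boot=0)
        assert "ITS" in res.top_model.spec.terms

    def test_bootstrap_deterministic_and_ci(self, rng):
        df = _synth_table(rng, n_per_cell=4, beta={"backbone": 0.8})
        r1 = DiversityModelSet(df, metric="PD").fit(n_boot=20, seed=5)
        r2 = DiversityModelSet(df, metric="PD").fit(n_boot=20, seed=5)
        pd.testing.assert_frame_equal(r1.averaged_coefs, r2.averaged_coefs)
        row = r1.averaged_coefs.set_index("term").loc["backbone"]
        assert row["ci_low"] <= row["boot_mean"] <= row["ci_high"]
        assert row["ci_low"] > 0  # strong effect: CI excludes 0
        assert 0 <= r1.top_model_stability <= 1

    def test_bootstrap_degenerate_data_zero_width_ci(self):
        # zero within-cell variance -> resampling returns identical data
        from phylodiv.conditions import enumerate_conditions

        rows = []
        for cond in enumerate_conditions():
            ind = cond.indicators
            v = float(np.exp(1.0 + 0.5 * ind["ITS"]))
            for p in ("600m", "100m"):
                rows.extend([{**ind, "plot": p, "value": v}] * 3)
        df = pd.DataFrame(rows)
        res = DiversityModelSet(df).fit(n_boot=10, seed=0)
        coefs = res.averaged_coefs.dropna()
        widths = coefs["ci_high"] - coefs["ci_low"]
        assert np.allclose(widths, 0.0, atol=1e-8)

    def test_zero_offset_policy_warns(self, rng):
        df = _synth_table(rng, n_per_cell=2)
        df.loc[df.index[0], "value"] = 0.0
        with pytest.warns(UserWarning, match="offset"):
            DiversityModelSet(df, metric="PD")

    def test_summary_mentions_top_model(self, rng):
        df = _synth_table(rng, n_per_cell=3)
        res = DiversityModelSet(df, metric="PD").fit(n_boot=0)
        s = res.summary()
        assert "Multi-model inference for PD" in s
        assert res.model_table["model"].iloc[0] in s
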