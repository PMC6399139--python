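"""Likelihoods, fits and diagnostics of the count-model families."""

import numpy as np
import pandas as pd
import pytest

import dasycanine as dc
from dasycanine.count_models import FitError, ModelSpec


def _table(y, e, **cov):
    return pd.DataFrame({"y": y, "e": e, **cov})


class TestLogLikelihood:
    def test_poisson_single_row_closed_form(self):
        """y=0, mu=1 -> log f = -mu = -1."""
        t = _table([0], [1.0])
        spec = ModelSpec("poisson")
        ll = dc.log_likelihood(spec, {"alpha": 0.0, "beta": {}}, t)
        assert ll == pytest.approx(-1.0)

    def test_zip_with_no_inflation_reduces_to_poisson(self, sim_table):
        pois = ModelSpec("poisson", dc.COUNT_COVARIATES)
        zip_ = ModelSpec("zip", dc.COUNT_COVARIATES)
        params = {"alpha": -5.0, "beta": {c: 0.01 for c in dc.COUNT_COVARIATES}}
        ll_p = dc.log_likelihood(pois, params, sim_table)
        ll_z = dc.log_likelihood(
            zip_, {**params, "gamma": {"intercept": -np.inf}}, sim_table)
        assert ll_z == pytest.approx(ll_p, abs=1e-9)

    def test_negbin_large_theta_approaches_poisson(self):
        rng = np.random.default_rng(8)
        t = _table(rng.poisson(2.0, 50), np.full(50, 100.0),
                   x=rng.normal(size=50))
        p = {"alpha": -4.0, "beta": {"x": 0.3}}
        ll_pois = dc.log_likelihood(ModelSpec("poisson", ("x",)), p, t)
        ll_nb = dc.log_likelihood(ModelSpec("negbin", ("x",)),
                                  {**p, "theta": 1e6}, t)
        assert abs(ll_nb - ll_pois) < 1e-3

    def test_invalid_inputs_rejected(self):
        t = _table([1], [1.0])
        with pytest.raises(ValueError):
            dc.log_likelihood(ModelSpec("poisson"), {"alpha": np.nan, "beta": {}}, t)
        with pytest.raises(ValueError):
            dc.log_likelihood(ModelSpec("negbin"),
                              {"alpha": 0.0, "beta": {}, "theta": -1.0}, t)
        with pytest.raises(ValueError):
            dc.log_likelihood(ModelSpec("poisson"), {"alpha": 0.0, "beta": {}},
                              _table([-1], [1.0]))
        with pytest.raises(ValueError):
            dc.log_likelihood(ModelSpec("poisson"), {"alpha": 0.0, "beta": {}},
                              _table([1], [0.0]))


class TestFit:
    def test_intercept_only_poisson_closed_form(self, sim_table):
        f = dc.fit(ModelSpec("poisson"), sim_table)
        expected = np.log(sim_table["y"].sum() / sim_table["e"].sum())
        assert f.alpha == pytest.approx(expected, abs=1e-8)

    def test_offset_rescaling_shifts_intercept_only(self, sim_table):
        spec = ModelSpec("poisson", ("DogAverageAge", "AverageIncomeTax"))
        f1 = dc.fit(spec, sim_table)
        c = 7.5
        t2 = sim_table.copy()
        t2["e"] = t2["e"] * c
        f2 = dc.fit(spec, t2)
        assert f2.alpha == pytest.approx(f1.alpha - np.log(c), abs=1e-6)
        for k in spec.count_covariates:
            assert f2.beta[k] == pytest.approx(f1.beta[k], abs=1e-6)

    def test_zero_inflated_families_nest_their_base(self, sim_table):
        fits = {}
        for fam in ("poisson", "zip", "negbin", "zinb"):
            zi = ("DogAverageAge",) if fam in ("zip", "zinb") else ()
            fits[fam] = dc.fit(ModelSpec(fam, dc.COUNT_COVARIATES, zi), sim_table)
        tol = 1e-6
        assert fits["zip"].loglik >= fits["poisson"].loglik - tol
        assert fits["zinb"].loglik >= fits["negbin"].loglik - tol
        assert fits["negbin"].loglik >= fits["poisson"].loglik - tol

    def test_negbin_beats_poisson_on_overdispersed_data(self):
        t = dc.simulate_unit_table(800, 21)
        truth = dc.TruthParams(alpha=-5.0, beta={"DogAverageAge": -0.2},
                               theta=0.4, gamma={})
        t["y"] = dc.generate_cancer_counts(t, truth, 22)
        spec_p = ModelSpec("poisson", ("DogAverageAge",))
        spec_nb = ModelSpec("negbin", ("DogAverageAge",))
        assert dc.fit(spec_nb, t).loglik > dc.fit(spec_p, t).loglik

    def test_matches_statsmodels_poisson_and_negbin(self, sim_table):
        sm = pytest.importorskip("statsmodels.api")
        cov = ["DogAverageAge", "AverageIncomeTax", "HumanPopulationDensity"]
        X = sm.add_constant(sim_table[cov])
        off = np.log(sim_table["e"])
        f = dc.fit(ModelSpec("poisson", tuple(cov)), sim_table)
        ref = sm.GLM(sim_table["y"], X, family=sm.families.Poisson(),
                     offset=off).fit()
        got = np.r_[f.alpha, [f.beta[c] for c in cov]]
        np.testing.assert_allclose(got, ref.params.values, rtol=1e-6, atol=1e-8)
        assert f.loglik == pytest.approx(ref.llf, abs=1e-6)

        f = dc.fit(ModelSpec("negbin", tuple(cov)), sim_table)
        ref = sm.NegativeBinomial(sim_table["y"], X, offset=off).fit(disp=0)
        got = np.r_[f.alpha, [f.beta[c] for c in cov]]
        # agreement is limited by statsmodels' own optimizer tolerance
        np.testing.assert_allclose(got, ref.params.values[:-1], rtol=1e-3,
                                   atol=2e-4)
        assert f.theta == pytest.approx(1.0 / ref.params.values[-1], rel=1e-3)
        assert f.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert f.loglik >= ref.llf - 1e-6  # our optimum is no worse

    def test_zinb_likelihood_matches_statsmodels(self, sim_table):
        smd = pytest.importorskip("statsmodels.discrete.count_model")
        sm = pytest.importorskip("statsmodels.api")
        cov = ("DogAverageAge", "AverageIncomeTax")
        spec = ModelSpec("zinb", cov, ("DogAverageAge",))
        X = sm.add_constant(sim_table[list(cov)])
        Z = sm.add_constant(sim_table[["DogAverageAge"]])
        model = smd.ZeroInflatedNegativeBinomialP(
            sim_table["y"], X, exog_infl=Z, offset=np.log(sim_table["e"]), p=2)
        rng = np.random.default_rng(3)
        for _ in range(4):
            a = -5.0 + rng.normal(0, 0.3)
            b = rng.normal([-0.2, 0.11], 0.05)
            th = float(np.exp(rng.normal(0.4, 0.3)))
            g = rng.normal([1.5, -0.6], 0.2)
            mine = dc.log_likelihood(spec, {
                "alpha": a, "beta": dict(zip(cov, b)), "theta": th,
                "gamma": {"intercept": g[0], "DogAverageAge": g[1]}}, sim_table)
            ref = model.loglike(np.r_[g, a, b, 1.0 / th])
            assert mine == pytest.approx(ref, abs=1e-8)

    def test_aic_and_param_count_conventions(self, sim_table):
        f = dc.fit(ModelSpec("zinb", dc.COUNT_COVARIATES, ("DogAverageAge",)),
                   sim_table)
        assert f.n_params == 1 + 6 + 1 + 2  # alpha, betas, theta, gammas
        assert f.aic == pytest.approx(2 * f.n_params - 2 * f.loglik)
        assert f.theta > 0

    def test_degenerate_designs_rejected(self, sim_table):
        t = sim_table.copy()
        t["flat"] = 1.0
        with pytest.raises(FitError, match="constant"):
            dc.fit(ModelSpec("poisson", ("flat",)), t)
        with pytest.raises(FitError, match="rows"):
            dc.fit(ModelSpec("poisson", dc.COUNT_COVARIATES), t.head(5))
        with pytest.raises(ValueError):
            ModelSpec("poisson", zi_covariates=("DogAverageAge",))
        with pytest.raises(ValueError):
            ModelSpec("weibull")


class TestMultiplicativeEffect:
    def test_identity_and_monotonicity(self):
        assert dc.multiplicative_effect(0.0) == 0.0
        bs = np.linspace(-1, 1, 11)
        vals = [dc.multiplicative_effect(b, decimals=None) for b in bs]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_formula(self):
        assert dc.multiplicative_effect(np.log(2.0)) == pytest.approx(100.0)
        assert dc.multiplicative_effect(-0.19) == -17.3
        assert dc.multiplicative_effect(-3.61) == -97.3


class TestSqvif:
    def test_bivariate_closed_form(self):
        """Exact sample correlation 0.9 -> VIF = 1/(1-0.81) = 5.263."""
        rng = np.random.default_rng(5)
        n = 400
        x1 = rng.normal(size=n)
        x1 = (x1 - x1.mean()) / x1.std()
        z = rng.normal(size=n)
        z = z - x1 * (z @ x1) / (x1 @ x1)  # orthogonalize
        z = (z - z.mean()) / z.std()
        x2 = 0.9 * x1 + np.sqrt(1 - 0.81) * z
        out = dc.sqvif(pd.DataFrame({"a": x1, "b": x2}), ["a", "b"])
        assert out.loc["a", "sqvif"] ** 2 == pytest.approx(1 / (1 - 0.81), rel=1e-6)
        assert out.loc["a", "sqvif"] == pytest.approx(2.294, abs=0.001)
        assert not out["ok"].any()

    def test_independent_covariates_near_one(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame(rng.normal(size=(10_000, 2)), columns=["a", "b"])
        out = dc.sqvif(t, ["a", "b"])
        assert out["sqvif"].max() == pytest.approx(1.0, abs=0.02)
        assert out["ok"].all()

    def test_collinear_rejected(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=100)
        with pytest.raises(ValueError, match="collinear"):
            dc.sqvif(pd.DataFrame({"a": a, "b": 2 * a}), ["a", "b"])


class TestDevianceReduction:
    def test_single_covariate_reduces_to_null_formula(self):
        t = dc.simulate_unit_table(600, 31)
        truth = dc.TruthParams(alpha=-5.0, beta={"AverageIncomeTax": 0.2},
                               theta=5.0, gamma={})
        t["y"] = dc.generate_cancer_counts(t, truth, 32)
        spec = ModelSpec("poisson", ("AverageIncomeTax",))
        full = dc.fit(spec, t)
        null = dc.fit(ModelSpec("poisson"), t)
        dr = dc.deviance_reduction(spec, t, full)
        want = 100.0 * (null.deviance - full.deviance) / null.deviance
        assert dr["deviance_reduction_pct"].iloc[0] == pytest.approx(want, abs=1e-6)

    def test_null_covariate_has_near_zero_reduction_and_ranking(self):
        t = dc.simulate_unit_table(1200, 41)
        truth = dc.TruthParams(alpha=-5.0, beta={"AverageIncomeTax": 0.25},
                               theta=5.0, gamma={})
        t["y"] = dc.generate_cancer_counts(t, truth, 42)
        spec = ModelSpec("poisson", ("AverageIncomeTax", "FemaleDogRatio"))
        full = dc.fit(spec, t)
        dr = dc.deviance_reduction(spec, t, full).set_index("covariate")
        assert dr.loc["FemaleDogRatio", "deviance_reduction_pct"] < 1.5
        assert (dr.loc["AverageIncomeTax", "deviance_reduction_pct"]
                > dr.loc["FemaleDogRatio", "deviance_reduction_pct"])


class TestZiSelection:
    def test_age_driven_zeros_retain_age_only(self):
        t = dc.simulate_unit_table(1500, 50)
        truth = dc.TruthParams(
            alpha=-5.0,
            beta={c: b for c, b in zip(dc.COUNT_COVARIATES,
                                       (-0.19, 0.01, 0.03, 0.11, 0.08, -0.04))},
            theta=2.0, gamma={"intercept": 4.0, "DogAverageAge": -1.0})
        t["y"] = dc.generate_cancer_counts(t, truth, 51)
        kept = dc.select_zi_covariates(t, list(dc.COUNT_COVARIATES),
                                       count_covariates=dc.COUNT_COVARIATES)
        assert kept == ["DogAverageAge"]

    def test_no_signal_reduces_to_intercept_only(self):
        t = dc.simulate_unit_table(1000, 60)
        truth = dc.TruthParams(alpha=-5.0, beta={"AverageIncomeTax": 0.11},
                               theta=2.0, gamma={"intercept": -1.5})
        t["y"] = dc.generate_cancer_counts(t, truth, 61)
        kept = dc.select_zi_covariates(
            t, ["DogAverageAge", "FemaleDogRatio"],
            count_covariates=("AverageIncomeTax",))
        assert kept == []

    def test_strong_candidates_all_retained(self):
        t = dc.simulate_unit_table(1500, 70)
        truth = dc.TruthParams(
            alpha=-5.0, beta={"MixedBreedRatio": 0.03}, theta=2.0,
            gamma={"intercept": 4.5, "DogAverageAge": -1.0,
                   "AverageIncomeTax": -0.5})
        t["y"] = dc.generate_cancer_counts(t, truth, 71)
        kept = dc.select_zi_covariates(
            t, ["DogAverageAge", "AverageIncomeTax"],
            count_covariates=("MixedBreedRatio",))
        assert set(kept) == {"DogAverageAge", "AverageIncomeTax"}
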