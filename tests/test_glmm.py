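"""Mixed-model fitting, information criteria, averaging, VIF, curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import riskscape as rs
from riskscape.glmm import ModelSpec


def _rows(n_sites=10, per_site=2, seed=0, **cov):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_sites):
        for j, diel in zip(range(per_site), ["day", "night"] * per_site):
            recs.append(
                {
                    "site_id": f"s{i:02d}",
                    "diel": diel,
                    "effort_days": 100.0,
                    "V": cov.get("V", rng.uniform(0, 1)),
                    "R": rng.uniform(0, 1),
                    "E": rng.uniform(0, 1),
                    "K": rng.uniform(0, 1),
                }
            )
    return pd.DataFrame(recs)


class TestCandidateSet:
    def test_fourteen_unique_models(self):
        specs = rs.candidate_set()
        assert len(specs) == 14
        assert len({s.terms for s in specs}) == 14

    def test_marginality_in_every_spec(self):
        for s in rs.candidate_set():
            for t in s.terms:
                if ":" in t:
                    a, b = t.split(":")
                    assert a in s.terms and b in s.terms

    def test_interaction_without_main_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", ("T", "T:V"))


class TestAicc:
    def test_closed_form(self):
        assert rs.aicc(-100.0, 3, 50) == pytest.approx(206.5217, abs=1e-4)

    def test_approaches_aic_for_large_n(self):
        aic = -2 * (-100.0) + 2 * 3
        assert rs.aicc(-100.0, 3, 10**7) == pytest.approx(aic, abs=1e-4)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rs.aicc(-10.0, 5, 6)


class TestAkaikeWeights:
    def test_delta_zero_two(self):
        w = rs.akaike_weights([100.0, 102.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_equal_values_equal_weights(self):
        np.testing.assert_allclose(rs.akaike_weights([5.0, 5.0, 5.0]), 1 / 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(-100, 100), min_size=1, max_size=10),
        shift=st.floats(-50, 50),
    )
    def test_sum_one_and_shift_invariance(self, vals, shift):
        w = rs.akaike_weights(vals)
        assert w.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(w, rs.akaike_weights(np.asarray(vals) + shift))


class TestFitPoissonGlmm:
    def test_sigma_zero_reduces_to_plain_poisson(self, landscape):
        """When the random effect vanishes the fit equals a Poisson GLM."""
        import statsmodels.api as sm

        _, dem, chm = landscape
        truth = rs.TruthModel(beta={"V": -2.0}, sigma_camera=0.0, baseline_rate=20.0)
        sv = rs.gen_camera_survey(dem, chm, None, truth, n_sites=40,
                                  days_per_site=100, seed=1)
        rows = sv.truth_rows
        fit = rs.fit_poisson_glmm(rows, ModelSpec("m", ("V",)))
        assert fit.sigma_site == 0.0
        X, _ = rs.build_design(rows, ModelSpec("m", ("V",)))
        glm = sm.GLM(
            rows["count"].to_numpy(float), X, family=sm.families.Poisson(),
            offset=np.log(rows["effort_days"].to_numpy() / 100.0),
        ).fit()
        np.testing.assert_allclose(fit.beta.to_numpy(), glm.params, atol=1e-4)
        assert fit.logLik == pytest.approx(glm.llf, abs=1e-6)

    def test_loglik_matches_quadrature_oracle_two_sites(self):
        """Marginal logLik vs brute-force integration over the intercepts.

        Evaluated at fixed parameters (two sites carry almost no
        information about sigma, so the MLE would sit on the boundary).
        """
        from scipy import integrate, special

        from riskscape.glmm import _marginal_loglik, _site_blocks

        rows = _rows(n_sites=2, seed=3)
        rng = np.random.default_rng(4)
        truth = rs.TruthModel(beta={"V": -1.0}, sigma_camera=0.7, baseline_rate=15.0)
        rows = rs.simulate_counts(rows, truth, rng)
        spec = ModelSpec("m", ("V",))
        beta = np.array([np.log(15.0), -1.0])
        sig = 0.7
        X, _ = rs.build_design(rows, spec)
        y = rows["count"].to_numpy(float)
        offset = np.log(rows["effort_days"].to_numpy() / 100.0)
        codes, n_sites = _site_blocks(rows)
        theta = np.concatenate([beta, [np.log(sig)]])
        got = _marginal_loglik(
            theta, y, X, offset, codes, n_sites,
            float(special.gammaln(y + 1).sum()), "agq", 25,
        )
        eta = offset + X @ beta
        ll = -special.gammaln(y + 1).sum()
        for sid in sorted(rows["site_id"].unique()):
            m = (rows["site_id"] == sid).to_numpy()

            def logjoint(b, m=m):
                return (
                    np.sum(y[m] * (eta[m] + b) - np.exp(eta[m] + b))
                    - b**2 / (2 * sig**2)
                )

            bgrid = np.linspace(-10 * sig, 10 * sig, 401)
            shift = max(logjoint(b) for b in bgrid)  # avoid underflow

            def integrand(b, m=m, shift=shift):
                return np.exp(logjoint(b, m) - shift) / np.sqrt(2 * np.pi * sig**2)

            val, _ = integrate.quad(integrand, -10 * sig, 10 * sig, limit=200)
            ll += shift + np.log(val)
        assert got == pytest.approx(ll, abs=1e-6)

    def test_laplace_close_to_agq_high_information(self):
        """Laplace and adaptive quadrature agree when per-site counts are large."""
        rows = _rows(n_sites=8, seed=5)
        rows["effort_days"] = 5000.0
        rng = np.random.default_rng(6)
        truth = rs.TruthModel(beta={"V": -1.0}, sigma_camera=0.5, baseline_rate=20.0)
        rows = rs.simulate_counts(rows, truth, rng)
        spec = ModelSpec("m", ("V",))
        fl = rs.fit_poisson_glmm(rows, spec, method="laplace")
        fa = rs.fit_poisson_glmm(rows, spec, method="agq", n_quad=25)
        assert abs(fl.logLik - fa.logLik) < 1e-3

    def test_intercept_recovers_log_mean_rate(self):
        """With no covariate effects the intercept is log(groups per 100 d)."""
        rng = np.random.default_rng(7)
        rows = _rows(n_sites=150, seed=8)
        truth = rs.TruthModel(beta={}, sigma_camera=0.0, baseline_rate=12.0)
        rows = rs.simulate_counts(rows, truth, rng)
        fit = rs.fit_poisson_glmm(rows, ModelSpec("null", ()))
        mc_se = 1.0 / np.sqrt(rows["count"].sum())
        assert fit.beta["(Intercept)"] == pytest.approx(np.log(12.0), abs=4 * mc_se)

    def test_single_site_rejected(self):
        rows = _rows(n_sites=1)
        rows["count"] = 1
        with pytest.raises(ValueError):
            rs.fit_poisson_glmm(rows, ModelSpec("null", ()))


class TestModelAverage:
    def _fake_fit(self, name, terms, beta, se, weight, aicc_val):
        idx = ["(Intercept)"] + list(terms)
        f = rs.FitResult(
            spec=ModelSpec(name, tuple(terms)),
            beta=pd.Series(beta, index=idx), se=pd.Series(se, index=idx),
            z=pd.Series(0.0, index=idx), p=pd.Series(1.0, index=idx),
            sigma_site=0.1, logLik=-10.0, k=len(terms) + 2, n_obs=50,
            converged=True,
        )
        f.weight = weight
        f.aicc = aicc_val
        return f

    def test_dominant_best_model_skips_averaging(self):
        f1 = self._fake_fit("a", ["V"], [1.0, 2.0], [0.1, 0.2], 0.96, 100.0)
        f2 = self._fake_fit("b", [], [1.1], [0.1], 0.04, 110.0)
        avg = rs.model_average([f1, f2], 0.95)
        assert not avg.averaged
        assert avg.model_names == ["a"]
        assert avg.beta["V"] == 2.0

    def test_weighted_mean_two_models(self):
        f1 = self._fake_fit("a", ["V"], [0.0, 1.0], [0.1, 0.2], 0.6, 100.0)
        f2 = self._fake_fit("b", ["V"], [0.0, 2.0], [0.1, 0.3], 0.4, 101.0)
        avg = rs.model_average([f1, f2], 0.95)
        assert avg.averaged
        assert avg.beta["V"] == pytest.approx(0.6 * 1.0 + 0.4 * 2.0)

    def test_unconditional_se_formula(self):
        f1 = self._fake_fit("a", ["V"], [0.0, 1.0], [0.1, 0.2], 0.6, 100.0)
        f2 = self._fake_fit("b", ["V"], [0.0, 2.0], [0.1, 0.3], 0.4, 101.0)
        avg = rs.model_average([f1, f2], 0.95)
        bbar = 1.4
        expect = 0.6 * np.sqrt(0.2**2 + (1.0 - bbar) ** 2) + 0.4 * np.sqrt(
            0.3**2 + (2.0 - bbar) ** 2
        )
        assert avg.se["V"] == pytest.approx(expect)
        # unconditional SE cannot fall below the pure within-model average
        within = 0.6 * 0.2 + 0.4 * 0.3
        assert avg.se["V"] >= within


class TestVifScreen:
    def test_orthogonal_predictors_unit_vif(self):
        n = 64
        t = np.arange(n)
        df = pd.DataFrame(
            {
                "a": np.cos(2 * np.pi * t / n),
                "b": np.sin(2 * np.pi * t / n),
                "c": np.cos(4 * np.pi * t / n),
            }
        )
        vif, _ = rs.vif_screen(df, ["a", "b", "c"])
        np.testing.assert_allclose(vif.to_numpy(), 1.0, atol=1e-9)

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=50)
        vif, _ = rs.vif_screen(df, ["a", "b", "c"])
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])

    def test_matches_independent_least_squares(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=200)
        df = pd.DataFrame(
            {"a": a, "b": 0.7 * a + rng.normal(size=200), "c": rng.normal(size=200)}
        )
        vif, rho = rs.vif_screen(df, ["a", "b", "c"])
        X = np.column_stack([np.ones(200), df["b"], df["c"]])
        beta, _, _, _ = np.linalg.lstsq(X, df["a"], rcond=None)
        r2 = 1 - np.sum((df["a"] - X @ beta) ** 2) / np.sum((df["a"] - df["a"].mean()) ** 2)
        assert vif["a"] == pytest.approx(1 / (1 - r2))
        assert abs(rho.loc["a", "b"]) > 0.4


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(11)
    rows = _rows(n_sites=40, seed=12)
    truth = rs.TruthModel(beta={"V": -2.0}, sigma_camera=0.3, baseline_rate=20.0)
    rows = rs.simulate_counts(rows, truth, rng)
    fit = rs.fit_poisson_glmm(rows, ModelSpec("m", ("V",)))
    return fit, rows


class TestMarginalCurve:
    def test_forty_points_span_observed_range(self, fitted):
        fit, rows = fitted
        curve = rs.marginal_curve(fit, rows, "V")
        assert len(curve) == 40
        assert curve["x"].iloc[0] == pytest.approx(rows["V"].min())
        assert curve["x"].iloc[-1] == pytest.approx(rows["V"].max())

    def test_monotone_decreasing_for_negative_coefficient(self, fitted):
        fit, rows = fitted
        assert fit.beta["V"] < 0
        curve = rs.marginal_curve(fit, rows, "V")
        assert (np.diff(curve["p_median"]) <= 1e-12).all()

    def test_flat_curve_for_null_effect(self, fitted):
        fit, rows = fitted
        flat = rs.FitResult(
            spec=fit.spec, beta=fit.beta.copy(), se=fit.se, z=fit.z, p=fit.p,
            sigma_site=fit.sigma_site, logLik=fit.logLik, k=fit.k,
            n_obs=fit.n_obs, converged=True, ranef=fit.ranef,
        )
        flat.beta["V"] = 0.0
        curve = rs.marginal_curve(flat, rows, "V")
        assert curve["p_median"].std() < 1e-12

    def test_absent_focal_rejected(self, fitted):
        fit, rows = fitted
        with pytest.raises(ValueError):
            rs.marginal_curve(fit, rows, "K")
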