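import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from tempmort.basis import BasisSpec
from tempmort.crossbasis import ReducedCurve
from tempmort.stage2 import (MetaInput, blup, fit_meta, heterogeneity,
                             sample_curve_ensemble, wald_test)

SCALAR_SPEC = BasisSpec("bspline", (0.4,), (0.0, 1.0), degree=1)


def _scalar_input(theta, var, ids=None, predictors=None):
    curves = [ReducedCurve(coef=np.array([t]), vcov=np.array([[v]]),
                           spec=SCALAR_SPEC) for t, v in zip(theta, var)]
    ids = ids or [f"s{i}" for i in range(len(theta))]
    return MetaInput(location_ids=ids, curves=curves, predictors=predictors)


def _mvn_input(rng, k=10, q=3, psi_scale=0.02, predictors=None):
    curves = []
    for _ in range(k):
        A = rng.normal(size=(q, q)) * 0.1
        S = A @ A.T + 0.01 * np.eye(q)
        theta = rng.normal(scale=0.3, size=q)
        curves.append(ReducedCurve(coef=theta, vcov=S,
                                   spec=BasisSpec("bspline", (0.3, 0.6),
                                                  (0.0, 1.0), degree=1)))
    return MetaInput(location_ids=[f"s{i}" for i in range(k)], curves=curves,
                     predictors=predictors)


class TestFitMeta:
    def test_homogeneity_limit(self):
        """Identical estimates with identical vcov: fixed effect is the
        common value, Psi collapses, Q and I2 are exactly zero."""
        theta = np.array([0.4, 0.4, 0.4, 0.4, 0.4])
        model = fit_meta(_scalar_input(theta, np.full(5, 0.03)))
        assert abs(model.beta[0, 0] - 0.4) < 1e-10
        assert model.psi[0, 0] < 1e-8
        assert model.Q < 1e-16
        assert model.I2 == 0.0

    def test_univariate_reml_matches_scalar_oracle(self):
        """The general multivariate REML must reduce to the textbook
        scalar random-effects REML solution (independent closed-form
        profile likelihood optimized in one dimension)."""
        theta = np.array([0.2, 0.5, -0.1, 0.35, 0.6, 0.15, 0.05, 0.42])
        var = np.array([0.02, 0.05, 0.03, 0.01, 0.04, 0.02, 0.06, 0.03])

        def neg2reml(tau2):
            w = 1.0 / (var + tau2)
            mu = np.sum(w * theta) / np.sum(w)
            return (np.sum(np.log(var + tau2)) + np.log(np.sum(w))
                    + np.sum(w * (theta - mu) ** 2))

        res = minimize_scalar(lambda t: neg2reml(np.exp(t)), bounds=(-30, 5),
                              method="bounded", options={"xatol": 1e-14})
        tau2 = float(np.exp(res.x))
        w = 1.0 / (var + tau2)
        mu = float(np.sum(w * theta) / np.sum(w))

        model = fit_meta(_scalar_input(theta, var))
        assert abs(model.psi[0, 0] - tau2) < 1e-8
        assert abs(model.beta[0, 0] - mu) < 1e-8

    def test_known_psi_recovered_in_simulation(self, rng):
        """Averaged over replicates, REML recovers a known
        between-location covariance and the fixed effects are
        unbiased within Monte-Carlo error."""
        q, k, reps = 2, 80, 15
        psi_true = np.array([[0.04, 0.015], [0.015, 0.03]])
        mu_true = np.array([0.3, -0.1])
        L = np.linalg.cholesky(psi_true)
        spec2 = BasisSpec("bspline", (0.5,), (0.0, 1.0), degree=1)
        psis, betas = [], []
        for _ in range(reps):
            curves = []
            for _ in range(k):
                S = 0.004 * np.eye(q)
                theta = (mu_true + L @ rng.standard_normal(q)
                         + rng.multivariate_normal(np.zeros(q), S))
                curves.append(ReducedCurve(coef=theta, vcov=S, spec=spec2))
            model = fit_meta(MetaInput(
                location_ids=[str(i) for i in range(k)], curves=curves))
            psis.append(model.psi)
            betas.append(model.beta[0])
        psi_bar = np.mean(psis, axis=0)
        err = np.linalg.norm(psi_bar - psi_true) / np.linalg.norm(psi_true)
        assert err < 0.25
        mc_se = np.sqrt(np.diag(psi_true) / k / reps).max() * 4
        assert np.max(np.abs(np.mean(betas, axis=0) - mu_true)) < mc_se

    def test_too_few_locations_raises(self):
        theta = np.array([0.1, 0.2])
        pred = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 1.0]})
        with pytest.raises(ValueError, match="insufficient"):
            fit_meta(_scalar_input(theta, np.full(2, 0.01), predictors=pred))

    def test_duplicated_predictor_raises(self, rng):
        k = 10
        z = rng.normal(size=k)
        pred = pd.DataFrame({"a": z, "b": z.copy()})
        mi = _mvn_input(rng, k=k, predictors=pred)
        with pytest.raises(ValueError, match="rank deficient|aliased"):
            fit_meta(mi)

    def test_non_psd_location_vcov_raises(self):
        bad = ReducedCurve.__new__(ReducedCurve)
        object.__setattr__(bad, "coef", np.array([0.1, 0.2]))
        object.__setattr__(bad, "vcov", np.array([[1.0, 0.0], [0.0, -0.5]]))
        object.__setattr__(bad, "spec", SCALAR_SPEC)
        object.__setattr__(bad, "center", None)
        good = ReducedCurve(coef=np.array([0.1, 0.2]), vcov=np.eye(2) * 0.01,
                            spec=SCALAR_SPEC)
        mi = MetaInput(location_ids=["a", "b", "c", "d"],
                       curves=[good, bad, good, good])
        with pytest.raises(ValueError, match="positive semi-definite"):
            fit_meta(mi)

    def test_reml_improves_on_zero_psi_start(self, rng):
        from tempmort.stage2 import _design, _neg2_loglik
        mi = _mvn_input(rng, k=12)
        model = fit_meta(mi)
        Z, *_ = _design(mi)
        theta, S = mi.theta(), mi.S()
        n2_zero = _neg2_loglik(np.zeros(6), theta, S, Z, "reml")
        assert -0.5 * n2_zero <= model.loglik + 1e-9


class TestWald:
    def test_zero_coefficient_gives_zero_stat(self):
        theta = np.array([0.3, 0.3, 0.3, 0.3, 0.3, 0.3])
        pred = pd.DataFrame({"z": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]})
        model = fit_meta(_scalar_input(theta, np.full(6, 0.02), predictors=pred))
        w = wald_test(model, "z")
        assert w["stat"] < 1e-12
        assert abs(w["p"] - 1.0) < 1e-10

    def test_unknown_predictor_raises(self, rng):
        model = fit_meta(_mvn_input(rng))
        with pytest.raises(KeyError):
            wald_test(model, "nope")

    def test_doubling_vcov_cannot_increase_stat(self, rng):
        k = 14
        z = np.linspace(0, 1, k)
        pred = pd.DataFrame({"z": z})
        theta = 0.2 + 0.3 * z + rng.normal(0, 0.05, k)
        var = np.full(k, 0.02)
        m1 = fit_meta(_scalar_input(theta, var, predictors=pred))
        m2 = fit_meta(_scalar_input(theta, 2 * var, predictors=pred))
        assert m2.wald["z"]["stat"] <= m1.wald["z"]["stat"] + 1e-9


class TestHeterogeneity:
    def test_scalar_q_matches_hand_formula(self):
        """Classical fixed-effect Cochran Q on five studies."""
        theta = np.array([0.30, 0.10, 0.45, 0.25, 0.05])
        var = np.array([0.04, 0.02, 0.05, 0.03, 0.02])
        w = 1.0 / var
        mu = np.sum(w * theta) / np.sum(w)
        q_hand = float(np.sum(w * (theta - mu) ** 2))
        model = fit_meta(_scalar_input(theta, var))
        het = heterogeneity(model)
        assert abs(het["Q"] - q_hand) < 1e-10
        assert het["Q_df"] == 4

    def test_i2_invariant_to_common_rescaling(self):
        theta = np.array([0.30, 0.10, 0.45, 0.25, 0.05])
        var = np.array([0.04, 0.02, 0.05, 0.03, 0.02])
        a = fit_meta(_scalar_input(theta, var))
        b = fit_meta(_scalar_input(3.0 * theta, 9.0 * var))
        assert abs(a.I2 - b.I2) < 1e-9


class TestBlup:
    def test_zero_psi_gives_fixed_effect_prediction(self):
        theta = np.array([0.4, 0.4, 0.4, 0.41, 0.39])
        mi = _scalar_input(theta, np.full(5, 0.05))
        model = fit_meta(mi)
        assert model.psi[0, 0] < 1e-7
        bl = blup(model, mi)
        np.testing.assert_allclose(bl.coefs[:, 0], model.beta[0, 0], atol=1e-3)

    def test_tiny_within_variance_gives_no_shrinkage(self, rng):
        theta = rng.normal(0.3, 0.2, 8)
        mi = _scalar_input(theta, np.full(8, 1e-8))
        model = fit_meta(mi)
        bl = blup(model, mi)
        np.testing.assert_allclose(bl.coefs[:, 0], theta, atol=1e-5)

    def test_noisier_location_shrinks_farther(self, rng):
        """A location with a large within-location variance moves a
        larger fraction of the way toward the pooled prediction."""
        k = 12
        true = rng.normal(0.3, 0.15, k)
        var = np.full(k, 0.01)
        var[0] = 0.5                      # one very noisy location
        theta = true + rng.normal(0, np.sqrt(var))
        mi = _scalar_input(theta, var)
        model = fit_meta(mi)
        bl = blup(model, mi)
        mu = model.beta[0, 0]
        frac = np.abs(theta - bl.coefs[:, 0]) / np.maximum(np.abs(theta - mu), 1e-12)
        assert frac[0] > np.median(frac[1:])

    def test_blup_between_estimate_and_pooled(self, rng):
        theta = rng.normal(0.3, 0.2, 10)
        mi = _scalar_input(theta, np.full(10, 0.03))
        model = fit_meta(mi)
        bl = blup(model, mi)
        mu = model.beta[0, 0]
        lo = np.minimum(theta, mu) - 1e-12
        hi = np.maximum(theta, mu) + 1e-12
        assert np.all((bl.coefs[:, 0] >= lo) & (bl.coefs[:, 0] <= hi))


class TestEnsemble:
    def test_ensemble_mean_approaches_blup(self, rng):
        mi = _mvn_input(rng, k=8)
        model = fit_meta(mi)
        bl = blup(model, mi)
        ens = sample_curve_ensemble(model, mi, 4000, seed=1)
        np.testing.assert_allclose(ens.mean(axis=1), bl.coefs, atol=0.02)

    def test_draws_correlated_across_locations_when_homogeneous(self):
        theta = np.array([0.4, 0.4, 0.4, 0.4, 0.4, 0.4])
        mi = _scalar_input(theta, np.full(6, 0.03))
        model = fit_meta(mi)
        ens = sample_curve_ensemble(model, mi, 500, seed=2)
        corr = np.corrcoef(ens[0, :, 0], ens[3, :, 0])[0, 1]
        assert corr > 0.95
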