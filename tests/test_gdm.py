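"""Generalized dissimilarity modelling: I-splines, deviance fit, importance."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from funclink import (
    FormatError,
    build_site_pairs,
    gdm_fit,
    ispline_basis,
    ispline_knots,
    var_importance,
)
from funclink.beta import FunctionalBetaMatrix
from funclink.gdm import SitePairTable, binomial_deviance


def _beta_from(vals, regions):
    m = np.zeros((len(regions), len(regions)))
    iu = np.triu_indices(len(regions), 1)
    m[iu] = vals
    m += m.T
    return FunctionalBetaMatrix(regions, m)


def synthetic_gdm_pairs(n_regions, coef_sets, a0, rng, noise_sd=0.0):
    """Pairs generated exactly from a known GDM over scalar predictors."""
    regions = [f"R{i}" for i in range(n_regions)]
    iu = np.triu_indices(n_regions, 1)
    eta = a0 * np.ones(len(iu[0]))
    scal = {}
    for name, coefs in coef_sets.items():
        x = rng.uniform(0, 10, n_regions)
        basis = ispline_basis(x, ispline_knots(x))
        eta = eta + np.abs(basis[iu[0]] - basis[iu[1]]) @ np.asarray(coefs)
        scal[name] = x
    mu = 1 - np.exp(-eta)
    if noise_sd:
        mu = np.clip(mu + rng.normal(0, noise_sd, len(mu)), 0.001, 0.999)
    table = build_site_pairs(
        _beta_from(mu, regions), scalar_predictors=pd.DataFrame(scal, index=regions)
    )
    return table


class TestSitePairs:
    def test_pair_count(self, rng):
        t = synthetic_gdm_pairs(4, {"x": (0.1, 0.1, 0.1)}, 0.0, rng)
        assert t.n_pairs == 6

    def test_three_region_hand_enumeration(self):
        regions = ["A", "B", "C"]
        resp = _beta_from([0.1, 0.2, 0.3], regions)
        t = build_site_pairs(
            resp, scalar_predictors=pd.DataFrame({"x": [1.0, 2.0, 4.0]}, index=regions)
        )
        # lexicographic pairs: (A,B), (A,C), (B,C)
        np.testing.assert_allclose(t.response, [0.1, 0.2, 0.3])
        np.testing.assert_allclose(t.scalar_predictors["x"], [1.0, 2.0, 4.0])
        assert list(t.pair_i) == [0, 0, 1] and list(t.pair_j) == [1, 2, 2]

    def test_region_mismatch_errors(self):
        resp = _beta_from([0.5], ["A", "B"])
        with pytest.raises(FormatError):
            build_site_pairs(resp, scalar_predictors=pd.DataFrame({"x": [1.0]}, index=["Z"]))


class TestISplines:
    def test_extremes_map_to_zero_and_one(self, rng):
        x = rng.uniform(-3, 7, 50)
        basis = ispline_basis(x, ispline_knots(x))
        np.testing.assert_allclose(basis[np.argmin(x)], 0.0, atol=1e-12)
        np.testing.assert_allclose(basis[np.argmax(x)], 1.0, atol=1e-12)

    def test_monotone_against_integrated_mspline_oracle(self):
        # the middle basis function equals the normalized integral of the
        # triangular (order-2 M-spline-like) density implied by its knots;
        # check monotonicity everywhere and the integral representation
        knots = np.array([0.0, 3.0, 10.0])
        xs = np.linspace(0, 10, 400)
        basis = ispline_basis(xs, knots)
        assert (np.diff(basis, axis=0) >= -1e-12).all()

        def density(u):  # piecewise-linear M-spline on (0, 3, 10)
            if u < 3.0:
                return 2 * u / (10 * 3)
            return 2 * (10 - u) / (10 * 7)

        for xv in (1.0, 3.0, 5.0, 9.0):
            num, _ = integrate.quad(density, 0.0, xv)
            val = ispline_basis(np.array([xv]), knots)[0, 1]
            assert val == pytest.approx(num, abs=1e-9)

    def test_degenerate_knots_rejected(self):
        with pytest.raises(FormatError, match="degenerate"):
            ispline_basis(np.array([1.0, 1.0]), np.array([1.0, 1.0, 1.0]))


class TestGDMFit:
    def test_constant_response_yields_null_model(self, rng):
        regions = [f"R{i}" for i in range(8)]
        resp = _beta_from(np.full(28, 0.4), regions)
        t = build_site_pairs(
            resp, scalar_predictors=pd.DataFrame({"x": rng.uniform(0, 1, 8)}, index=regions)
        )
        fit = gdm_fit(t)
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(fit.predictors[0].coefs, 0.0, atol=1e-8)

    def test_noise_free_recovery(self, rng):
        t = synthetic_gdm_pairs(40, {"x": (0.4, 0.3, 0.3)}, 0.05, rng)
        fit = gdm_fit(t)
        assert fit.deviance_explained >= 99.0
        assert fit.predictors[0].height == pytest.approx(1.0, rel=0.10)
        assert fit.intercept == pytest.approx(0.05, abs=0.02)

    def test_coefficients_nonnegative_fitted_in_unit_interval(self, rng):
        for _ in range(5):
            t = synthetic_gdm_pairs(
                12, {"x": (0.3, 0.2, 0.1), "y": (0.0, 0.1, 0.2)}, 0.02, rng, noise_sd=0.1
            )
            fit = gdm_fit(t)
            assert fit.intercept >= 0
            for p in fit.predictors:
                assert (p.coefs >= 0).all()
            assert (fit.fitted >= 0).all() and (fit.fitted < 1).all()

    def test_transforms_monotone(self, rng):
        t = synthetic_gdm_pairs(20, {"x": (0.4, 0.3, 0.3)}, 0.05, rng, noise_sd=0.05)
        fit = gdm_fit(t)
        p = fit.predictors[0]
        grid = np.linspace(p.knots[0], p.knots[2], 200)
        f = ispline_basis(grid, p.knots) @ p.coefs
        assert (np.diff(f) >= -1e-12).all()
        assert f[0] == pytest.approx(0.0, abs=1e-12)

    def test_adding_predictor_never_decreases_deviance_explained(self, rng):
        t2 = synthetic_gdm_pairs(15, {"x": (0.4, 0.2, 0.2), "z": (0.0, 0.0, 0.0)}, 0.05, rng, noise_sd=0.05)
        t1 = SitePairTable(
            t2.regions, t2.response, {"x": t2.scalar_predictors["x"]}, {}, t2.pair_i, t2.pair_j
        )
        assert gdm_fit(t2).deviance_explained >= gdm_fit(t1).deviance_explained - 1e-6

    def test_matrix_predictor_supported(self, small_realm):
        from funclink import (
            functional_dissimilarity,
            gower_distance,
            great_circle,
            nj_build,
            prepare_traits,
        )

        ftree = nj_build(gower_distance(prepare_traits(small_realm.flea_traits)))
        htree = nj_build(gower_distance(prepare_traits(small_realm.host_traits)))
        fbeta = functional_dissimilarity(ftree, small_realm.flea_incidence)
        hbeta = functional_dissimilarity(htree, small_realm.host_incidence)
        geo = great_circle(small_realm.coords)
        t = build_site_pairs(fbeta, matrix_predictors={"host": hbeta, "geo": geo})
        fit = gdm_fit(t)
        assert np.isfinite(fit.deviance_explained)
        assert {p.name for p in fit.predictors} <= {"host", "geo"}

    def test_constant_predictor_dropped_with_warning(self, rng, caplog):
        regions = [f"R{i}" for i in range(6)]
        resp = _beta_from(rng.uniform(0.2, 0.8, 15), regions)
        t = build_site_pairs(
            resp, scalar_predictors=pd.DataFrame({"flat": np.ones(6)}, index=regions)
        )
        with caplog.at_level("WARNING", logger="funclink"):
            fit = gdm_fit(t)
        assert fit.dropped == ["flat"]

    def test_deviance_zero_iff_perfect_fit(self):
        # exact-0/1 responses meet the clipped link, so "zero" is 1e-8-scale
        d = np.array([0.2, 0.5, 0.0, 1.0])
        assert binomial_deviance(d, d) == pytest.approx(0.0, abs=1e-8)
        assert binomial_deviance(d, np.clip(d + 0.05, 0, 1)) > 0


class TestImportance:
    def test_sole_informative_predictor_dominates(self, rng):
        t = synthetic_gdm_pairs(20, {"signal": (0.5, 0.4, 0.4)}, 0.05, rng, noise_sd=0.02)
        imp = var_importance(t, n_perm=100, seed=1)
        tab = imp.table
        assert tab.loc["signal", "importance"] >= 80.0
        assert tab.loc["signal", "p_value"] <= 0.02
        assert imp.model_p_value <= 0.02

    def test_noise_predictor_importance_near_zero(self, rng):
        t = synthetic_gdm_pairs(
            20, {"signal": (0.5, 0.4, 0.4), "noise": (0.0, 0.0, 0.0)}, 0.05, rng, noise_sd=0.02
        )
        imp = var_importance(t, n_perm=50, seed=1)
        assert abs(imp.table.loc["noise", "importance"]) <= 5.0

    def test_undefined_when_model_explains_nothing(self, rng):
        regions = [f"R{i}" for i in range(8)]
        resp = _beta_from(np.full(28, 0.4), regions)
        t = build_site_pairs(
            resp, scalar_predictors=pd.DataFrame({"x": rng.uniform(0, 1, 8)}, index=regions)
        )
        with pytest.raises(FormatError, match="importance undefined"):
            var_importance(t, n_perm=10, seed=0)

    def test_null_p_values_roughly_uniform(self, rng):
        # model-level permutation p-values under a global null
        ps = []
        for rep in range(100):
            regions = [f"R{i}" for i in range(12)]
            resp = _beta_from(rng.uniform(0.2, 0.8, 66), regions)
            t = build_site_pairs(
                resp,
                scalar_predictors=pd.DataFrame(
                    {"a": rng.uniform(0, 1, 12), "b": rng.uniform(0, 1, 12)}, index=regions
                ),
            )
            fit = gdm_fit(t)
            if fit.deviance_explained <= 0:
                continue
            imp = var_importance(t, n_perm=25, seed=rep, fit=fit)
            ps.append(imp.model_p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
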