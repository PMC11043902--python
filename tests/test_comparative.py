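"""Region pseudo-tree, PGLS, stepwise selection and Moran's I."""

import numpy as np
import pandas as pd
import pytest

from funclink import (
    FormatError,
    RegionTree,
    bm_covariance,
    morans_i,
    pgls_fit,
    phylostep_forward,
    region_pseudotree,
)
from funclink.io import IncidenceMatrix
from tests.conftest import bm_sample, make_incidence


@pytest.fixture
def three_region_tree():
    # A={s1,s2}, B={s1,s3}, C={s4}: bray(A,B)=0.5, bray(A,C)=bray(B,C)=1
    inc = make_incidence(
        ["A", "B", "C"],
        ["s1", "s2", "s3", "s4"],
        [[1, 1, 0, 0], [1, 0, 1, 0], [0, 0, 0, 1]],
    )
    host = make_incidence(["A", "B", "C"], ["s1", "s2", "s3", "s4"], inc.values)
    return region_pseudotree(inc, host)


class TestRegionPseudotree:
    def test_hand_computed_linkage_heights(self, three_region_tree):
        coph = pd.DataFrame(
            three_region_tree.coph,
            index=three_region_tree.regions,
            columns=three_region_tree.regions,
        )
        assert coph.loc["A", "B"] == pytest.approx(0.5)
        assert coph.loc["A", "C"] == pytest.approx(1.0)
        assert coph.loc["B", "C"] == pytest.approx(1.0)

    def test_identical_regions_merge_at_zero(self):
        inc = make_incidence(["A", "B"], ["s1", "s2"], [[1, 1], [1, 1]])
        rt = region_pseudotree(inc, inc)
        assert rt.coph[0, 1] == pytest.approx(0.0)

    def test_disjoint_regions_pendants_half(self):
        flea = make_incidence(["A", "B"], ["s1", "s2"], [[1, 0], [0, 1]])
        host = make_incidence(["A", "B"], ["h1", "h2"], [[1, 0], [0, 1]])
        rt = region_pseudotree(flea, host)
        assert rt.coph[0, 1] == pytest.approx(1.0)
        assert rt.depth == pytest.approx(0.5)

    def test_region_set_mismatch_errors(self):
        a = make_incidence(["A"], ["s"], [[1]])
        b = make_incidence(["B"], ["s"], [[1]])
        with pytest.raises(FormatError, match="region sets"):
            region_pseudotree(a, b)

    def test_newick_round_trip_preserves_cophenetic(self, small_realm):
        rt = region_pseudotree(small_realm.flea_incidence, small_realm.host_incidence)
        back = RegionTree.from_newick(rt.to_newick())
        idx = [back.regions.index(r) for r in rt.regions]
        np.testing.assert_allclose(
            rt.coph, back.coph[np.ix_(idx, idx)], atol=1e-10
        )

    def test_patristic_equals_merge_height(self, small_realm):
        # cophenetic/patristic equivalence under the half-height convention
        rt = region_pseudotree(small_realm.flea_incidence, small_realm.host_incidence)
        np.testing.assert_allclose(rt.patristic(), rt.coph, atol=1e-12)


class TestBMCovariance:
    def test_star_tree_is_scaled_identity(self):
        n = 5
        coph = np.full((n, n), 0.8)
        np.fill_diagonal(coph, 0.0)
        C = bm_covariance(RegionTree([f"r{i}" for i in range(n)], coph))
        np.testing.assert_allclose(C, 0.4 * np.eye(n), atol=1e-12)

    def test_two_leaf_tree(self):
        coph = np.array([[0.0, 1.0], [1.0, 0.0]])
        C = bm_covariance(RegionTree(["a", "b"], coph))
        np.testing.assert_allclose(C, [[0.5, 0.0], [0.0, 0.5]], atol=1e-12)

    def test_three_region_example(self, three_region_tree):
        C = pd.DataFrame(
            bm_covariance(three_region_tree),
            index=three_region_tree.regions,
            columns=three_region_tree.regions,
        )
        assert C.loc["A", "B"] == pytest.approx(0.25)
        assert C.loc["A", "A"] == pytest.approx(0.5)
        assert C.loc["A", "C"] == pytest.approx(0.0)


class TestPGLS:
    def test_identity_covariance_reduces_to_ols(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 25))
            X = rng.normal(size=(n, 3))
            y = rng.normal(size=n)
            fit = pgls_fit(y, pd.DataFrame(X, columns=list("abc")), np.eye(n))
            ols = np.linalg.lstsq(np.hstack([np.ones((n, 1)), X]), y, rcond=None)[0]
            np.testing.assert_allclose(fit.params["coef"].to_numpy(), ols, atol=1e-10)

    def test_exact_linear_response_zero_residuals(self, rng):
        n = 10
        X = rng.normal(size=(n, 2))
        y = 1.0 + X @ np.array([2.0, -1.0])
        fit = pgls_fit(y, X, np.eye(n))
        assert np.abs(fit.residuals).max() < 1e-10
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_matches_explicit_matrix_algebra(self, rng):
        # 5-region fixture evaluated independently via the GLS normal equations
        n = 5
        C = np.array(
            [
                [1.0, 0.4, 0.2, 0.0, 0.0],
                [0.4, 1.0, 0.2, 0.0, 0.0],
                [0.2, 0.2, 1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 1.0, 0.6],
                [0.0, 0.0, 0.0, 0.6, 1.0],
            ]
        )
        X = np.hstack([np.ones((n, 1)), rng.normal(size=(n, 1))])
        y = rng.normal(size=n)
        Ci = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        fit = pgls_fit(y, X[:, 1:], C)
        np.testing.assert_allclose(fit.params["coef"].to_numpy(), beta, atol=1e-10)
        resid = y - X @ beta
        assert fit.sigma2 == pytest.approx(float(resid @ Ci @ resid) / n, abs=1e-12)
        k = X.shape[1] + 1
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik)

    def test_loglik_maximal_at_estimate(self, rng):
        n = 12
        C = np.eye(n) + 0.3
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        fit = pgls_fit(y, X, C)

        def loglik(beta):
            Xi = np.hstack([np.ones((n, 1)), X])
            r = y - Xi @ beta
            Ci = np.linalg.inv(C)
            s2 = float(r @ Ci @ r) / n
            _, logdet = np.linalg.slogdet(C)
            return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)

        best = fit.params["coef"].to_numpy()
        for _ in range(20):
            assert loglik(best + rng.normal(scale=0.05, size=3)) <= loglik(best) + 1e-10

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame({"a": np.arange(5.0), "b": 2 * np.arange(5.0)})
        with pytest.raises(FormatError, match="collinear"):
            pgls_fit(np.zeros(5), X, np.eye(5))


class TestPGLSRecovery:
    def test_slope_recovery_and_coverage(self, small_realm, rng):
        # y = 1 + 0.8 x + BM(sigma2=0.5) on the realm pseudo-tree
        from scipy import stats

        rt = region_pseudotree(small_realm.flea_incidence, small_realm.host_incidence)
        C = bm_covariance(rt)
        C = C + 1e-8 * np.eye(len(C))
        n = len(C)
        betas, cover = [], 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(size=n)
            y = 1.0 + 0.8 * x + bm_sample(C, 0.5, rng)
            fit = pgls_fit(y, pd.DataFrame({"x": x}), C)
            b = fit.params.loc["x", "coef"]
            se = fit.params.loc["x", "se"]
            betas.append(b)
            tcrit = stats.t.ppf(0.975, n - 2)
            cover += b - tcrit * se <= 0.8 <= b + tcrit * se
        assert np.mean(betas) == pytest.approx(0.8, abs=0.05)
        assert 0.92 <= cover / reps <= 0.98


class TestPhylostep:
    def test_final_aic_never_worse_than_intercept(self, rng):
        n = 20
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = rng.normal(size=n)
        fit = phylostep_forward(y, X, np.eye(n))
        assert fit.aic <= fit.selection_path[0]["aic"] + 1e-12

    def test_strong_predictor_always_enters(self, rng):
        n = 30
        hits = 0
        for _ in range(50):
            X = pd.DataFrame(rng.normal(size=(n, 4)), columns=["true", "n1", "n2", "n3"])
            y = 0.8 * X["true"].to_numpy() + rng.normal(size=n)
            fit = phylostep_forward(y, X, np.eye(n))
            hits += "true" in fit.terms
        assert hits >= 48

    def test_null_selection_matches_aic_theory(self, rng):
        # with 4 pure-noise candidates, plain-AIC forward selection keeps
        # the intercept-only model at roughly (1 - P(chi2_1 > 2))^4 ~ 0.5
        n = 30
        none = 0
        reps = 120
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
            y = rng.normal(size=n)
            fit = phylostep_forward(y, X, np.eye(n))
            none += len(fit.terms) == 1
        assert 0.35 <= none / reps <= 0.65

    def test_empty_candidates_intercept_only(self, rng):
        fit = phylostep_forward(rng.normal(size=8), pd.DataFrame(index=range(8)), np.eye(8))
        assert fit.terms == ["intercept"]


class TestMoransI:
    def _line_coords(self, n):
        return pd.DataFrame(
            {"lat": np.linspace(5, 25, n), "lon": np.linspace(2, 38, n)},
            index=[f"r{i}" for i in range(n)],
        )

    def test_expectation_value(self, rng):
        res = morans_i(rng.normal(size=11), self._line_coords(11))
        assert res.expectation == pytest.approx(-0.1)

    def test_spatial_gradient_detected(self):
        coords = self._line_coords(15)
        res = morans_i(coords["lon"].to_numpy(), coords)
        assert res.I > 0
        assert res.p_value < 0.05

    def test_permutation_mean_matches_analytic_expectation(self, rng):
        n = 12
        coords = self._line_coords(n)
        z = rng.normal(size=n)
        vals = np.array(
            [morans_i(z[rng.permutation(n)], coords).I for _ in range(2000)]
        )
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - (-1 / (n - 1))) < 3 * se

    def test_coincident_regions_error(self):
        coords = pd.DataFrame({"lat": [0.0, 0.0, 1.0, 2.0], "lon": [0.0, 0.0, 1.0, 2.0]}, index=list("abcd"))
        with pytest.raises(FormatError, match="jitter"):
            morans_i(np.arange(4.0), coords)

    def test_small_sample_rejected(self):
        with pytest.raises(FormatError):
            morans_i(np.arange(3.0), self._line_coords(3))
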