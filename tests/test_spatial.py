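"""Binary weights, Moran's I, collinearity screen, spatial GLS."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import skerrydiv as sd
from skerrydiv.errors import ConvergenceError, ValidationError, ZeroVarianceError
from skerrydiv.spatial import SpatialExponentialGLS, default_interactions

from conftest import make_square


def grid_squares(n_side, spacing=1000.0):
    return [
        make_square(f"g{i:02d}{j:02d}", x=spacing * j, y=spacing * i)
        for i in range(n_side) for j in range(n_side)
    ]


class TestBinaryWeights:
    def test_lag_boundary_inclusive(self):
        sqs = [make_square("a", 0, 0), make_square("b", 1000, 0)]
        W = sd.binary_weights(sqs, lag=1000.0)
        assert W.values[0, 1] == 1

    def test_diagonal_neighbours_excluded(self):
        sqs = [make_square("a", 0, 0), make_square("b", 1000, 1000),
               make_square("c", 1000, 0)]
        W = sd.binary_weights(sqs, lag=1000.0)
        assert W.values[0, 1] == 0  # 1414 m apart

    def test_rook_neighbourhood_on_grid(self):
        W = sd.binary_weights(grid_squares(3), lag=1000.0)
        row_sums = W.values.sum(axis=1)
        # centre square has 4 neighbours; corners 2; edges 3
        assert sorted(row_sums.tolist()) == [2, 2, 2, 2, 3, 3, 3, 3, 4]

    def test_all_zero_weights_rejected(self):
        sqs = [make_square("a", 0, 0), make_square("b", 9000, 0)]
        with pytest.raises(ValidationError):
            sd.binary_weights(sqs, lag=1000.0)


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        sqs = grid_squares(2)
        W = sd.binary_weights(sqs)
        x = np.array([1.0, -1.0, -1.0, 1.0])  # every rook pair differs
        res = sd.morans_i(x, W)
        assert res.I == pytest.approx(-1.0, abs=1e-12)
        assert res.expected == pytest.approx(-1 / 3)

    def test_affine_invariance(self, rng):
        sqs = grid_squares(5)
        W = sd.binary_weights(sqs)
        x = rng.normal(size=25)
        a = sd.morans_i(x, W)
        b = sd.morans_i(5.0 - 2.0 * x, W)
        assert a.I == pytest.approx(b.I)
        assert a.variance == pytest.approx(b.variance)

    def test_permutation_mean_matches_expectation(self, rng):
        sqs = grid_squares(5)
        W = sd.binary_weights(sqs)
        x = rng.normal(size=25)
        n_perm = 2000
        vals = np.array([
            sd.morans_i(rng.permutation(x), W).I for _ in range(n_perm)
        ])
        se = vals.std(ddof=1) / np.sqrt(n_perm)
        assert abs(vals.mean() - (-1 / 24)) < 3 * se

    def test_constant_values_rejected(self):
        W = sd.binary_weights(grid_squares(2))
        with pytest.raises(ZeroVarianceError):
            sd.morans_i(np.ones(4), W)


class TestCollinearityScreen:
    def test_duplicated_covariate_flagged(self):
        sqs = [make_square(f"s{i}", 1000.0 * i, 0, dist=1000.0 * i, width=1000.0 * i,
                           shore=100.0 * i * i, land=1000.0 * i)
               for i in range(1, 6)]
        tab = sd.collinearity_screen(sqs)
        row = tab[(tab.var1 == "dist_sea") & (tab.var2 == "width")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.flagged

    def test_symmetric_in_argument_order(self, rng):
        sqs = grid_squares(4)
        sqs = [
            sd.SquareRecord(s.square_id, s.x, s.y,
                            land_area=float(rng.uniform(0, 1e6)),
                            shoreline=float(rng.uniform(0, 4000)),
                            dist_sea=float(rng.uniform(0, 9000)),
                            width=float(rng.uniform(9000, 20000)))
            for s in sqs
        ]
        tab = sd.collinearity_screen(sqs)
        lookup = {(r.var1, r.var2): r.r for r in tab.itertuples()}
        for (a, b), r in lookup.items():
            assert r == pytest.approx(
                float(np.corrcoef(
                    [getattr(s, a) for s in sqs], [getattr(s, b) for s in sqs]
                )[0, 1])
            )

    def test_independent_covariates_unflagged(self, rng):
        n = 500
        sqs = [
            sd.SquareRecord(f"s{i:03d}", 0.0, 1000.0 * i,
                            land_area=float(rng.uniform(0, 1e6)),
                            shoreline=float(rng.uniform(0, 4000)),
                            dist_sea=float(rng.uniform(0, 9000)),
                            width=float(rng.uniform(9000, 30000)))
            for i in range(n)
        ]
        assert not sd.collinearity_screen(sqs)["flagged"].any()


def simulate_gls(rng, n_side, beta, sigma, rho, nugget):
    sqs = grid_squares(n_side)
    coords = np.array([[s.x, s.y] for s in sqs])
    n = len(sqs)
    X = pd.DataFrame(
        rng.standard_normal((n, 4)),
        columns=["dist_sea", "width", "shoreline", "land_area"],
        index=[s.square_id for s in sqs],
    )
    X = (X - X.mean()) / X.std(ddof=1)
    D = squareform(pdist(coords))
    R = (1 - nugget) * np.exp(-D / rho) + nugget * np.eye(n)
    L = np.linalg.cholesky(R)
    eps = sigma * (L @ rng.standard_normal(n))
    y = beta[0] + X.to_numpy() @ np.asarray(beta[1:]) + eps
    return sqs, X, y, coords


class TestSpatialGLS:
    def test_fixed_nugget_one_equals_ols(self, rng):
        sqs, X, y, coords = simulate_gls(rng, 7, [0.5, 0.3, -0.3, 0.2, -0.2],
                                         sigma=0.3, rho=3000.0, nugget=1.0)
        est = SpatialExponentialGLS(nugget=1.0, rho=1000.0).fit(X, y, coords)
        Xd = np.column_stack([np.ones(len(y)), X.to_numpy()])
        beta_ols, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        np.testing.assert_allclose(est.coef_.to_numpy(), beta_ols, atol=1e-6)
        assert est.nugget_ == 1.0

    def test_two_point_gls_mean_closed_form(self):
        # intercept-only fit with known correlation: weighted mean 1'R^-1 y / 1'R^-1 1
        coords = np.array([[0.0, 0.0], [1000.0, 0.0]])
        y = np.array([1.0, 3.0])
        rho, nu = 2000.0, 0.2
        est = SpatialExponentialGLS(rho=rho, nugget=nu)
        X = pd.DataFrame(index=["a", "b"])  # no covariates -> intercept only
        # need n > p: add a third point
        coords = np.vstack([coords, [500.0, 800.0]])
        y = np.append(y, 2.0)
        X = pd.DataFrame(index=["a", "b", "c"])
        est.fit(X, y, coords)
        D = squareform(pdist(coords))
        R = (1 - nu) * np.exp(-D / rho) + nu * np.eye(3)
        Ri = np.linalg.inv(R)
        one = np.ones(3)
        expected = (one @ Ri @ y) / (one @ Ri @ one)
        assert est.coef_["intercept"] == pytest.approx(expected, rel=1e-8)

    def test_loglik_at_optimum_at_least_ols(self, rng):
        sqs, X, y, coords = simulate_gls(rng, 7, [0.0, 0.3, -0.3, 0.2, -0.2],
                                         sigma=0.3, rho=3000.0, nugget=0.2)
        free = SpatialExponentialGLS(n_rho=10, n_nugget=5).fit(X, y, coords)
        ols = SpatialExponentialGLS(nugget=1.0, rho=1000.0).fit(X, y, coords)
        assert free.loglik_ >= ols.loglik_ - 1e-8

    def test_sign_recovery_with_spatial_error(self, rng):
        beta = [0.0, 0.3, -0.3, 0.3, -0.3]
        sqs, X, y, coords = simulate_gls(rng, 20, beta, sigma=0.3,
                                         rho=3000.0, nugget=0.2)
        est = SpatialExponentialGLS(n_rho=10, n_nugget=5).fit(X, y, coords)
        for name, b in zip(["dist_sea", "width", "shoreline", "land_area"], beta[1:]):
            assert np.sign(est.coef_[name]) == np.sign(b)
        assert est.rho_ > 0
        assert 0.0 <= est.nugget_ <= 1.0
        # Wald intervals are symmetric +-1.96 SE
        half = (est.conf_int_["hi95"] - est.conf_int_["lo95"]) / 2
        np.testing.assert_allclose(half, 1.96 * est.se_, rtol=1e-10)

    def test_singular_design_rejected(self, rng):
        sqs, X, y, coords = simulate_gls(rng, 4, [0.0, 0.1, 0.1, 0.1, 0.1],
                                         sigma=0.3, rho=2000.0, nugget=0.5)
        X["dup"] = X["dist_sea"]
        with pytest.raises(ValidationError):
            SpatialExponentialGLS().fit(X, y, coords)

    def test_interactions_built_from_products(self, rng):
        sqs, X, y, coords = simulate_gls(rng, 5, [0.0, 0.2, -0.2, 0.1, -0.1],
                                         sigma=0.4, rho=2000.0, nugget=1.0)
        est = SpatialExponentialGLS(
            interactions=(("shoreline", "land_area"),), nugget=1.0, rho=1000.0
        ).fit(X, y, coords)
        assert "shoreline:land_area" in est.coef_.index
        pred = est.predict(X)
        assert pred.shape == y.shape

    def test_default_interactions_drop_for_generalists(self):
        inter = default_interactions("generalist")
        assert len(inter) == 5
        assert frozenset(("land_area", "width")) not in {frozenset(p) for p in inter}
        assert len(default_interactions("specialist")) == 6


class TestFitSpatialGls:
    def test_response_column_checked(self, desk_ds):
        rt = sd.richness(desk_ds)
        with pytest.raises(ValidationError):
            sd.fit_spatial_gls(rt.drop(columns=["total"]), desk_ds.grid,
                               sd.ModelSpec("total"))

    def test_fit_on_synthetic_survey(self, desk_ds):
        filtered, excl = sd.filter_squares(desk_ds)
        occ = sd.reassign_records(desk_ds, excl)
        ds = sd.SurveyDataset(filtered.grid, occ)
        rt = sd.richness(ds)
        fit = sd.fit_spatial_gls(rt, ds.grid, sd.ModelSpec("specialist"))
        assert fit.sigma > 0
        assert len(fit.params) == 1 + 4 + 6
        assert fit.residuals.shape == (len(ds.grid),)
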