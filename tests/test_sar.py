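"""Spatial-lag model: likelihood machinery, fitting, screening, stepwise."""

import numpy as np
import pandas as pd
import pytest

from invascape.errors import InfeasibleRhoError, SingularDesignError
from invascape.sar import (
    concentrated_loglik,
    feasible_rho_interval,
    fit_sar_ml,
    full_loglik,
    log_det_factor,
    neighbor_average,
    residual_autocorrelation,
    screen_collinear,
    stepwise_aic,
)
from invascape.synthetic import GroundTruth, simulate_severity
from invascape.weights import SpatialWeights


def _simulate(w, rho, beta, sigma, seed, x_seed=0):
    rng = np.random.default_rng(x_seed)
    x1 = rng.uniform(0, 100, w.n)
    x = pd.DataFrame({"x1": x1}, index=w.ids)
    design = pd.DataFrame({"intercept": 1.0, "x1": x1}, index=w.ids)
    truth = GroundTruth(rho=rho, beta=np.asarray(beta, float), sigma=sigma, seed=seed)
    y = simulate_severity(w, design, truth)
    return y, x


class TestNeighborAverage:
    def test_chain_average(self, chain3):
        v = pd.Series([1.0, 2.0, 3.0], index=chain3.ids)
        out = neighbor_average(v, chain3)
        assert list(out) == [2.0, 2.0, 2.0]

    def test_explicit_neighbor_values(self):
        w = SpatialWeights(
            ids=["a", "b"],
            neighbors=[np.array([1]), np.array([0])],
            style="row",
        )
        v = pd.Series([10.0, 20.0], index=["a", "b"])
        out = neighbor_average(v, w)
        assert out["a"] == 20.0 and out["b"] == 10.0

    def test_constant_field_is_invariant(self, queen5):
        v = pd.Series(7.3, index=queen5.ids)
        assert np.allclose(neighbor_average(v, queen5), 7.3)

    def test_island_gets_nan(self):
        w = SpatialWeights(
            ids=["a", "b", "c"],
            neighbors=[np.array([1]), np.array([0]), np.array([], dtype=int)],
            style="row",
        )
        out = neighbor_average(pd.Series([1.0, 2.0, 3.0], index=w.ids), w)
        assert np.isnan(out["c"])


class TestScreenCollinear:
    def test_exact_duplicate_drops_weaker_response_correlate(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=50)
        y = x1 + 0.1 * rng.normal(size=50)
        x = pd.DataFrame({"x1": x1, "x2": 2 * x1})
        kept, log = screen_collinear(x, y)
        assert list(kept.columns) == ["x1"]
        assert log[0]["removed"] == "x2"

    def test_uncorrelated_set_unchanged(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        y = rng.normal(size=200)
        kept, log = screen_collinear(x, y)
        assert list(kept.columns) == list("abcd") and log == []

    def test_zero_variance_dropped_first(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame({"flat": 1.0, "v": rng.normal(size=30)})
        kept, log = screen_collinear(x, rng.normal(size=30))
        assert "flat" not in kept.columns
        assert log[0]["reason"] == "zero variance"

    def test_matches_exhaustive_rule_application(self):
        """Brute-force oracle: independently re-apply the worst-pair rule
        on a five-covariate set with a planted correlation structure."""
        rng = np.random.default_rng(3)
        n = 300
        base = rng.normal(size=n)
        x = pd.DataFrame(
            {
                "a": base + 0.2 * rng.normal(size=n),
                "b": base + 0.25 * rng.normal(size=n),
                "c": rng.normal(size=n),
                "d": rng.normal(size=n),
                "e": -base + 0.3 * rng.normal(size=n),
            }
        )
        y = base + 0.5 * rng.normal(size=n)
        kept, _ = screen_collinear(x, y, threshold=0.6)

        cols = list(x.columns)
        ys = pd.Series(y)
        while True:
            sub = x[cols]
            corr = sub.corr().abs()
            np.fill_diagonal(corr.values, 0)
            if corr.values.max() <= 0.6:
                break
            i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
            pair = [corr.index[i], corr.columns[j]]
            drop = min(pair, key=lambda cname: abs(x[cname].corr(ys)))
            cols.remove(drop)
        assert list(kept.columns) == cols


class TestLogDeterminant:
    def test_zero_rho_gives_zero(self, queen10):
        assert log_det_factor(0.0, queen10) == 0.0

    def test_two_unit_symmetric_closed_form(self):
        w = SpatialWeights(
            ids=["a", "b"],
            neighbors=[np.array([1]), np.array([0])],
            style="binary",
        )
        # eigenvalues ±1: ln|I − 0.5W| = ln(0.5 · 1.5)
        assert log_det_factor(0.5, w) == pytest.approx(np.log(0.75))

    def test_matches_dense_determinant(self):
        rng = np.random.default_rng(4)
        nbrs = []
        n = 20
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n - 1):  # ring plus random chords, symmetric
            adj[i, i + 1] = adj[i + 1, i] = True
        adj[0, n - 1] = adj[n - 1, 0] = True
        for _ in range(15):
            i, j = rng.integers(0, n, 2)
            if i != j:
                adj[i, j] = adj[j, i] = True
        nbrs = [np.nonzero(adj[i])[0] for i in range(n)]
        w = SpatialWeights(
            ids=[f"u{i}" for i in range(n)], neighbors=nbrs, style="row"
        )
        for rho in (-0.6, -0.2, 0.3, 0.8):
            direct = np.linalg.slogdet(np.eye(n) - rho * w.dense())[1]
            assert log_det_factor(rho, w) == pytest.approx(direct, abs=1e-8)

    def test_boundary_rho_rejected(self, queen10):
        lo, hi = feasible_rho_interval(queen10)
        with pytest.raises(InfeasibleRhoError):
            log_det_factor(hi, queen10)
        with pytest.raises(InfeasibleRhoError):
            log_det_factor(lo - 0.01, queen10)


class TestConcentratedLikelihood:
    def test_rho_zero_equals_ols_loglik(self, queen10):
        y, x = _simulate(queen10, 0.0, [4.0, 0.03], 1.0, seed=11)
        design = pd.DataFrame(
            {"intercept": 1.0, "x1": x["x1"]}, index=queen10.ids
        )
        import statsmodels.api as sm

        ols = sm.OLS(y.to_numpy(), design.to_numpy()).fit()
        assert concentrated_loglik(0.0, y.to_numpy(), design, queen10) == (
            pytest.approx(ols.llf)
        )

    def test_invariant_to_consistent_permutation(self, queen10):
        y, x = _simulate(queen10, 0.4, [4.0, 0.03], 1.0, seed=12)
        design = pd.DataFrame(
            {"intercept": 1.0, "x1": x["x1"]}, index=queen10.ids
        )
        base = concentrated_loglik(0.3, y.to_numpy(), design, queen10)
        rng = np.random.default_rng(13)
        perm = rng.permutation(queen10.n)
        ids_p = [queen10.ids[i] for i in perm]
        w_p = SpatialWeights(
            ids=ids_p,
            neighbors=[
                np.array(
                    [int(np.where(perm == j)[0][0]) for j in queen10.neighbors[i]]
                )
                for i in perm
            ],
            style="row",
        )
        val = concentrated_loglik(
            0.3, y.to_numpy()[perm], design.iloc[perm], w_p
        )
        assert val == pytest.approx(base, abs=1e-8)

    def test_matches_full_likelihood_at_profiled_parameters(self, queen10):
        y, x = _simulate(queen10, 0.5, [4.0, 0.03], 1.0, seed=14)
        design = pd.DataFrame(
            {"intercept": 1.0, "x1": x["x1"]}, index=queen10.ids
        )
        from invascape.sar import _beta_sigma, _design

        xm, _ = _design(design, queen10.n)
        wy = queen10.sparse().dot(y.to_numpy())
        for rho in (-0.3, 0.0, 0.45):
            beta, _, s2 = _beta_sigma(rho, y.to_numpy(), xm, wy)
            assert concentrated_loglik(rho, y.to_numpy(), design, queen10) == (
                pytest.approx(full_loglik(rho, beta, s2, y.to_numpy(), design, queen10))
            )


class TestFitSar:
    def test_null_lag_data_recovers_rho_near_zero(self, queen10):
        y, x = _simulate(queen10, 0.0, [4.0, 0.03], 0.1, seed=15)
        fit = fit_sar_ml(y, x, queen10)
        assert abs(fit.rho) <= 3 * fit.se_rho

    def test_fixed_rho_zero_reproduces_ols_exactly(self, queen10):
        y, x = _simulate(queen10, 0.0, [4.0, 0.03], 1.0, seed=16)
        fit = fit_sar_ml(y, x, queen10, fix_rho=0.0)
        import statsmodels.api as sm

        design = sm.add_constant(x["x1"].to_numpy())
        ols = sm.OLS(y.to_numpy(), design).fit()
        assert np.allclose(fit.beta.to_numpy(), ols.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-6)
        # ML standard errors: OLS bse rescaled from s² to σ̂²_ML
        se_ml = ols.bse * np.sqrt(ols.df_resid / queen10.n)
        assert np.allclose(fit.se_beta.to_numpy(), se_ml, atol=1e-6)

    def test_lag_fit_never_below_ols_likelihood(self, queen10):
        for seed in range(5):
            y, x = _simulate(queen10, 0.3, [4.0, 0.03], 1.0, seed=30 + seed)
            fit = fit_sar_ml(y, x, queen10)
            fit0 = fit_sar_ml(y, x, queen10, fix_rho=0.0)
            assert fit.loglik >= fit0.loglik - 1e-9

    def test_aic_counts_rho_and_sigma2(self, queen10):
        y, x = _simulate(queen10, 0.4, [4.0, 0.03], 1.0, seed=17)
        fit = fit_sar_ml(y, x, queen10)
        assert fit.k == 2 + 2
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)

    def test_scale_equivariance(self, queen10):
        y, x = _simulate(queen10, 0.4, [4.0, 0.03], 1.0, seed=18)
        fit1 = fit_sar_ml(y, x, queen10)
        fit2 = fit_sar_ml(y, x * 100.0, queen10)
        assert fit2.rho == pytest.approx(fit1.rho, abs=1e-8)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-8)
        assert fit2.beta["x1"] == pytest.approx(fit1.beta["x1"] / 100.0)

    def test_residual_identity(self, queen10):
        y, x = _simulate(queen10, 0.4, [4.0, 0.03], 1.0, seed=19)
        fit = fit_sar_ml(y, x, queen10)
        manual = (
            y.to_numpy()
            - fit.rho * queen10.sparse().dot(y.to_numpy())
            - np.column_stack([np.ones(queen10.n), x["x1"]]) @ fit.beta.to_numpy()
        )
        assert np.allclose(fit.residuals.to_numpy(), manual)

    def test_parameter_recovery_over_replicates(self, queen10):
        """ρ* = 0.5, β* = (4, 0.03): estimates land within 3 SEs in at
        least 90% of 20 seeded replicates."""
        hits = 0
        reps = 20
        for rep in range(reps):
            y, x = _simulate(queen10, 0.5, [4.0, 0.03], 1.0, seed=100 + rep,
                             x_seed=rep)
            fit = fit_sar_ml(y, x, queen10)
            ok = abs(fit.rho - 0.5) <= 3 * fit.se_rho
            ok &= abs(fit.beta["intercept"] - 4.0) <= 3 * fit.se_beta["intercept"]
            ok &= abs(fit.beta["x1"] - 0.03) <= 3 * fit.se_beta["x1"]
            hits += bool(ok)
        assert hits >= 0.9 * reps

    def test_rank_deficient_design_rejected(self, queen10):
        y, x = _simulate(queen10, 0.3, [4.0, 0.03], 1.0, seed=20)
        x = x.assign(dup=2.0 * x["x1"])
        with pytest.raises(SingularDesignError):
            fit_sar_ml(y, x, queen10)


class TestStepwise:
    def test_strong_covariate_retained_noise_mostly_dropped(self, queen10):
        y, x = _simulate(queen10, 0.4, [4.0, 0.08], 0.5, seed=21)
        rng = np.random.default_rng(22)
        candidates = x.assign(noise1=rng.normal(size=queen10.n))
        best, path = stepwise_aic(y, candidates, queen10)
        assert "x1" in best.beta.index
        assert path["action"].iloc[0] == "start"

    def test_pure_noise_candidates_usually_give_intercept_only(self, queen10):
        intercept_only = 0
        reps = 15
        for rep in range(reps):
            rng = np.random.default_rng(200 + rep)
            y = pd.Series(rng.normal(size=queen10.n), index=queen10.ids)
            candidates = pd.DataFrame(
                rng.normal(size=(queen10.n, 3)),
                columns=["n1", "n2", "n3"],
                index=queen10.ids,
            )
            best, _ = stepwise_aic(y, candidates, queen10)
            if list(best.beta.index) == ["intercept"]:
                intercept_only += 1
        assert intercept_only > reps / 2

    def test_true_model_beats_junk_augmented_model_by_aic(self, queen10):
        wins = 0
        reps = 20
        for rep in range(reps):
            y, x = _simulate(
                queen10, 0.5, [4.0, 0.05], 1.0, seed=300 + rep, x_seed=rep
            )
            rng = np.random.default_rng(400 + rep)
            junk = x.assign(junk=rng.normal(size=queen10.n))
            fit_true = fit_sar_ml(y, x, queen10)
            fit_junk = fit_sar_ml(y, junk, queen10)
            wins += fit_true.aic <= fit_junk.aic
        assert wins >= 0.7 * reps

    def test_path_is_deterministic(self, queen10):
        y, x = _simulate(queen10, 0.4, [4.0, 0.05], 1.0, seed=23)
        rng = np.random.default_rng(24)
        candidates = x.assign(n1=rng.normal(size=queen10.n))
        _, path1 = stepwise_aic(y, candidates, queen10)
        _, path2 = stepwise_aic(y, candidates, queen10)
        pd.testing.assert_frame_equal(path1, path2)


class TestResidualMoran:
    def test_permuted_residuals_sit_at_null_expectation(self, queen10):
        y, x = _simulate(queen10, 0.5, [4.0, 0.03], 1.0, seed=25)
        fit = fit_sar_ml(y, x, queen10)
        rng = np.random.default_rng(26)
        from invascape.moran import morans_i_permutation

        _, _, perms = morans_i_permutation(
            pd.Series(rng.permutation(fit.residuals.to_numpy()), index=fit.ids),
            queen10,
            999,
            seed=27,
        )
        assert abs(perms.mean() - (-1 / 99)) < 3 * perms.std() / np.sqrt(999)

    def test_well_specified_fit_has_unstructured_residuals(self, queen10):
        y, x = _simulate(queen10, 0.5, [4.0, 0.03], 1.0, seed=28)
        fit = fit_sar_ml(y, x, queen10)
        res = residual_autocorrelation(fit, queen10)
        assert fit.residual_moran is res

    def test_spatial_gradient_in_residuals_is_detected(self, queen10):
        y, x = _simulate(queen10, 0.4, [4.0, 0.03], 1.0, seed=29)
        fit = fit_sar_ml(y, x, queen10)
        grad = np.add.outer(np.arange(10), np.arange(10)).ravel().astype(float)
        fit.residuals = pd.Series(
            grad + 0.5 * np.random.default_rng(30).normal(size=100),
            index=fit.ids,
        )
        res = residual_autocorrelation(fit, queen10)
        assert res.p < 0.05
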