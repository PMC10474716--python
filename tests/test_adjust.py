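"""Line-model REML, generalized heritability, de-regression."""

import numpy as np
import pandas as pd
import pytest

from gspred import adjust
from gspred.data import PlotTable
from gspred import simulate as sim


def _plots_from_arrays(line_ids, yields):
    n = len(line_ids)
    return PlotTable(pd.DataFrame({
        "plot_id": [f"P{i}" for i in range(n)],
        "line_id": line_ids,
        "row": np.arange(n),
        "range": np.zeros(n, dtype=int),
        "yield": yields,
    }))


def _dense_mme(plots, lam):
    """Independently coded dense mixed-model-equation solve."""
    df = plots.df
    lines = sorted(df["line_id"].unique())
    Z = (df["line_id"].to_numpy()[:, None] == np.array(lines)[None, :]).astype(float)
    y = df["yield"].to_numpy(float)
    n, r = Z.shape
    X = np.ones((n, 1))
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(r)]])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(C, rhs)
    Cinv = np.linalg.inv(C)
    return sol[0], sol[1:], Cinv[1:, 1:]


class TestFitLineBlup:
    def test_matches_dense_mme_oracle(self):
        # 5 lines x 2 reps, fixed numbers
        line_ids = [f"L{i}" for i in range(5)] * 2
        y = np.array([4.1, 3.8, 5.0, 4.4, 3.5, 4.3, 3.6, 5.2, 4.6, 3.4])
        plots = _plots_from_arrays(line_ids, y)
        fit = adjust.fit_line_blup(plots)
        mu_o, g_o, C22 = _dense_mme(plots, fit.lambda_hat)
        assert abs(fit.mu_hat - mu_o) < 1e-8
        np.testing.assert_allclose(fit.g_tilde, g_o, atol=1e-8)
        np.testing.assert_allclose(fit.pev, fit.sigma2_e_hat * np.diag(C22),
                                   atol=1e-8)
        np.testing.assert_allclose(fit.g_error_cov, fit.sigma2_e_hat * C22,
                                   atol=1e-8)

    def test_profile_loglik_matches_dense_oracle_on_grid(self):
        rng = np.random.default_rng(3)
        line_ids = [f"L{i}" for i in range(8) for _ in range(2)]
        y = 4 + rng.standard_normal(16)
        plots = _plots_from_arrays(line_ids, y)

        def dense_profile(ll):
            lam = np.exp(ll)
            df = plots.df
            lines = sorted(df["line_id"].unique())
            Z = (df["line_id"].to_numpy()[:, None] == np.array(lines)[None, :]
                 ).astype(float)
            yv = df["yield"].to_numpy(float)
            n = len(yv)
            V0 = Z @ Z.T + lam * np.eye(n)
            Vi = np.linalg.inv(V0)
            one = np.ones(n)
            xvx = one @ Vi @ one
            P = Vi - np.outer(Vi @ one, one @ Vi) / xvx
            ypy = yv @ P @ yv
            sign, logdet = np.linalg.slogdet(V0)
            return -0.5 * (logdet + np.log(xvx) + (n - 1) * np.log(ypy))

        for ll in np.linspace(-3, 3, 10):
            assert abs(adjust.reml_profile_loglik(plots, ll)
                       - dense_profile(ll)) < 1e-6

    def test_complete_shrinkage_limit(self):
        rng = np.random.default_rng(4)
        line_ids = [f"L{i}" for i in range(6) for _ in range(2)]
        y = 4 + rng.standard_normal(12)
        plots = _plots_from_arrays(line_ids, y)
        fit = adjust.fit_line_blup(plots, log_lambda_bounds=(14.0, 16.0))
        assert np.max(np.abs(fit.g_tilde)) < 1e-4
        np.testing.assert_allclose(fit.pev, fit.sigma2_g_hat,
                                   rtol=1e-3)
        assert fit.boundary_flag

    def test_fewer_than_two_lines_rejected(self):
        plots = _plots_from_arrays(["A", "A", "A"], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="2 lines"):
            adjust.fit_line_blup(plots)

    def test_variance_recovery_and_pev_ordering(self):
        # sigma2_g = sigma2_e = 1, 1.25x replication, 1000 lines
        sg_hats, ordering_ok = [], []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            g = rng.standard_normal(1000)
            cfg = sim.FieldTrialConfig(n_rows=36, n_ranges=36,
                                       replication_factor=1.25,
                                       sigma2_spatial=0.0, sigma2_nugget=1.0)
            plots = sim.simulate_field_trial(
                [f"L{i:04d}" for i in range(1000)], g, cfg, seed=300 + rep)
            fit = adjust.fit_line_blup(plots)
            sg_hats.append(fit.sigma2_g_hat)
            counts = fit.counts
            ordering_ok.append(fit.pev[counts > 1].max()
                               < fit.pev[counts == 1].min())
        assert abs(np.median(sg_hats) - 1.0) < 0.1
        assert all(ordering_ok)


class TestGeneralizedH2:
    def _fit_with_cov(self, cov, sg2):
        r = cov.shape[0]
        return adjust.BlupFit(
            line_ids=[f"L{i}" for i in range(r)], mu_hat=0.0,
            g_tilde=np.zeros(r), pev=np.diag(cov).copy(),
            sigma2_g_hat=sg2, sigma2_e_hat=1.0, loglik=0.0,
            g_error_cov=cov,
        )

    def test_perfect_information_gives_one(self):
        fit = self._fit_with_cov(np.zeros((4, 4)), 0.8)
        assert adjust.generalized_h2(fit) == 1.0
        assert adjust.generalized_h2(fit, "mean_pev") == 1.0

    def test_no_information_gives_zero(self):
        sg2 = 0.8
        fit = self._fit_with_cov(sg2 * np.eye(5), sg2)
        assert adjust.generalized_h2(fit) == 0.0
        assert adjust.generalized_h2(fit, "mean_pev") == 0.0

    def test_zero_genetic_variance_rejected(self):
        fit = self._fit_with_cov(np.eye(3) * 0.1, 0.0)
        with pytest.raises(ValueError):
            adjust.generalized_h2(fit)

    def test_invariant_to_line_relabelling(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((6, 6))
        cov = 0.05 * (A @ A.T)
        fit = self._fit_with_cov(cov, 1.0)
        perm = rng.permutation(6)
        fit_p = self._fit_with_cov(cov[np.ix_(perm, perm)], 1.0)
        assert abs(adjust.generalized_h2(fit)
                   - adjust.generalized_h2(fit_p)) < 1e-12

    def test_increases_with_replication(self):
        # an entirely unreplicated design (1.0x) cannot separate the two
        # variances in the iid line model, so the lowest level carries a
        # small replicated fraction
        h2s = []
        for k, rep_factor in enumerate((1.1, 1.25, 2.0)):
            rng = np.random.default_rng(40)
            g = rng.standard_normal(300) * np.sqrt(0.7 / 0.3)
            cfg = sim.FieldTrialConfig(n_rows=25, n_ranges=25,
                                       replication_factor=rep_factor,
                                       sigma2_spatial=0.0, sigma2_nugget=1.0)
            plots = sim.simulate_field_trial(
                [f"L{i}" for i in range(300)], g, cfg, seed=41)
            h2s.append(adjust.generalized_h2(adjust.fit_line_blup(plots)))
        assert h2s[0] < h2s[1] < h2s[2]
        assert 0.7 < h2s[1] < 1.0


class TestDeregress:
    def test_direct_arithmetic(self):
        fit = adjust.BlupFit(
            line_ids=["L1"], mu_hat=4.0, g_tilde=np.array([0.5]),
            pev=np.array([0.2]), sigma2_g_hat=0.8, sigma2_e_hat=1.0,
            loglik=0.0, g_error_cov=np.array([[0.2]]),
        )
        out = adjust.deregress(fit)
        assert abs(out.adjusted_yield[0] - (4.0 + 0.5 / 0.75)) < 1e-12
        assert abs(out.adjusted_yield[0] - 4.66667) < 1e-4

    def test_zero_pev_means_no_shrinkage_correction(self):
        fit = adjust.BlupFit(
            line_ids=["a", "b"], mu_hat=2.0, g_tilde=np.array([0.3, -0.4]),
            pev=np.array([0.0, 0.0]), sigma2_g_hat=1.0, sigma2_e_hat=1.0,
            loglik=0.0, g_error_cov=np.zeros((2, 2)),
        )
        out = adjust.deregress(fit)
        np.testing.assert_allclose(out.adjusted_yield, [2.3, 1.6], atol=1e-12)

    def test_unreliable_lines_excluded_not_clamped(self, caplog):
        fit = adjust.BlupFit(
            line_ids=["ok", "bad"], mu_hat=1.0, g_tilde=np.array([0.1, 0.2]),
            pev=np.array([0.3, 1.2]), sigma2_g_hat=1.0, sigma2_e_hat=1.0,
            loglik=0.0, g_error_cov=np.diag([0.3, 1.2]),
        )
        out = adjust.deregress(fit)
        assert list(out.line_id) == ["ok"]
        fit_all_bad = adjust.BlupFit(
            line_ids=["x"], mu_hat=1.0, g_tilde=np.array([0.1]),
            pev=np.array([2.0]), sigma2_g_hat=1.0, sigma2_e_hat=1.0,
            loglik=0.0, g_error_cov=np.array([[2.0]]),
        )
        with pytest.raises(ValueError, match="de-regress"):
            adjust.deregress(fit_all_bad)

    def test_order_preserving_in_g_tilde(self):
        g = np.array([-1.0, -0.2, 0.1, 0.9])
        fit = adjust.BlupFit(
            line_ids=list("abcd"), mu_hat=0.0, g_tilde=g,
            pev=np.full(4, 0.3), sigma2_g_hat=1.0, sigma2_e_hat=1.0,
            loglik=0.0, g_error_cov=np.diag(np.full(4, 0.3)),
        )
        out = adjust.deregress(fit)
        assert np.all(np.diff(out.adjusted_yield) > 0)

    def test_deshrinkage_slope_near_one_on_simulation(self):
        rng = np.random.default_rng(77)
        g = rng.standard_normal(1000)
        cfg = sim.FieldTrialConfig(n_rows=36, n_ranges=36,
                                   replication_factor=1.25,
                                   sigma2_spatial=0.2, sigma2_nugget=0.8)
        plots = sim.simulate_field_trial(
            [f"L{i:04d}" for i in range(1000)], g, cfg, seed=78)
        fit = adjust.fit_line_blup(plots)
        table = adjust.deregress(fit)
        gmap = {f"L{i:04d}": g[i] for i in range(1000)}
        gt = np.array([gmap[l] for l in table.line_id])
        slope = np.polyfit(gt, table.adjusted_yield, 1)[0]
        gt_all = np.array([gmap[l] for l in fit.line_ids])
        slope_raw = np.polyfit(gt_all, fit.g_tilde, 1)[0]
        assert abs(slope - 1.0) < 0.1
        assert slope_raw < slope
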