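"""Selection layer, objective, gradients, and training contracts."""

import numpy as np
import pytest

from gspred import nn, vbsml
from gspred import simulate as sim


def _tiny_net(p=5, hidden=(4, 3, 1), seed=0, dtype=np.float64, jitter=True):
    rng = np.random.default_rng(seed)
    theta = nn.init_theta(p, hidden, rng, dtype)
    if jitter:
        # keep every preactivation away from the ReLU kinks so the
        # objective is differentiable at the test point
        for k in theta:
            theta[k] = theta[k] + 0.05 * rng.standard_normal(theta[k].shape)
    return theta


class TestSelectionForward:
    def test_identity_gate(self, rng):
        m = rng.integers(0, 3, (6, 8)).astype(float)
        x = vbsml.selection_forward(m, np.ones(8), np.zeros(8), "deterministic")
        np.testing.assert_array_equal(x, m)

    def test_zero_mu_hard_exclusion(self, rng):
        m = rng.integers(0, 3, (4, 3)).astype(float)
        mu = np.array([1.0, 0.0, 2.0])
        la = np.array([0.0, 5.0, -2.0])
        for mode in ("deterministic", "stochastic"):
            x = vbsml.selection_forward(m, mu, la, mode, seed=1)
            np.testing.assert_array_equal(x[:, 1], 0.0)

    def test_stochastic_moments(self):
        # mean -> m*mu, var -> m^2 alpha mu^2 over many draws
        m = np.array([[2.0, 1.0, 1.0]])
        mu = np.array([0.8, -1.2, 0.5])
        la = np.log(np.array([0.3, 1.0, 2.0]))
        rng = np.random.default_rng(5)
        eps = rng.standard_normal((100_000, 3))
        x = vbsml.selection_forward(np.repeat(m, 100_000, 0), mu, la,
                                    "stochastic", eps=eps)
        np.testing.assert_allclose(x.mean(0), (m * mu)[0], rtol=0.02, atol=5e-3)
        np.testing.assert_allclose(
            x.var(0), (m[0] ** 2) * np.exp(la) * mu**2, rtol=0.02)

    def test_width_mismatch(self):
        with pytest.raises(ValueError, match="width"):
            vbsml.selection_forward(np.ones((2, 3)), np.ones(4), np.zeros(4))


class TestObjectivePieces:
    def test_regularizer_closed_forms(self):
        assert abs(vbsml.vbs_regularizer(np.zeros(1)) - 0.5 * np.log(2)) < 1e-12
        assert vbsml.vbs_regularizer(np.full(3, 20.0)) < 1e-6
        a = vbsml.vbs_regularizer(np.log([0.1]))
        b = vbsml.vbs_regularizer(np.log([10.0]))
        assert a > b  # strictly decreasing in alpha

    def test_objective_decomposition(self):
        theta = {"w": np.array([1.0, -2.0])}
        total, comps = vbsml.objective([1.0, 3.0], [2.0, 5.0], theta,
                                       np.full(2, 20.0), 0.0)
        assert abs(comps["mae"] - 1.5) < 1e-12
        total2, comps2 = vbsml.objective([1.0, 3.0], [1.0, 3.0], theta,
                                         np.full(2, 20.0), 1.0)
        assert abs(total2 - 3.0) < 1e-6  # pure L1 term
        total3, _ = vbsml.objective([1.0], [1.0], {"w": np.zeros(1)},
                                    np.full(4, 20.0), 0.0)
        assert total3 < 1e-6

    def test_total_is_sum_of_nonnegative_components(self, rng):
        theta = {"w": rng.standard_normal(7)}
        y, yp = rng.standard_normal((2, 9))
        la = rng.standard_normal(6)
        total, c = vbsml.objective(y, yp, theta, la, 1e-3)
        assert all(v >= 0 for v in c.values())
        assert abs(total - (c["mae"] + 1e-3 * c["l1"] + c["vbs"])) < 1e-12

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vbsml.objective([], [], {"w": np.zeros(1)}, np.zeros(1), 0.0)


class TestGradients:
    def test_analytic_matches_central_differences(self):
        # 5 markers x 8 samples, fixed noise; rel. error < 1e-4
        rng = np.random.default_rng(0)
        p, B = 5, 8
        Mb = rng.standard_normal((B, p))
        yb = rng.standard_normal(B)
        mu = rng.standard_normal(p) * 0.5 + 1.0
        la = rng.standard_normal(p) * 0.5
        theta = _tiny_net(p)
        eps = rng.standard_normal((B, p))
        lam = 1e-2

        def f():
            t, *_ = vbsml._loss_and_grads(Mb, yb, mu, la, theta, lam, eps=eps)
            return t

        _, _, gth, gsel = vbsml._loss_and_grads(Mb, yb, mu, la, theta, lam,
                                                eps=eps)
        h = 1e-6
        worst = 0.0
        for arr, g in ((mu, gsel["mu"]), (la, gsel["log_alpha"])):
            for i in range(p):
                o = arr[i]
                arr[i] = o + h
                fp = f()
                arr[i] = o - h
                fm = f()
                arr[i] = o
                num = (fp - fm) / (2 * h)
                worst = max(worst, abs(num - g[i]) / max(abs(num), 1e-6))
        for k in theta:
            flat, gk = theta[k].ravel(), gth[k].ravel()
            for i in range(flat.size):
                o = flat[i]
                flat[i] = o + h
                fp = f()
                flat[i] = o - h
                fm = f()
                flat[i] = o
                num = (fp - fm) / (2 * h)
                worst = max(worst, abs(num - gk[i]) / max(abs(num), 1e-6))
        assert worst < 1e-4


@pytest.fixture(scope="module")
def tiny_trait():
    m = sim.simulate_genotypes(120, 30, n_chromosomes=3, ld_rho=0.3, seed=51)
    arch, ph = sim.simulate_trait(m, 4, 0.7, seed=52, sd_total=0.5)
    return m, arch, ph


def _fast_cfg(**kw):
    base = dict(max_epochs=30, batch_size=32, seed=0, patience=0,
                selection_warmup=5)
    base.update(kw)
    return vbsml.VBSTrainConfig(**base)


class TestTraining:
    def test_seeded_determinism(self, tiny_trait):
        m, _, ph = tiny_trait
        cfg = _fast_cfg()
        m1 = vbsml.train_vbs(m, ph, vbsml.NetworkSpec((8, 4, 1)), cfg)
        m2 = vbsml.train_vbs(m, ph, vbsml.NetworkSpec((8, 4, 1)), cfg)
        assert m1.history.equals(m2.history)
        np.testing.assert_array_equal(m1.mu, m2.mu)
        np.testing.assert_array_equal(m1.theta["W1"], m2.theta["W1"])

    def test_frozen_selection_reduces_to_naive(self, tiny_trait):
        m, _, ph = tiny_trait
        cfg = _fast_cfg(max_epochs=15)
        spec = vbsml.NetworkSpec((8, 4, 1))
        frozen = vbsml.train_vbs(m, ph, spec, cfg, freeze_selection=True,
                                 init_mu=np.ones(30),
                                 init_log_alpha=np.full(30, 20.0))
        naive = vbsml.train_naive(m, ph, spec, cfg)
        np.testing.assert_allclose(frozen.history["mae"], naive.history["mae"],
                                   atol=1e-12)
        np.testing.assert_array_equal(frozen.theta["W1"], naive.theta["W1"])

    def test_history_components_sum_to_total(self, tiny_trait):
        m, _, ph = tiny_trait
        model = vbsml.train_vbs(m, ph, vbsml.NetworkSpec((8, 4, 1)), _fast_cfg())
        h = model.history
        np.testing.assert_allclose(
            h["total"],
            h["mae"] + model.cfg.lambda_theta * h["l1"] + h["vbs"],
            rtol=1e-10)
        assert (h[["mae", "l1", "vbs"]] >= 0).all().all()

    def test_select_features_contracts(self, tiny_trait):
        m, _, ph = tiny_trait
        model = vbsml.train_vbs(m, ph, vbsml.NetworkSpec((8, 4, 1)), _fast_cfg())
        sel = vbsml.select_features(model)
        assert np.all(np.diff(sel.indices) > 0)
        assert np.all(sel.criterion_value
                      < model.cfg.selection_threshold_log_alpha)
        # total sparsity is reported, not an error
        model.log_alpha = np.full(30, 20.0)
        empty = vbsml.select_features(model)
        assert empty.n_selected == 0
        naive = vbsml.train_naive(m, ph, vbsml.NetworkSpec((8, 4, 1)),
                                  _fast_cfg(max_epochs=5))
        with pytest.raises(ValueError, match="selection"):
            vbsml.select_features(naive)

    def test_prediction_ignores_pruned_markers(self, tiny_trait):
        m, _, ph = tiny_trait
        model = vbsml.train_vbs(m, ph, vbsml.NetworkSpec((8, 4, 1)),
                                _fast_cfg(max_epochs=40))
        pred = vbsml.predict(model, m)
        dropped = np.where(model.log_alpha
                           >= model.cfg.selection_threshold_log_alpha)[0]
        d = m.dosages.copy()
        d[:, dropped] = 0.0
        from gspred.data import MarkerMatrix
        m_zeroed = MarkerMatrix(m.line_ids, m.marker_ids, d)
        pred2 = vbsml.predict(model, m_zeroed)
        np.testing.assert_allclose(pred, pred2, atol=1e-6)

    def test_prediction_deterministic_and_batch_invariant(self, tiny_trait):
        m, _, ph = tiny_trait
        model = vbsml.train_vbs(m, ph, vbsml.NetworkSpec((8, 4, 1)), _fast_cfg())
        p1 = vbsml.predict(model, m)
        p2 = vbsml.predict(model, m)
        np.testing.assert_array_equal(p1, p2)
        rows = np.concatenate([vbsml.predict(model, m.subset_lines([i, i + 1]))
                               for i in range(0, 10, 2)])
        np.testing.assert_allclose(rows, p1[:10], atol=1e-6)

    def test_permutation_equivariance_with_shared_init(self, tiny_trait):
        m, _, ph = tiny_trait
        p = m.n_markers
        spec = vbsml.NetworkSpec((8, 4, 1), dropout_rate=0.0)
        cfg = _fast_cfg(max_epochs=20, stochastic_gates=False,
                        batch_size=120, dtype="float64")
        rng = np.random.default_rng(99)
        theta0 = nn.init_theta(p, spec.hidden_sizes, rng, np.float64)
        m1 = vbsml.train_vbs(m, ph, spec, cfg, init_theta=theta0)

        perm = np.random.default_rng(7).permutation(p)
        theta_p = {k: (v[perm] if k == "W1" else v.copy())
                   for k, v in theta0.items()}
        m2 = vbsml.train_vbs(m.subset_markers(perm), ph, spec, cfg,
                             init_theta=theta_p)
        np.testing.assert_allclose(m2.mu, m1.mu[perm], atol=1e-8)
        np.testing.assert_allclose(m2.log_alpha, m1.log_alpha[perm], atol=1e-8)
        sel1 = set(m1.selected.indices.tolist())
        sel2 = {int(perm[i]) for i in m2.selected.indices}
        assert sel1 == sel2

    def test_transfer_requires_nonempty_selection(self, tiny_trait):
        m, _, ph = tiny_trait
        empty = vbsml.SelectedMarkers(np.empty(0, int), np.empty(0), np.empty(0))
        with pytest.raises(ValueError, match="empty"):
            vbsml.train_transfer(empty, m, ph)

    def test_transfer_on_full_set_equals_naive(self, tiny_trait):
        m, _, ph = tiny_trait
        cfg = _fast_cfg(max_epochs=10)
        sel = vbsml.SelectedMarkers(np.arange(30), np.ones(30), np.zeros(30))
        t = vbsml.train_transfer(sel, m, ph, vbsml.NetworkSpec((8, 4, 1)), cfg)
        n = vbsml.train_naive(m, ph, vbsml.NetworkSpec((8, 4, 1)), cfg)
        np.testing.assert_allclose(t.history["mae"], n.history["mae"],
                                   atol=1e-12)

    def test_checkpoint_round_trip(self, tiny_trait, tmp_path):
        m, _, ph = tiny_trait
        model = vbsml.train_vbs(m, ph, vbsml.NetworkSpec((8, 4, 1)), _fast_cfg())
        path = tmp_path / "ck.npz"
        model.save(path)
        back = vbsml.FittedVBSModel.load(path)
        np.testing.assert_array_equal(back.mu, model.mu)
        np.testing.assert_allclose(vbsml.predict(back, m),
                                   vbsml.predict(model, m), atol=1e-7)
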