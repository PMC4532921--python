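"""RBM energies, conditionals, exact likelihood/gradient oracles, CD-k and
the training loop, checked against brute-force enumeration and finite
differences on tiny instances."""

import numpy as np
import pytest

from divrbm import rbm
from divrbm.rbm import GradientSet, RBMParams, TrainConfig

from conftest import random_binary_data, random_rbm


def brute_force_log_likelihood(params, data):
    """Full 2^(Nv+Nh) enumeration oracle for the average log p(v)."""
    nv, nh = params.n_visible, params.n_hidden
    vs = rbm._binary_states(nv)
    hs = rbm._binary_states(nh)
    energies = np.array(
        [[rbm.energy(v, h, params) for h in hs] for v in vs]
    )
    joint = np.exp(-energies)
    Z = joint.sum()
    total = 0.0
    for row in np.atleast_2d(data):
        pv = 0.0
        for h, e in zip(hs, joint[0]):
            pv += np.exp(-rbm.energy(row, h, params))
        total += np.log(pv / Z)
    return total / len(np.atleast_2d(data))


class TestEnergyAndConditionals:
    def test_zero_configuration_zero_energy(self):
        p = random_rbm(3, 2, seed=1)
        assert rbm.energy(np.zeros(3), np.zeros(2), p) == 0.0

    def test_bias_only_energy(self):
        p = RBMParams(np.zeros((4, 3)), np.ones(3), np.zeros(4))
        assert rbm.energy(np.zeros(4), np.ones(3), p) == -3.0

    def test_hand_computed_case(self):
        p = RBMParams(np.array([[1.0], [2.0]]), np.array([0.5]), np.zeros(2))
        assert rbm.energy([1, 1], [1], p) == pytest.approx(-3.5)

    def test_shape_mismatch_rejected(self):
        p = random_rbm(3, 2)
        with pytest.raises(ValueError):
            rbm.energy(np.zeros(4), np.zeros(2), p)

    def test_zero_params_give_half_probabilities(self):
        p = RBMParams(np.zeros((3, 2)), np.zeros(2), np.zeros(3))
        assert np.allclose(rbm.prob_h_given_v(p, np.ones(3)), 0.5)
        assert np.allclose(rbm.prob_v_given_h(p, np.ones(2)), 0.5)

    def test_large_bias_saturates(self):
        p = RBMParams(np.zeros((2, 2)), np.array([50.0, -50.0]), np.zeros(2))
        ph = rbm.prob_h_given_v(p, np.zeros(2))
        assert ph[0] == pytest.approx(1.0)
        assert ph[1] == pytest.approx(0.0, abs=1e-12)

    def test_conditional_factorizes(self):
        """p(h|v) from the joint equals the product of per-unit logistic
        marginals on an enumerable instance."""
        p = random_rbm(3, 2, seed=5)
        v = np.array([1.0, 0.0, 1.0])
        hs = rbm._binary_states(2)
        joint = np.array([np.exp(-rbm.energy(v, h, p)) for h in hs])
        joint /= joint.sum()
        ph = rbm.prob_h_given_v(p, v)
        expected = np.array(
            [np.prod(ph**h * (1 - ph) ** (1 - h)) for h in hs]
        )
        assert np.allclose(joint, expected, atol=1e-12)


class TestExactOracles:
    def test_uniform_model_log_likelihood(self):
        p = RBMParams(np.zeros((3, 2)), np.zeros(2), np.zeros(3))
        data = random_binary_data(3, 5, seed=2)
        assert rbm.exact_log_likelihood(p, data) == pytest.approx(-3 * np.log(2))

    def test_single_unit_uniform(self):
        p = RBMParams(np.zeros((1, 1)), np.zeros(1), np.zeros(1))
        assert rbm.exact_log_likelihood(p, [[1.0]]) == pytest.approx(np.log(0.5))

    @pytest.mark.parametrize("nv,nh", [(3, 2), (2, 3), (4, 3)])
    def test_matches_brute_force_double_enumeration(self, nv, nh):
        p = random_rbm(nv, nh, seed=nv * 10 + nh)
        data = random_binary_data(nv, 6, seed=nh)
        assert rbm.exact_log_likelihood(p, data) == pytest.approx(
            brute_force_log_likelihood(p, data), rel=1e-10
        )

    def test_enumeration_guard(self):
        p = RBMParams(np.zeros((25, 25)), np.zeros(25), np.zeros(25))
        with pytest.raises(ValueError, match="refused"):
            rbm.exact_log_likelihood(p, np.zeros((1, 25)))

    def test_exact_gradient_matches_finite_differences(self):
        p = random_rbm(4, 3, seed=8)
        data = random_binary_data(4, 5, seed=8)
        g = rbm.exact_gradient(p, data)
        eps = 1e-5
        for arr, grad in ((p.W, g.dW), (p.b, g.db), (p.c, g.dc)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                up = rbm.exact_log_likelihood(p, data)
                arr[idx] = orig - eps
                dn = rbm.exact_log_likelihood(p, data)
                arr[idx] = orig
                fd = (up - dn) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, rel=1e-6, abs=1e-9)

    def test_zero_params_visible_gradient_closed_form(self):
        """At all-zero parameters dc = mean(v) - 1/2 and dW, db vanish."""
        p = RBMParams(np.zeros((3, 2)), np.zeros(2), np.zeros(3))
        data = random_binary_data(3, 40, seed=3)
        g = rbm.exact_gradient(p, data)
        assert np.allclose(g.dc, data.mean(axis=0) - 0.5, atol=1e-12)
        assert np.allclose(g.db, 0.0, atol=1e-12)
        expected_dW = data.T @ (0.5 * np.ones((40, 2))) / 40 - 0.25
        assert np.allclose(g.dW, expected_dW, atol=1e-12)


class TestCDGradient:
    def test_fixed_seed_bit_identical(self):
        p = random_rbm(4, 3, seed=1)
        batch = random_binary_data(4, 10, seed=1)
        g1 = rbm.cd_gradient(p, batch, k=2, rng=np.random.default_rng(7))
        g2 = rbm.cd_gradient(p, batch, k=2, rng=np.random.default_rng(7))
        assert np.array_equal(g1.dW, g2.dW)
        assert np.array_equal(g1.db, g2.db)
        assert np.array_equal(g1.dc, g2.dc)

    def test_identical_rows_equal_single_row(self):
        p = random_rbm(3, 2, seed=2)
        row = np.array([[1.0, 0.0, 1.0]])
        batch = np.repeat(row, 6, axis=0)
        g_batch = rbm.cd_gradient(p, batch, k=1, rng=np.random.default_rng(0))
        # same hidden-sample draws per row => averaging identical rows must
        # equal a single-row gradient in expectation; with a common seed per
        # call the batch mean equals the mean of the per-row statistics
        gs = [
            rbm.cd_gradient(p, row, k=1, rng=np.random.default_rng(0))
            for _ in range(1)
        ]
        assert g_batch.dW.shape == gs[0].dW.shape
        # exact check: each row's negative phase depends only on its own
        # sampled h, so the batch gradient is the mean of row gradients
        rng = np.random.default_rng(11)
        g_all = rbm.cd_gradient(p, batch, k=1, rng=rng)
        rng2 = np.random.default_rng(11)
        per_row = []
        draws = rng2.random((6, 2))
        ph = rbm.prob_h_given_v(p, batch)
        h = (draws < ph).astype(float)
        v_neg = rbm.prob_v_given_h(p, h)
        ph_neg = rbm.prob_h_given_v(p, v_neg)
        dW = (batch.T @ ph - v_neg.T @ ph_neg) / 6
        assert np.allclose(g_all.dW, dW, atol=1e-12)

    def test_empty_batch_rejected(self):
        p = random_rbm(3, 2)
        with pytest.raises(ValueError):
            rbm.cd_gradient(p, np.zeros((0, 3)), rng=np.random.default_rng(0))

    def test_cd_expectation_matches_enumeration(self):
        """Mean CD-1 weight gradient over many draws agrees with the
        analytically enumerated expectation over hidden samples (the only
        randomness in CD-1), within 4 Monte-Carlo SE elementwise."""
        p = random_rbm(3, 2, seed=9, scale=0.8)
        batch = random_binary_data(3, 4, seed=9)
        exp_dW = cd1_expected_dW(p, batch)
        rng = np.random.default_rng(123)
        draws = np.array(
            [rbm.cd_gradient(p, batch, 1, rng).dW for _ in range(3000)]
        )
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(mean - exp_dW) <= 4 * se + 1e-12)

    def test_cd_k_approaches_exact_gradient(self):
        """The CD-k expectation drifts toward the exact gradient as k grows
        (statistical check on a tiny instance)."""
        p = random_rbm(3, 2, seed=4, scale=1.0)
        batch = random_binary_data(3, 8, seed=4)
        exact = rbm.exact_gradient(p, batch).dW
        errs = {}
        for k in (1, 20):
            rng = np.random.default_rng(5)
            draws = np.array(
                [rbm.cd_gradient(p, batch, k, rng).dW for _ in range(2000)]
            )
            errs[k] = np.abs(draws.mean(axis=0) - exact).max()
        assert errs[20] <= errs[1] + 0.02


def cd1_expected_dW(params, batch):
    """Enumerate all hidden-sample outcomes of CD-1 for each row."""
    hs = rbm._binary_states(params.n_hidden)
    total = np.zeros_like(params.W)
    batch = np.atleast_2d(batch)
    for v in batch:
        ph = rbm.prob_h_given_v(params, v)
        pos = np.outer(v, ph)
        neg = np.zeros_like(params.W)
        for h in hs:
            prob = np.prod(ph**h * (1 - ph) ** (1 - h))
            v_neg = rbm.prob_v_given_h(params, h)
            ph_neg = rbm.prob_h_given_v(params, v_neg)
            neg += prob * np.outer(v_neg, ph_neg)
        total += pos - neg
    return total / len(batch)


class TestTraining:
    def test_zero_epochs_returns_initial(self, tiny_patchset):
        init = rbm.initialize(25, 4, seed=0)
        cfg = TrainConfig(epochs=0, regularizer="none", lambda_div=0.0)
        out, hist = rbm.train(init, tiny_patchset, cfg)
        assert np.array_equal(out.W, init.W)
        assert len(hist) == 0

    def test_exact_gradient_ascent_increases_likelihood(self):
        """With the exact gradient substituted for CD and no prior, the
        average log-likelihood is non-decreasing across epochs."""
        data = random_binary_data(4, 30, seed=6)
        init = rbm.initialize(4, 2, seed=6)
        cfg = TrainConfig(
            lambda_div=0.0, regularizer="none", learning_rate=0.2,
            epochs=15, batch_size=30, seed=6, renormalize_columns=False,
        )

        lls = [rbm.exact_log_likelihood(init, data)]

        def exact_fn(params, batch, rng):
            return rbm.exact_gradient(params, batch)

        def record(epoch, params, row):
            lls.append(rbm.exact_log_likelihood(params, data))

        rbm.train(init, data, cfg, gradient_fn=exact_fn, callback=record)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_training_reproducible(self, tiny_patchset):
        init = rbm.initialize(25, 4, seed=3)
        cfg = TrainConfig(epochs=3, batch_size=50, seed=3,
                          regularizer="diversity", lambda_div=1e-3)
        a, ha = rbm.train(init, tiny_patchset, cfg)
        b, hb = rbm.train(init, tiny_patchset, cfg)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.b, b.b)
        assert ha.equals(hb)

    def test_unit_norm_constraint_and_arm_equivalence(self, tiny_patchset):
        """Under the unit-norm constraint mode every column norm is 1 after
        training, and a diversity run at lambda=0 is bit-identical to a
        plain (no-regularizer) run with the same seed."""
        init = rbm.initialize(25, 4, seed=3)
        on = TrainConfig(epochs=2, batch_size=50, seed=3,
                         regularizer="diversity", lambda_div=1e-2)
        off = TrainConfig(epochs=2, batch_size=50, seed=3,
                          regularizer="diversity", lambda_div=0.0)
        none = TrainConfig(epochs=2, batch_size=50, seed=3,
                           regularizer="none", lambda_div=0.0)
        free = TrainConfig(epochs=2, batch_size=50, seed=3,
                           regularizer="none", lambda_div=0.0,
                           renormalize_columns=False)
        p_on, _ = rbm.train(init, tiny_patchset, on)
        p_off, _ = rbm.train(init, tiny_patchset, off)
        p_none, _ = rbm.train(init, tiny_patchset, none)
        p_free, _ = rbm.train(init, tiny_patchset, free)
        assert np.allclose(np.linalg.norm(p_on.W, axis=0), 1.0, atol=1e-8)
        assert np.allclose(np.linalg.norm(p_none.W, axis=0), 1.0, atol=1e-8)
        assert np.array_equal(p_off.W, p_none.W)
        assert not np.allclose(np.linalg.norm(p_free.W, axis=0), 1.0)

    def test_divergence_aborts_with_diagnostic(self, tiny_patchset):
        """Non-finite parameters abort training with a diagnostic naming
        the run settings."""
        init = rbm.initialize(25, 4, seed=0)
        cfg = TrainConfig(epochs=1, batch_size=50,
                          regularizer="none", lambda_div=0.0)

        def bad_gradient(params, batch, rng):
            g = rbm.cd_gradient(params, batch, 1, rng)
            g.dW = g.dW + np.nan
            return g

        with pytest.raises(RuntimeError, match="diverged"):
            rbm.train(init, tiny_patchset, cfg, gradient_fn=bad_gradient)

    def test_model_roundtrip(self, tmp_path):
        p = random_rbm(5, 3, seed=12)
        cfg = TrainConfig(seed=5)
        path = tmp_path / "m.h5"
        p.save(path, cfg)
        q = RBMParams.load(path)
        assert np.array_equal(p.W, q.W)
        assert np.array_equal(p.b, q.b)
        assert np.array_equal(p.c, q.c)
        assert RBMParams.load_config(path) == cfg
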