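"""Encoding, prediction and training objectives of the neural processes."""

import numpy as np
import pytest

from molnp.np_core import (ContextSet, PredictiveGaussian, TargetSet,
                           TaskObservations, clone_model, cnp_loss,
                           encode_contexts, gaussian_kl, load_model,
                           log_predictive_density, lnp_loss, lnp_posterior,
                           make_cnp, make_lnp, predict, save_model,
                           VAR_FLOOR)


def _permute_context(ctx, perm):
    return ContextSet(np.asarray(ctx.x)[perm], ctx.y[perm])


class TestEncodeContexts:
    def test_permutation_invariance(self, small_cnp, toy_context, rng):
        r0 = encode_contexts(small_cnp, toy_context).r
        perm = rng.permutation(toy_context.size)
        r1 = encode_contexts(small_cnp, _permute_context(toy_context, perm)).r
        assert np.allclose(r0, r1, atol=1e-6)

    def test_empty_context_is_zero(self, small_cnp):
        enc = encode_contexts(small_cnp, ContextSet(np.zeros((0, 3)), []))
        assert np.array_equal(enc.r, np.zeros(small_cnp.r_dim))

    def test_duplication_invariance(self, small_cnp, toy_context):
        r0 = encode_contexts(small_cnp, toy_context).r
        doubled = ContextSet(np.concatenate([toy_context.x, toy_context.x]),
                             np.concatenate([toy_context.y, toy_context.y]))
        assert np.allclose(r0, encode_contexts(small_cnp, doubled).r,
                           atol=1e-10)

    def test_dimension_mismatch_raises(self, small_cnp):
        with pytest.raises(ValueError, match="x_dim"):
            encode_contexts(small_cnp, ContextSet(np.zeros((4, 7)),
                                                  np.zeros(4)))


class TestPredict:
    def test_shapes_and_positive_variance(self, small_cnp, toy_context, rng):
        tx = rng.normal(size=(9, 3))
        pred = predict(small_cnp, toy_context, tx)
        assert pred.mean.shape == (9,)
        assert (pred.variance >= VAR_FLOOR).all()

    def test_target_permutation_equivariance(self, small_cnp, toy_context,
                                             rng):
        tx = rng.normal(size=(9, 3))
        perm = rng.permutation(9)
        p0 = predict(small_cnp, toy_context, tx)
        p1 = predict(small_cnp, toy_context, tx[perm])
        assert np.allclose(p0.mean[perm], p1.mean)
        assert np.allclose(p0.variance[perm], p1.variance)

    def test_deterministic(self, small_cnp, toy_context, rng):
        tx = rng.normal(size=(5, 3))
        p0 = predict(small_cnp, toy_context, tx)
        p1 = predict(small_cnp, toy_context, tx)
        assert np.array_equal(p0.mean, p1.mean)
        assert np.array_equal(p0.variance, p1.variance)

    def test_variance_floor_on_extreme_inputs(self, small_cnp, toy_context):
        pred = predict(small_cnp, toy_context, np.full((3, 3), 50.0))
        assert np.isfinite(pred.mean).all()
        assert (pred.variance >= VAR_FLOOR).all()


class TestLogPredictiveDensity:
    def test_standard_normal_at_mean(self):
        pred = PredictiveGaussian(mean=[0.0], variance=[1.0])
        assert log_predictive_density(pred, [0.0]) == pytest.approx(
            -0.9189385, abs=1e-6)

    def test_additivity(self):
        one = PredictiveGaussian(mean=[0.3], variance=[0.5])
        many = PredictiveGaussian(mean=[0.3] * 7, variance=[0.5] * 7)
        assert log_predictive_density(many, [0.1] * 7) == pytest.approx(
            7 * log_predictive_density(one, [0.1]))

    def test_variance_doubling_at_mode(self):
        p1 = PredictiveGaussian(mean=[1.0], variance=[1.0])
        p2 = PredictiveGaussian(mean=[1.0], variance=[2.0])
        drop = (log_predictive_density(p1, [1.0])
                - log_predictive_density(p2, [1.0]))
        assert drop == pytest.approx(0.5 * np.log(2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            log_predictive_density(
                PredictiveGaussian(mean=[0.0], variance=[1.0]), [0.0, 1.0])


class TestCnpLoss:
    def test_equals_negative_log_density(self, small_cnp, toy_context,
                                         toy_targets):
        loss = cnp_loss(small_cnp, toy_context, toy_targets)
        pred = predict(small_cnp, toy_context, toy_targets.x)
        assert loss == pytest.approx(
            -log_predictive_density(pred, toy_targets.y), rel=1e-10)

    def test_context_permutation_invariance(self, small_cnp, toy_context,
                                            toy_targets, rng):
        l0 = cnp_loss(small_cnp, toy_context, toy_targets)
        perm = rng.permutation(toy_context.size)
        l1 = cnp_loss(small_cnp, _permute_context(toy_context, perm),
                      toy_targets)
        assert l1 == pytest.approx(l0, abs=1e-6)

    def test_unlabelled_targets_rejected(self, small_cnp, toy_context):
        with pytest.raises(ValueError, match="labels"):
            cnp_loss(small_cnp, toy_context, TargetSet(np.zeros((2, 3))))


class TestLatentPath:
    def test_posterior_permutation_invariant(self, small_lnp, toy_context,
                                             rng):
        p0 = lnp_posterior(small_lnp, toy_context)
        perm = rng.permutation(toy_context.size)
        p1 = lnp_posterior(small_lnp, _permute_context(toy_context, perm))
        assert np.allclose(p0.mean, p1.mean, atol=1e-6)
        assert np.allclose(p0.variance, p1.variance, atol=1e-6)
        assert (p0.variance > 0).all()

    def test_posterior_deterministic_and_data_dependent(self, small_lnp,
                                                        toy_task):
        x, y = toy_task
        small = ContextSet(x[:10], y[:10])
        big = ContextSet(x[:25], y[:25])
        a = lnp_posterior(small_lnp, small)
        b = lnp_posterior(small_lnp, small)
        c = lnp_posterior(small_lnp, big)
        assert np.array_equal(a.mean, b.mean)
        assert not np.allclose(a.mean, c.mean)

    def test_kl_closed_form(self):
        assert gaussian_kl([1.0], [1.0], [0.0], [1.0]) == pytest.approx(0.5)
        assert gaussian_kl([0.0], [1.0], [0.0], [1.0]) == 0.0

    def test_loss_seeded_repeatability(self, small_lnp, toy_context,
                                       toy_targets):
        l0 = lnp_loss(small_lnp, toy_context, toy_targets,
                      np.random.default_rng(7))
        l1 = lnp_loss(small_lnp, toy_context, toy_targets,
                      np.random.default_rng(7))
        assert l0 == l1


class TestCheckpoint:
    def test_roundtrip_bit_stable(self, small_lnp, toy_context, tmp_path,
                                  rng):
        path = tmp_path / "model.npz"
        save_model(small_lnp, path)
        loaded = load_model(path)
        src = dict(small_lnp.named_parameters())
        for name, p in loaded.named_parameters():
            assert np.array_equal(p.data, src[name].data), name
        tx = rng.normal(size=(4, 3))
        p0 = predict(small_lnp, toy_context, tx)
        p1 = predict(loaded, toy_context, tx)
        assert np.array_equal(p0.mean, p1.mean)

    def test_clone_is_independent(self, small_cnp):
        twin = clone_model(small_cnp)
        twin.encoder.layers[0].W.data += 1.0
        assert not np.allclose(twin.encoder.layers[0].W.data,
                               small_cnp.encoder.layers[0].W.data)


class TestBayesLinearRegressionOracle:
    """A trained CNP approaches the exact Bayes posterior mean on linear
    tasks with a known weight prior."""

    @staticmethod
    def _bayes_mean(xc, yc, xt, prior_var=1.0, noise_var=0.01):
        # 1-D Bayesian linear regression, w ~ N(0, prior_var)
        precision = 1.0 / prior_var + (xc ** 2).sum() / noise_var
        w_post = (xc * yc).sum() / noise_var / precision
        return w_post * xt

    def test_cnp_approaches_bayes_posterior(self):
        from molnp.meta_train import SamplingConfig, meta_train

        rng = np.random.default_rng(11)
        noise_sd = 0.1
        tasks = []
        for _ in range(300):
            w = rng.normal()
            x = rng.uniform(-2, 2, size=30)
            y = w * x + noise_sd * rng.normal(size=30)
            tasks.append(TaskObservations(x[:, None], y))
        model = make_cnp(1, rng, r_dim=32, z_dim=16, width=32)
        cfg = SamplingConfig(c_range=(3, 12), t_range=(3, 12))
        gaps = []
        for n_epochs in (10, 190):
            model, _ = meta_train(model, tasks, cfg, n_epochs, rng)
            errs = []
            test_rng = np.random.default_rng(5)
            for _ in range(40):
                w = test_rng.normal()
                xc = test_rng.uniform(-2, 2, size=8)
                yc = w * xc + noise_sd * test_rng.normal(size=8)
                xt = test_rng.uniform(-2, 2, size=20)
                pred = predict(model, ContextSet(xc[:, None], yc), xt[:, None])
                bayes = self._bayes_mean(xc, yc, xt,
                                         noise_var=noise_sd ** 2)
                errs.append(np.sqrt(np.mean((pred.mean - bayes) ** 2)))
            gaps.append(np.mean(errs))
        # RMSE gap to the closed-form oracle shrinks with training
        assert gaps[-1] < gaps[0]
        assert gaps[-1] < 0.25
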