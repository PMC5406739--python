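import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mtmdecode as md
from mtmdecode.mtm import RegimePosterior
from mtmdecode.regime import ModelSet, RegimeModel
from helpers import random_regime_model
from oracles import grid_mixture_decode, kalman_filter


def model_1d(A=1.0, b=0.0, Q=1.0, H=1.0, p=0.0, V=1.0, key=("m",)):
    return RegimeModel(
        key=key,
        A=np.array([[A]]), b=np.array([b]), Q=np.array([[Q]]),
        H=np.array([[H]]), p=np.array([p]), V=np.array([[V]]),
    )


class TestPredictStep:
    def test_identity_dynamics_leave_posterior_unchanged(self):
        post = RegimePosterior(np.array([1.0, 2.0]), np.diag([0.5, 0.7]))
        model = RegimeModel(("m",), np.eye(2), np.zeros(2), np.zeros((2, 2)),
                            np.eye(2), np.zeros(2), np.eye(2))
        pred = md.predict_step(post, model)
        assert np.allclose(pred.mean, post.mean)
        assert np.allclose(pred.cov, post.cov)

    def test_random_walk_adds_variances(self):
        pred = md.predict_step(RegimePosterior(np.zeros(1), np.eye(1)), model_1d())
        assert pred.mean == pytest.approx(0.0)
        assert pred.cov[0, 0] == pytest.approx(2.0)

    def test_bias_translates_mean_only(self):
        post = RegimePosterior(np.array([0.0, 0.0]), np.eye(2))
        model = RegimeModel(("m",), np.eye(2), np.array([1.0, 0.0]),
                            0.25 * np.eye(2), np.eye(2), np.zeros(2), np.eye(2))
        pred = md.predict_step(post, model)
        assert np.allclose(pred.mean, [1.0, 0.0])
        assert np.allclose(pred.cov, 1.25 * np.eye(2))


class TestUpdateStep:
    def test_scalar_closed_form(self):
        """Prior N(0,2), obs y=2 with unit noise: posterior N(4/3, 2/3)."""
        upd = md.update_step(
            RegimePosterior(np.zeros(1), 2 * np.eye(1)), np.array([2.0]), model_1d()
        )
        assert upd.mean[0] == pytest.approx(4.0 / 3.0)
        assert upd.cov[0, 0] == pytest.approx(2.0 / 3.0)

    def test_uninformative_observation_keeps_prediction(self):
        pred = RegimePosterior(np.array([0.7]), np.array([[1.3]]))
        upd = md.update_step(pred, np.array([5.0]), model_1d(V=1e12))
        assert upd.mean[0] == pytest.approx(0.7, abs=1e-9)
        assert upd.cov[0, 0] == pytest.approx(1.3, abs=1e-9)

    def test_decoupled_observation_likelihood_ignores_state(self):
        m = model_1d(H=0.0, p=1.0, V=2.0)
        upd_a = md.update_step(RegimePosterior(np.array([0.0]), np.eye(1)), np.array([1.5]), m)
        upd_b = md.update_step(RegimePosterior(np.array([9.0]), np.eye(1)), np.array([1.5]), m)
        assert np.allclose(upd_a.mean, [0.0])
        assert upd_a.log_likelihood_increment == pytest.approx(
            upd_b.log_likelihood_increment
        )

    def test_singular_innovation_raises(self):
        m = model_1d(Q=0.0, V=0.0)
        with pytest.raises(ValueError, match="singular"):
            md.update_step(RegimePosterior(np.zeros(1), np.zeros((1, 1))),
                           np.array([0.0]), m)


class TestCollapse:
    def test_identical_components_collapse_to_themselves(self):
        posts = [RegimePosterior(np.array([1.0, -1.0]), np.diag([2.0, 3.0]))] * 3
        mean, cov = md.collapse_mixture(posts, np.array([0.2, 0.3, 0.5]))
        assert np.allclose(mean, [1.0, -1.0])
        assert np.allclose(cov, np.diag([2.0, 3.0]))

    def test_two_point_masses(self):
        posts = [
            RegimePosterior(np.array([1.0]), np.zeros((1, 1))),
            RegimePosterior(np.array([-1.0]), np.zeros((1, 1))),
        ]
        mean, cov = md.collapse_mixture(posts, np.array([0.5, 0.5]))
        assert mean[0] == pytest.approx(0.0)
        assert cov[0, 0] == pytest.approx(1.0)

    def test_degenerate_weight_selects_component(self):
        posts = [
            RegimePosterior(np.array([2.0]), np.array([[0.5]])),
            RegimePosterior(np.array([-7.0]), np.array([[9.0]])),
        ]
        mean, cov = md.collapse_mixture(posts, np.array([1.0, 0.0]))
        assert mean[0] == pytest.approx(2.0)
        assert cov[0, 0] == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_collapsed_cov_psd_and_exceeds_weighted_mean_cov(self, seed):
        """Mixture covariance is PSD and >= the within-component average."""
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 5)
        posts = []
        for _ in range(k):
            L = rng.normal(size=(2, 2))
            posts.append(RegimePosterior(rng.normal(size=2), L @ L.T + 0.01 * np.eye(2)))
        w = rng.dirichlet(np.ones(k))
        mean, cov = md.collapse_mixture(posts, w)
        within = sum(wi * p.cov for wi, p in zip(w, posts))
        assert np.linalg.eigvalsh(cov - within).min() >= -1e-10


def toy_model_set(models, m0, P0):
    keys = [m.key for m in models]
    return ModelSet(keys=keys, models={m.key: m for m in models},
                    initial_mean=np.asarray(m0, float),
                    initial_cov=np.asarray(P0, float))


class TestDecodeTrial:
    def test_single_regime_equals_textbook_kalman(self):
        rng = np.random.default_rng(3)
        model = random_regime_model(rng, d=2, n=5)
        ms = toy_model_set([model], rng.normal(size=2), np.eye(2))
        ys = rng.normal(size=(6, 5))
        res = md.decode_trial(ys, ms)
        means, covs, logliks = kalman_filter(
            ys, model.A, model.b, model.Q, model.H, model.p, model.V,
            ms.initial_mean, ms.initial_cov,
        )
        assert np.allclose(res.means, means, atol=1e-9)
        assert np.allclose(res.covs, covs, atol=1e-9)
        lls = [p.per_regime[model.key].log_likelihood_increment for p in res.posteriors]
        assert np.allclose(lls, logliks, atol=1e-9)

    def test_point_mass_prior_selects_regime_filter(self):
        rng = np.random.default_rng(4)
        models = [random_regime_model(rng, 2, 4) for _ in range(3)]
        for i, m in enumerate(models):
            m.key = (f"m{i}",)
        ms = toy_model_set(models, np.zeros(2), np.eye(2))
        ys = rng.normal(size=(5, 4))
        prior = np.array([0.0, 1.0, 0.0])
        res = md.decode_trial(ys, ms, md.DecodeConfig(prior_over_regimes=prior))
        solo = md.decode_trial(ys, toy_model_set([models[1]], np.zeros(2), np.eye(2)))
        assert np.allclose(res.means, solo.means, atol=1e-12)
        assert np.allclose(res.weights[:, 1], 1.0)

    def test_mismatched_prior_length_rejected(self):
        rng = np.random.default_rng(5)
        ms = toy_model_set([random_regime_model(rng)], np.zeros(2), np.eye(2))
        with pytest.raises(ValueError, match="prior"):
            md.decode_trial(rng.normal(size=(3, 4)), ms,
                            md.DecodeConfig(prior_over_regimes=np.array([0.5, 0.5])))

    def test_static_weights_stay_at_prior(self):
        rng = np.random.default_rng(6)
        models = [random_regime_model(rng, 1, 2) for _ in range(2)]
        models[0].key, models[1].key = ("a",), ("b",)
        ms = toy_model_set(models, np.zeros(1), np.eye(1))
        prior = np.array([0.3, 0.7])
        res = md.decode_trial(
            rng.normal(size=(4, 2)), ms,
            md.DecodeConfig(prior_over_regimes=prior, weight_update="static"),
        )
        assert np.allclose(res.weights, np.tile(prior, (4, 1)))

    def test_grid_integration_oracle_1d(self):
        """Collapsed means match dense numerical integration of the recursion."""
        m1 = model_1d(A=0.8, b=0.5, Q=0.4, H=1.2, p=0.1, V=0.6, key=("r1",))
        m2 = model_1d(A=1.1, b=-0.3, Q=0.3, H=0.7, p=-0.2, V=0.8, key=("r2",))
        ms = toy_model_set([m1, m2], np.array([0.2]), np.array([[0.8]]))
        ys = np.array([[0.5], [1.4], [-0.3]])
        prior = np.array([0.35, 0.65])
        res = md.decode_trial(ys, ms, md.DecodeConfig(prior_over_regimes=prior))
        grid_means, grid_w = grid_mixture_decode(
            ys,
            [(m.A, m.b, m.Q, m.H, m.p, m.V) for m in (m1, m2)],
            prior, ms.initial_mean, ms.initial_cov,
            axes=[np.linspace(-10, 10, 2001)],
        )
        assert np.allclose(res.means, grid_means, atol=1e-3)
        assert np.allclose(res.weights, grid_w, atol=1e-3)

    def test_prior_sharpness_never_hurts(self, small_session, geometry):
        """MSE is non-increasing as the prior concentrates on the true regime."""
        ms = md.fit_model_set(small_session)
        tests = small_session[:15]
        mses = []
        for eps in (1.0, 0.5, 0.2, 0.0):
            total = 0.0
            for t in tests:
                prior = np.full(6, eps / 6)
                prior[t.condition.regime_id - 1] += 1 - eps
                r = md.decode_trial(t, ms, md.DecodeConfig(prior_over_regimes=prior))
                true = md.normalize_positions(
                    t.positions[md.epoch_slice(t, "movement")], geometry
                )
                dec = md.normalize_positions(r.means, geometry)
                total += np.mean(np.sum((dec - true) ** 2, axis=1))
            mses.append(total / len(tests))
        assert all(mses[i + 1] <= mses[i] + 1e-12 for i in range(len(mses) - 1))

    def test_weights_normalized_and_covs_psd_on_session(self, benchmark_session,
                                                        benchmark_model_set):
        for t in benchmark_session[:10]:
            res = md.decode_trial(t, benchmark_model_set)
            assert np.allclose(res.weights.sum(axis=1), 1.0, atol=1e-9)
            for c in res.covs:
                assert np.linalg.eigvalsh(c).min() >= -1e-10

    def test_credible_interval_width_matches_level(self):
        rng = np.random.default_rng(8)
        model = random_regime_model(rng, 2, 3)
        ms = toy_model_set([model], np.zeros(2), np.eye(2))
        res95 = md.decode_trial(rng.normal(size=(4, 3)), ms,
                                md.DecodeConfig(credible_level=0.95))
        res50 = md.decode_trial(rng.normal(size=(4, 3)), ms,
                                md.DecodeConfig(credible_level=0.50))
        w95 = res95.ci_upper - res95.ci_lower
        w50 = res50.ci_upper - res50.ci_lower
        assert np.all(w95 > w50)
        sd = np.sqrt(np.diagonal(res95.covs, axis1=1, axis2=2))
        assert np.allclose(w95, 2 * 1.959963984540054 * sd, rtol=1e-9)


class TestDecoderEstimator:
    def test_fit_decode_roundtrip(self, small_session):
        dec = md.MixtureTrajectoryDecoder(min_trials=3).fit(small_session)
        assert dec.n_regimes_ == 6
        res = dec.decode(small_session[0])
        n_mov = np.diff(small_session[0].epochs["movement"])[0]
        assert res.means.shape == (n_mov, 2)
        preds = dec.predict(small_session[:2])
        assert len(preds) == 2

    def test_get_set_params(self):
        dec = md.MixtureTrajectoryDecoder()
        assert dec.get_params()["weight_update"] == "likelihood"
        dec.set_params(weight_update="static", credible_level=0.9)
        assert dec.credible_level == 0.9
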