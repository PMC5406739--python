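import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm
from sklearn.naive_bayes import GaussianNB

import mtmdecode as md
from mtmdecode.priors import DelayWindowClassifier, trial_class_label


def classifier_from(mu, var):
    clf = DelayWindowClassifier()
    clf.classes_ = np.arange(len(mu))
    clf.mu_ = np.atleast_2d(np.asarray(mu, float))
    clf.var_ = np.atleast_2d(np.asarray(var, float))
    if clf.mu_.shape[0] == 1:
        clf.mu_, clf.var_ = clf.mu_.T, clf.var_.T
    return clf


class TestWindowFeatures:
    def test_target_window_averages_nine_bins(self, benchmark_session):
        """Rest + delay-1 + first delay-2 bin: 5 + 3 + 1 = 9 bins."""
        t = benchmark_session[0]
        feats = md.extract_window_features(t, "target")
        manual = np.vstack([t.counts[:8], t.counts[8:9]]).mean(axis=0)
        assert np.allclose(feats, manual)

    def test_selection_window_averages_four_bins(self, benchmark_session):
        t = benchmark_session[0]
        feats = md.extract_window_features(t, "selection")
        d2 = t.counts[md.epoch_slice(t, "delay2")]
        assert np.allclose(feats, d2[1:5].mean(axis=0))

    def test_constant_counts_give_constant_feature(self):
        from helpers import make_trial
        trial = make_trial(np.zeros((10, 2)), np.zeros((10, 3)), pre_counts=4.0)
        for which in ("target", "selection"):
            assert np.allclose(md.extract_window_features(trial, which), 4.0)

    def test_unknown_window_rejected(self, benchmark_session):
        with pytest.raises(ValueError):
            md.extract_window_features(benchmark_session[0], "movement")


class TestClassifier:
    def test_equal_likelihoods_give_uniform_posterior(self):
        clf = classifier_from(mu=[[0.0], [0.0], [0.0]], var=[[1.0], [1.0], [1.0]])
        probs = clf.predict_proba([[0.7]])[0]
        assert np.allclose(probs, 1 / 3)

    def test_symmetric_point_is_undecided(self):
        clf = classifier_from(mu=[[0.0], [2.0]], var=[[1.0], [1.0]])
        assert np.allclose(clf.predict_proba([[1.0]])[0], [0.5, 0.5])

    def test_density_ratio_closed_form(self):
        """y=0 under N(0,1) vs N(2,1): posterior e^2 / (1 + e^2)."""
        clf = classifier_from(mu=[[0.0], [2.0]], var=[[1.0], [1.0]])
        p = clf.predict_proba([[0.0]])[0]
        assert p[0] == pytest.approx(np.exp(2) / (1 + np.exp(2)), abs=1e-12)

    def test_zero_variance_class_is_floored(self):
        clf = DelayWindowClassifier().fit([[0.0], [0.0], [2.0], [2.0]], [0, 0, 1, 1])
        assert np.allclose(clf.mu_.ravel(), [0.0, 2.0])
        assert np.allclose(clf.var_, 1e-4)

    def test_underpopulated_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            DelayWindowClassifier().fit([[0.0], [1.0], [1.2]], [0, 1, 1])

    def test_nonfinite_features_rejected(self):
        clf = classifier_from(mu=[[0.0], [1.0]], var=[[1.0], [1.0]])
        with pytest.raises(ValueError, match="finite"):
            clf.predict_proba([[np.nan]])

    def test_log_domain_matches_direct_densities(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            C, n = rng.integers(2, 5), rng.integers(1, 6)
            mu = rng.normal(size=(C, n))
            var = rng.uniform(0.5, 2.0, size=(C, n))
            clf = DelayWindowClassifier()
            clf.classes_, clf.mu_, clf.var_ = np.arange(C), mu, var
            y = rng.normal(size=n)
            direct = np.array([
                np.prod(norm.pdf(y, mu[c], np.sqrt(var[c]))) for c in range(C)
            ])
            direct /= direct.sum()
            assert np.allclose(clf.predict_proba([y])[0], direct, atol=1e-12)

    def test_matches_sklearn_gaussian_nb(self):
        """Independent cross-check against sklearn's Gaussian naive Bayes."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 5)) + np.repeat(rng.normal(size=(3, 5)), 20, axis=0)
        y = np.repeat([0, 1, 2], 20)
        ours = DelayWindowClassifier(var_floor=0.0).fit(X, y)
        ref = GaussianNB(priors=np.full(3, 1 / 3), var_smoothing=1e-15).fit(X, y)
        assert np.allclose(ours.predict_proba(X), ref.predict_proba(X), atol=1e-6)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_posterior_normalized_for_arbitrary_features(self, seed):
        rng = np.random.default_rng(seed)
        clf = classifier_from(
            mu=rng.normal(size=(3, 4), scale=5),
            var=rng.uniform(1e-4, 10, size=(3, 4)),
        )
        probs = clf.predict_proba(rng.normal(size=(5, 4), scale=20))
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)


class TestCombine:
    def test_uniform_times_uniform_is_uniform(self, geometry):
        cat = md.build_regime_catalogue(geometry, start_label="bottom")
        combined = md.combine_priors(np.full(3, 1 / 3), np.full(2, 0.5), cat)
        assert np.allclose(combined, 1 / 6)

    def test_products_map_through_catalogue(self, geometry):
        cat = md.build_regime_catalogue(geometry, start_label="bottom")
        tp = np.array([0.6, 0.3, 0.1])  # targets: left, top, right
        sp = np.array([0.7, 0.3])  # openings: clockwise, counterclockwise
        combined = md.combine_priors(tp, sp, cat)
        assert np.allclose(sorted(combined, reverse=True),
                           [0.42, 0.21, 0.18, 0.09, 0.07, 0.03])
        assert combined.sum() == pytest.approx(1.0)
        for c in cat:
            t_idx = ["left", "top", "right"].index(c.target_label)
            o_idx = ["clockwise", "counterclockwise"].index(c.opening_side)
            assert combined[c.regime_id - 1] == pytest.approx(tp[t_idx] * sp[o_idx])

    def test_delta_times_delta_is_delta(self, geometry):
        cat = md.build_regime_catalogue(geometry, start_label="bottom")
        combined = md.combine_priors([0, 1, 0], [1, 0], cat)
        assert combined.sum() == pytest.approx(1.0)
        assert np.count_nonzero(combined) == 1

    def test_expand_target_prior_splits_openings_evenly(self, geometry):
        cat = md.build_regime_catalogue(geometry, start_label="bottom")
        expanded = md.expand_target_prior([0.8, 0.1, 0.1], cat)
        assert expanded.sum() == pytest.approx(1.0)
        assert np.isclose(expanded.max(), 0.4)

    def test_broken_catalogue_rejected(self, geometry):
        cat = md.build_regime_catalogue(geometry, start_label="bottom")
        broken = [md.Condition(c.start_label, c.target_label, c.opening_side, 1)
                  for c in cat]
        with pytest.raises(ValueError, match="bijection"):
            md.combine_priors(np.full(3, 1 / 3), np.full(2, 0.5), broken)


class TestLoocv:
    def test_null_labels_give_chance_level(self):
        """Label-permuted data: expectation at chance, t-test non-significant."""
        rng = np.random.default_rng(0)
        trials = md.generate_benchmark_session(seed=2, n_trials=200, n_units=15)
        for which, chance in (("target", 1 / 3), ("selection", 1 / 2)):
            labels = [trial_class_label(t, which) for t in trials]
            permuted = list(rng.permutation(labels))
            res = md.loocv_expectation(trials, which, labels=permuted)
            se = res.sd / np.sqrt(len(trials))
            assert abs(res.mean - chance) < 3 * se
            assert res.p_value > 0.05

    def test_separated_classes_score_high(self):
        trials = md.generate_benchmark_session(
            seed=3, n_trials=120, n_units=20,
            delay1_gain=40.0, delay2_select_gain=25.0, delay2_target_gain=0.0,
        )
        res = md.loocv_expectation(trials, "target")
        assert res.mean > 0.9
        assert res.p_value < 1e-6
        # the two openings separate cleanly within a single target
        top = [t for t in trials if t.condition.target_label == "top"]
        res = md.loocv_expectation(top, "selection")
        assert res.mean > 0.9
        assert res.p_value < 1e-6

    def test_expectations_bounded(self, small_session):
        res = md.loocv_expectation(small_session, "selection")
        assert np.all(res.expectations >= 0) and np.all(res.expectations <= 1)
        assert 0 <= res.accuracy <= 1

    def test_separation_sweep_is_monotone(self):
        """Mean LOOCV expectation never drops as class separation grows."""
        means = []
        for gain in (0.0, 4.0, 8.0, 16.0):
            trials = md.generate_benchmark_session(
                seed=4, n_trials=96, n_units=12, delay1_gain=gain
            )
            means.append(md.loocv_expectation(trials, "target").mean)
        assert all(means[i + 1] >= means[i] - 1e-12 for i in range(len(means) - 1))
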