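"""Decoding target direction and intended movement selection from delay activity.

During the delay epochs the upcoming movement is already encoded in the
premotor population: target direction during delay 1 (target visible) and
the clockwise/counterclockwise path choice during delay 2 (obstacle
visible).  Both are decoded with a per-unit Gaussian Bayes classifier:
unit rates are modelled as independent Gaussians per class,

    y | m  ~  prod_i N(y_i ; mu_im, sigma2_im),

with class-conditional means and ML variances estimated from training
trials, a uniform class prior (the task presents classes equally often),
and the posterior computed in the log domain.

Features are per-unit mean counts over a fixed window:

* target window    — the rest and delay-1 bins plus the first delay-2 bin
  (0-900 ms of the trial: 5 + 3 + 1 = 9 bins at the default epoch
  lengths; the extra delay-2 bin absorbs the causal response delay);
* selection window — delay-2 bins 2-5 (100-500 ms after obstacle onset,
  4 bins).

The two posteriors combine under independence,
P(m | y) = P(m1 | y1) P(m2 | y2), into a prior over the six movement
regimes for the trajectory decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin

from .synthetic import Trial, epoch_slice
from .task import CANONICAL_POSITIONS, OPENING_SIDES, Condition

__all__ = [
    "extract_window_features",
    "DelayWindowClassifier",
    "PriorModel",
    "PriorEstimate",
    "fit_prior_model",
    "classify",
    "combine_priors",
    "expand_target_prior",
    "loocv_expectation",
    "LoocvResult",
    "trial_class_label",
]

WINDOWS = ("target", "selection")


def extract_window_features(trial: Trial, which: str) -> np.ndarray:
    """Per-unit mean count over the decoding window of one trial."""
    if which not in WINDOWS:
        raise ValueError(f"unknown window {which!r}")
    if which == "target":
        rest = trial.counts[epoch_slice(trial, "rest")]
        d1 = trial.counts[epoch_slice(trial, "delay1")]
        d2 = trial.counts[epoch_slice(trial, "delay2")]
        if d2.shape[0] < 1:
            raise ValueError("target window needs at least one delay-2 bin")
        window = np.vstack([rest, d1, d2[:1]])
    else:
        d2 = trial.counts[epoch_slice(trial, "delay2")]
        if d2.shape[0] < 5:
            raise ValueError("selection window needs delay-2 bins 2-5")
        window = d2[1:5]
    return np.asarray(window, dtype=float).mean(axis=0)


def trial_class_label(trial: Trial, which: str) -> str:
    """Class label of a trial for the given window (target or opening)."""
    if trial.condition is None:
        raise ValueError("trial has no condition labels")
    if which == "target":
        return trial.condition.target_label
    return trial.condition.opening_side


class DelayWindowClassifier(BaseEstimator, ClassifierMixin):
    """Per-unit Gaussian Bayes classifier for delay-window rate features.

    Equivalent to Gaussian naive Bayes with a uniform class prior (unless
    ``class_prior`` is given) and a variance floor for silent units; the
    posterior is computed in the log domain.

    Attributes
    ----------
    classes_ : ndarray of class labels.
    mu_ : (n_classes, n_units) class-conditional means.
    var_ : (n_classes, n_units) class-conditional ML variances (floored).
    """

    def __init__(self, var_floor: float = 1e-4, class_prior: np.ndarray | None = None):
        self.var_floor = var_floor
        self.class_prior = class_prior

    def fit(self, X: np.ndarray, y) -> "DelayWindowClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be (trials x units)")
        self.classes_, idx = np.unique(y, return_inverse=True)
        counts = np.bincount(idx)
        if counts.min() < 2:
            few = self.classes_[counts < 2]
            raise ValueError(f"classes with fewer than 2 trials: {list(few)}")
        C, n = len(self.classes_), X.shape[1]
        self.mu_ = np.empty((C, n))
        self.var_ = np.empty((C, n))
        for c in range(C):
            Xc = X[idx == c]
            self.mu_[c] = Xc.mean(axis=0)
            self.var_[c] = np.maximum(Xc.var(axis=0), self.var_floor)
        return self

    def _log_prior(self) -> np.ndarray:
        C = len(self.classes_)
        if self.class_prior is None:
            return np.full(C, -np.log(C))
        p = np.asarray(self.class_prior, dtype=float)
        if p.shape != (C,) or not np.isclose(p.sum(), 1.0):
            raise ValueError("class_prior must be a probability vector over classes")
        with np.errstate(divide="ignore"):
            return np.log(p)

    def predict_log_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        # log prod_i N(y_i; mu, var), vectorised over classes
        ll = -0.5 * (
            np.log(2 * np.pi * self.var_).sum(axis=1)[None, :]
            + (((X[:, None, :] - self.mu_[None]) ** 2) / self.var_[None]).sum(axis=2)
        )
        logpost = ll + self._log_prior()[None, :]
        logpost -= logpost.max(axis=1, keepdims=True)
        logpost -= np.log(np.exp(logpost).sum(axis=1, keepdims=True))
        return logpost

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X: np.ndarray):
        return self.classes_[np.argmax(self.predict_log_proba(X), axis=1)]


@dataclass
class PriorModel:
    """Fitted Gaussian parameters of one delay-window decoder."""

    classes: list
    mu: np.ndarray  # (units x classes)
    sigma2: np.ndarray  # (units x classes)
    window: str

    def to_classifier(self) -> DelayWindowClassifier:
        clf = DelayWindowClassifier()
        clf.classes_ = np.asarray(self.classes)
        clf.mu_ = self.mu.T.copy()
        clf.var_ = self.sigma2.T.copy()
        return clf


@dataclass
class PriorEstimate:
    """Decoded regime prior of one trial."""

    target_probs: np.ndarray
    selection_probs: np.ndarray
    combined: np.ndarray
    target_classes: list
    selection_classes: list


def fit_prior_model(
    trials: list[Trial],
    which: str,
    labels: list | None = None,
    var_floor: float = 1e-4,
) -> PriorModel:
    """Fit the Gaussian window decoder on labelled trials."""
    X = np.array([extract_window_features(t, which) for t in trials])
    if labels is None:
        labels = [trial_class_label(t, which) for t in trials]
    clf = DelayWindowClassifier(var_floor=var_floor).fit(X, labels)
    return PriorModel(
        classes=list(clf.classes_), mu=clf.mu_.T, sigma2=clf.var_.T, window=which
    )


def classify(
    features: np.ndarray,
    model: PriorModel,
    class_prior: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior class probabilities for one feature vector."""
    clf = model.to_classifier()
    clf.class_prior = class_prior
    return clf.predict_proba(features)[0]


def _ordered_targets(start_label: str) -> list[str]:
    return [p for p in CANONICAL_POSITIONS if p != start_label]


def combine_priors(
    target_probs: np.ndarray,
    selection_probs: np.ndarray,
    catalogue: list[Condition],
    target_classes: list[str] | None = None,
    selection_classes: list[str] | None = None,
) -> np.ndarray:
    """Product prior over regimes: P(m) = P(target) * P(opening).

    ``catalogue`` is the 6-condition catalogue of one start position; the
    returned vector is ordered by regime_id.  Raises if the catalogue's
    (target, opening) -> regime_id map is not a bijection.
    """
    starts = {c.start_label for c in catalogue}
    if len(starts) != 1:
        raise ValueError("catalogue must cover exactly one start position")
    start = starts.pop()
    if target_classes is None:
        target_classes = _ordered_targets(start)
    if selection_classes is None:
        selection_classes = list(OPENING_SIDES)
    target_probs = np.asarray(target_probs, dtype=float)
    selection_probs = np.asarray(selection_probs, dtype=float)
    pairs = {(c.target_label, c.opening_side): c.regime_id for c in catalogue}
    ids = sorted(pairs.values())
    if len(pairs) != len(catalogue) or ids != list(range(1, len(catalogue) + 1)):
        raise ValueError("catalogue is not a bijection of (target, opening) onto 1..M")
    combined = np.empty(len(catalogue))
    for (tgt, opening), rid in pairs.items():
        combined[rid - 1] = (
            target_probs[target_classes.index(tgt)]
            * selection_probs[selection_classes.index(opening)]
        )
    return combined


def expand_target_prior(
    target_probs: np.ndarray,
    catalogue: list[Condition],
    target_classes: list[str] | None = None,
) -> np.ndarray:
    """Spread a 3-class target prior over 6 regimes (openings split equally)."""
    n_open = len(OPENING_SIDES)
    uniform_sel = np.full(n_open, 1.0 / n_open)
    return combine_priors(target_probs, uniform_sel, catalogue, target_classes)


def estimate_regime_prior(
    trial: Trial,
    target_model: PriorModel,
    selection_model: PriorModel,
    catalogue: list[Condition],
) -> PriorEstimate:
    """Decode both delay windows of one trial and combine into a regime prior."""
    tp = classify(extract_window_features(trial, "target"), target_model)
    sp = classify(extract_window_features(trial, "selection"), selection_model)
    combined = combine_priors(
        tp, sp, catalogue, list(target_model.classes), list(selection_model.classes)
    )
    return PriorEstimate(
        target_probs=tp,
        selection_probs=sp,
        combined=combined,
        target_classes=list(target_model.classes),
        selection_classes=list(selection_model.classes),
    )


@dataclass
class LoocvResult:
    """Leave-one-out expectations of a delay-window decoder.

    ``expectations[i]`` is the posterior probability assigned to the true
    class of held-out trial i; ``accuracy`` the hard-classification rate;
    ``p_value`` a one-sample two-sided t-test of the expectations against
    the chance level (1/n_classes).
    """

    expectations: np.ndarray
    predictions: list
    true_labels: list
    chance: float
    mean: float
    sd: float
    t_stat: float
    p_value: float

    @property
    def accuracy(self) -> float:
        return float(
            np.mean([p == t for p, t in zip(self.predictions, self.true_labels)])
        )


def loocv_expectation(
    trials: list[Trial],
    which: str,
    labels: list | None = None,
    var_floor: float = 1e-4,
) -> LoocvResult:
    """Leave-one-out posterior expectation of the true class.

    For each trial the classifier is refitted on all other trials and the
    posterior probability of the held-out trial's true class recorded —
    the "expectation of selecting the right class".  Chance is 1/3 for the
    target window and 1/2 for the selection window.
    """
    X = np.array([extract_window_features(t, which) for t in trials])
    if labels is None:
        labels = [trial_class_label(t, which) for t in trials]
    labels = np.asarray(labels)
    classes = np.unique(labels)
    chance = 1.0 / len(classes)
    n = len(trials)
    expectations = np.empty(n)
    predictions = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = DelayWindowClassifier(var_floor=var_floor).fit(X[mask], labels[mask])
        probs = clf.predict_proba(X[i])[0]
        k = list(clf.classes_).index(labels[i])
        expectations[i] = probs[k]
        predictions.append(clf.classes_[np.argmax(probs)])
        mask[i] = True
    t_stat, p_value = stats.ttest_1samp(expectations, chance)
    return LoocvResult(
        expectations=expectations,
        predictions=predictions,
        true_labels=list(labels),
        chance=chance,
        mean=float(expectations.mean()),
        sd=float(expectations.std(ddof=1)),
        t_stat=float(t_stat),
        p_value=float(p_value),
    )
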