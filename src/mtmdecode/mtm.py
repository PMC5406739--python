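"""Recursive Bayesian trajectory decoding under a mixture of trajectory models.

The posterior over hand position given all spike counts so far is a
mixture over movement regimes,

    P(x_t | y_1..t) = sum_m P(x_t | y_1..t, m) P(m | y_1..t),

where each regime-conditional posterior is propagated by the usual
Gaussian predict/update recursion under that regime's linear-Gaussian
model (so it is an exact Kalman filter), and the regime weights combine a
prior P(m) — uniform, or supplied by the delay-period decoders — with the
accumulated marginal likelihood P(y_1..t | m) of each regime's filter.

Weights, being products of many small per-bin likelihoods over ~40 units,
are accumulated in the log domain and normalised after max-subtraction.
Decoding is causal (forward filtering only).  The collapsed mixture mean
and covariance are the exact mixture moments; per-coordinate credible
intervals are read off the collapsed covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .regime import ModelSet, RegimeModel, TrajectoryModelSet
from .synthetic import Trial, epoch_slice

__all__ = [
    "RegimePosterior",
    "MixturePosterior",
    "DecodeConfig",
    "DecodeResult",
    "predict_step",
    "update_step",
    "collapse_mixture",
    "decode_trial",
    "MixtureTrajectoryDecoder",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class RegimePosterior:
    """Gaussian state posterior of one regime's filter at one bin."""

    mean: np.ndarray
    cov: np.ndarray
    log_likelihood_increment: float = 0.0


@dataclass
class MixturePosterior:
    """Mixture posterior over hand position at one bin."""

    per_regime: dict
    weights: dict
    collapsed_mean: np.ndarray
    collapsed_cov: np.ndarray


@dataclass
class DecodeConfig:
    """Decoding options: regime prior, weight update rule, credible level.

    ``prior_over_regimes=None`` means uniform.  ``weight_update`` is
    "likelihood" (weights proportional to P(y_1..t | m) P(m), updated each
    bin) or "static" (weights pinned at the prior throughout).
    """

    prior_over_regimes: np.ndarray | None = None
    weight_update: str = "likelihood"
    credible_level: float = 0.95

    def __post_init__(self) -> None:
        if self.weight_update not in ("likelihood", "static"):
            raise ValueError("weight_update must be 'likelihood' or 'static'")
        if not 0.0 < self.credible_level < 1.0:
            raise ValueError("credible_level must be in (0, 1)")
        if self.prior_over_regimes is not None:
            p = np.asarray(self.prior_over_regimes, dtype=float)
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
                raise ValueError("prior_over_regimes must be a probability vector")
            self.prior_over_regimes = p


def _symmetrize(S: np.ndarray) -> np.ndarray:
    return (S + S.T) / 2.0


def predict_step(post: RegimePosterior, model: RegimeModel) -> RegimePosterior:
    """One-step-ahead prediction: propagate the Gaussian through the dynamics."""
    mean = model.A @ post.mean + model.b
    cov = _symmetrize(model.A @ post.cov @ model.A.T + model.Q)
    return RegimePosterior(mean=mean, cov=cov)


def update_step(
    pred: RegimePosterior, y: np.ndarray, model: RegimeModel
) -> RegimePosterior:
    """Condition the predicted Gaussian on one bin of spike counts.

    Standard Kalman measurement update (Joseph-form covariance), plus the
    log innovation likelihood log N(y; H mu + p, H P H' + V), which is the
    per-bin increment of log P(y_1..t | m).
    """
    y = np.asarray(y, dtype=float)
    H, p, V = model.H, model.p, model.V
    P = pred.cov
    S = _symmetrize(H @ P @ H.T + V)
    try:
        chol = sla.cho_factor(S, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular innovation covariance") from exc
    resid = y - (H @ pred.mean + p)
    alpha = sla.cho_solve(chol, resid)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    loglik = -0.5 * (y.size * _LOG2PI + logdet + resid @ alpha)
    K = P @ H.T @ sla.cho_solve(chol, np.eye(S.shape[0]))
    mean = pred.mean + K @ resid
    IKH = np.eye(P.shape[0]) - K @ H
    cov = _symmetrize(IKH @ P @ IKH.T + K @ V @ K.T)
    return RegimePosterior(mean=mean, cov=cov, log_likelihood_increment=float(loglik))


def collapse_mixture(
    per_regime: list[RegimePosterior], weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact mean and covariance of a Gaussian mixture."""
    w = np.asarray(weights, dtype=float)
    means = np.array([p.mean for p in per_regime])
    mean = w @ means
    d = means.shape[1]
    cov = np.zeros((d, d))
    for wi, post in zip(w, per_regime):
        dm = post.mean - mean
        cov += wi * (post.cov + np.outer(dm, dm))
    return mean, _symmetrize(cov)


@dataclass
class DecodeResult:
    """Decoded movement-epoch trajectory of one trial.

    ``posteriors[t]`` is the full mixture posterior at movement bin t;
    ``means``/``covs``/``weights`` are the same as arrays, and
    ``ci_lower``/``ci_upper`` the per-coordinate credible band at the
    configured level.
    """

    posteriors: list[MixturePosterior]
    keys: list[tuple]
    credible_level: float
    means: np.ndarray = field(init=False)
    covs: np.ndarray = field(init=False)
    weights: np.ndarray = field(init=False)
    ci_lower: np.ndarray = field(init=False)
    ci_upper: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.means = np.array([p.collapsed_mean for p in self.posteriors])
        self.covs = np.array([p.collapsed_cov for p in self.posteriors])
        self.weights = np.array(
            [[p.weights[k] for k in self.keys] for p in self.posteriors]
        )
        z = norm.ppf(0.5 + self.credible_level / 2.0)
        sd = np.sqrt(np.maximum(np.diagonal(self.covs, axis1=1, axis2=2), 0.0))
        self.ci_lower = self.means - z * sd
        self.ci_upper = self.means + z * sd


def _movement_counts(trial) -> np.ndarray:
    if isinstance(trial, Trial):
        counts = np.asarray(trial.counts[epoch_slice(trial, "movement")], dtype=float)
        if counts.shape[0] == 0:
            raise ValueError("trial has no movement-epoch bins")
        return counts
    return np.asarray(trial, dtype=float)


def decode_trial(
    trial,
    model_set: ModelSet,
    config: DecodeConfig | None = None,
) -> DecodeResult:
    """Decode one trial's movement-epoch trajectory under the mixture model.

    ``trial`` may be a :class:`Trial` (its movement-epoch counts are used)
    or a raw (T x n_units) count matrix.  Runs M regime filters in
    parallel from the model set's initial state and mixes them with the
    configured prior and weight-update rule.
    """
    if config is None:
        config = DecodeConfig()
    counts = _movement_counts(trial)
    M = model_set.M
    prior = config.prior_over_regimes
    if prior is None:
        prior = np.full(M, 1.0 / M)
    if prior.shape != (M,):
        raise ValueError(f"prior has length {prior.shape[0]}, model set has M={M}")

    models = model_set.ordered_models()
    posts = [
        RegimePosterior(model_set.initial_mean.copy(), model_set.initial_cov.copy())
        for _ in range(M)
    ]
    with np.errstate(divide="ignore"):
        log_w = np.log(prior)
    out = []
    for y in counts:
        new_posts = []
        increments = np.empty(M)
        for j, (post, model) in enumerate(zip(posts, models)):
            pred = predict_step(post, model)
            upd = update_step(pred, y, model)
            increments[j] = upd.log_likelihood_increment
            new_posts.append(upd)
        posts = new_posts
        if config.weight_update == "likelihood":
            log_w = log_w + increments
            shifted = log_w - log_w.max()
            weights = np.exp(shifted)
            weights /= weights.sum()
        else:
            weights = prior
        mean, cov = collapse_mixture(posts, weights)
        out.append(
            MixturePosterior(
                per_regime={k: p for k, p in zip(model_set.keys, posts)},
                weights={k: float(w) for k, w in zip(model_set.keys, weights)},
                collapsed_mean=mean,
                collapsed_cov=cov,
            )
        )
    return DecodeResult(
        posteriors=out, keys=list(model_set.keys), credible_level=config.credible_level
    )


class MixtureTrajectoryDecoder(BaseEstimator):
    """Mixture-of-trajectory-models decoder as a scikit-learn estimator.

    ``fit`` learns one linear-Gaussian state-space model per movement
    regime from labelled training trials; ``decode``/``predict`` run the
    recursive Bayesian mixture filter on test trials, optionally with a
    regime prior decoded from delay-period activity.

    Parameters
    ----------
    keying : {"target_and_opening", "target_only"}
        Regime granularity (M=6 or M=3 per start position).
    weight_update : {"likelihood", "static"}
        Whether mixture weights track the accumulated regime likelihoods
        (default) or stay pinned at the prior.
    credible_level : float
        Level of the reported per-coordinate credible intervals.
    min_trials, var_floor, diagonal_v
        Passed to the regime-model fitter.
    """

    def __init__(
        self,
        keying: str = "target_and_opening",
        weight_update: str = "likelihood",
        credible_level: float = 0.95,
        min_trials: int = 5,
        var_floor: float = 1e-6,
        diagonal_v: bool = True,
    ):
        self.keying = keying
        self.weight_update = weight_update
        self.credible_level = credible_level
        self.min_trials = min_trials
        self.var_floor = var_floor
        self.diagonal_v = diagonal_v

    def fit(self, trials: list[Trial], y=None) -> "MixtureTrajectoryDecoder":
        fitter = TrajectoryModelSet(
            keying=self.keying,
            min_trials=self.min_trials,
            var_floor=self.var_floor,
            diagonal_v=self.diagonal_v,
        ).fit(trials)
        self.model_set_ = fitter.model_set_
        self.n_regimes_ = fitter.n_regimes_
        self.n_units_ = fitter.n_units_
        return self

    def decode(self, trial, prior: np.ndarray | None = None) -> DecodeResult:
        config = DecodeConfig(
            prior_over_regimes=prior,
            weight_update=self.weight_update,
            credible_level=self.credible_level,
        )
        return decode_trial(trial, self.model_set_, config)

    def predict(self, trials, priors=None) -> list[np.ndarray]:
        """Decoded mean trajectories for a list of trials."""
        if priors is None:
            priors = [None] * len(trials)
        return [self.decode(t, p).means for t, p in zip(trials, priors)]
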