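"""Per-regime linear-Gaussian state-space models fitted from labelled trials.

Each movement regime m (a (target, obstacle-opening) pair, or a target
alone) gets its own model

    x_t | x_{t-1}, m  ~  N(A_m x_{t-1} + b_m, Q_m)          (state / kinematics)
    y_t | x_t, m      ~  N(H_m x_t + p_m, V_m)              (observation / counts)

with x_t the 2D hand position (cm) and y_t the n-unit spike-count vector
in one 100 ms bin.  All parameters are fitted by least squares on the
movement-epoch bins of the training trials and held fixed at test time.

The state dynamics are parameterised as a perturbation of a random walk:
the position increment x_t - x_{t-1} is regressed on [x_{t-1}, 1], and
A_m = I + slope.  At full rank this is identical to regressing x_t on
x_{t-1}; when the design is rank-deficient (e.g. constant positions) the
minimum-norm pseudo-inverse solution is the random walk A = I, b = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np
from sklearn.base import BaseEstimator

from .synthetic import Trial, epoch_slice
from .task import CANONICAL_POSITIONS, OPENING_SIDES

__all__ = [
    "RegimeModel",
    "ModelSet",
    "fit_state_model",
    "fit_observation_model",
    "fit_model_set",
    "TrajectoryModelSet",
]


@dataclass
class RegimeModel:
    """Linear-Gaussian state-space parameters of one movement regime."""

    key: tuple
    A: np.ndarray
    b: np.ndarray
    Q: np.ndarray
    H: np.ndarray
    p: np.ndarray
    V: np.ndarray

    @property
    def n_units(self) -> int:
        return self.H.shape[0]

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]


@dataclass
class ModelSet:
    """An ordered collection of regime models plus the shared initial state.

    ``keys`` fixes the regime order used for prior vectors and mixture
    weights; ``initial_mean``/``initial_cov`` describe x_0 (empirical
    moments of movement-onset positions in training).
    """

    keys: list[tuple]
    models: dict[tuple, RegimeModel]
    initial_mean: np.ndarray
    initial_cov: np.ndarray
    keying: str = "target_and_opening"

    @property
    def M(self) -> int:
        return len(self.keys)

    @property
    def n_units(self) -> int:
        return next(iter(self.models.values())).n_units

    def ordered_models(self) -> list[RegimeModel]:
        return [self.models[k] for k in self.keys]

    def to_json(self, path) -> None:
        payload = {
            "keying": self.keying,
            "keys": [list(k) for k in self.keys],
            "initial_mean": self.initial_mean.tolist(),
            "initial_cov": self.initial_cov.tolist(),
            "models": {
                "|".join(map(str, k)): {
                    name: getattr(self.models[k], name).tolist()
                    for name in ("A", "b", "Q", "H", "p", "V")
                }
                for k in self.keys
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ModelSet":
        with open(path) as fh:
            payload = json.load(fh)
        keys = [tuple(k) for k in payload["keys"]]
        models = {}
        for k in keys:
            raw = payload["models"]["|".join(map(str, k))]
            models[k] = RegimeModel(
                key=k, **{name: np.asarray(raw[name], dtype=float) for name in raw}
            )
        return cls(
            keys=keys,
            models=models,
            initial_mean=np.asarray(payload["initial_mean"], dtype=float),
            initial_cov=np.asarray(payload["initial_cov"], dtype=float),
            keying=payload["keying"],
        )


def _symmetrize(S: np.ndarray) -> np.ndarray:
    return (S + S.T) / 2.0


def _movement_xy(trials: list[Trial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack movement-epoch (x_{t-1}, x_t) pairs and (x_t, y_t) rows."""
    prev, curr, counts, states = [], [], [], []
    for trial in trials:
        sl = epoch_slice(trial, "movement")
        pos = np.asarray(trial.positions[sl], dtype=float)
        cnt = np.asarray(trial.counts[sl], dtype=float)
        if pos.shape[0] >= 2:
            prev.append(pos[:-1])
            curr.append(pos[1:])
        states.append(pos)
        counts.append(cnt)
    if not states:
        raise ValueError("no movement-epoch bins in the provided trials")
    prev_a = np.concatenate(prev) if prev else np.empty((0, 2))
    curr_a = np.concatenate(curr) if curr else np.empty((0, 2))
    return prev_a, curr_a, (np.concatenate(states), np.concatenate(counts))


def fit_state_model(trials: list[Trial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit (A, b, Q) of the state dynamics from movement-epoch transitions.

    Least squares over all consecutive movement-epoch position pairs, in
    increment form (see module docstring); Q is the maximum-likelihood
    residual covariance, symmetrised.
    """
    prev, curr, _ = _movement_xy(trials)
    if prev.shape[0] < 4:
        raise ValueError(
            f"underdetermined state fit: {prev.shape[0]} transition pairs (< 4)"
        )
    design = np.column_stack([prev, np.ones(prev.shape[0])])
    W, *_ = np.linalg.lstsq(design, curr - prev, rcond=None)
    A = np.eye(2) + W[:2].T
    b = W[2]
    resid = curr - (prev @ A.T + b)
    Q = _symmetrize(resid.T @ resid / resid.shape[0])
    return A, b, Q


def fit_observation_model(
    trials: list[Trial],
    var_floor: float = 1e-6,
    diagonal_v: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit (H, p, V) of the observation model from movement-epoch bins.

    Per-unit least squares of counts on position with intercept.  V is the
    maximum-likelihood residual covariance: diagonal by default (unit noise
    treated as independent, consistent with the delay-epoch model; a full
    covariance with ~40 units and ~50 trials per regime is ill-conditioned),
    with diagonal entries floored at ``var_floor`` so silent units cannot
    produce a degenerate density.
    """
    _, _, (states, counts) = _movement_xy(trials)
    if states.shape[0] < 3:
        raise ValueError("need at least 3 movement-epoch bins to fit observations")
    design = np.column_stack([states, np.ones(states.shape[0])])
    W, *_ = np.linalg.lstsq(design, counts, rcond=None)
    H = W[:2].T
    p = W[2]
    resid = counts - design @ W
    if diagonal_v:
        V = np.diag(np.maximum(resid.var(axis=0), var_floor))
    else:
        V = _symmetrize(resid.T @ resid / resid.shape[0])
        V[np.diag_indices_from(V)] = np.maximum(np.diag(V), var_floor)
    return H, p, V


def _regime_key(trial: Trial, keying: str) -> tuple:
    cond = trial.condition
    if cond is None:
        raise ValueError("trial without condition labels cannot be used for fitting")
    if keying == "target_and_opening":
        return (cond.start_label, cond.target_label, cond.opening_side)
    if keying == "target_only":
        return (cond.start_label, cond.target_label)
    raise ValueError(f"unknown keying {keying!r}")


def _catalogue_keys(start_labels: list[str], keying: str) -> list[tuple]:
    keys = []
    for start in start_labels:
        for tgt in [p for p in CANONICAL_POSITIONS if p != start]:
            if keying == "target_only":
                keys.append((start, tgt))
            else:
                for opening in OPENING_SIDES:
                    keys.append((start, tgt, opening))
    return keys


def fit_model_set(
    trials: list[Trial],
    keying: str = "target_and_opening",
    min_trials: int = 5,
    var_floor: float = 1e-6,
    diagonal_v: bool = True,
) -> ModelSet:
    """Fit one regime model per (start, target[, opening]) present in a session.

    With a single start position this yields M=6 regimes under
    ``target_and_opening`` keying and M=3 under ``target_only``.  Raises a
    ValueError naming any regime of the catalogue that has no (or too few)
    trials.
    """
    groups: dict[tuple, list[Trial]] = {}
    for trial in trials:
        groups.setdefault(_regime_key(trial, keying), []).append(trial)
    start_labels = sorted(
        {t.condition.start_label for t in trials if t.condition is not None},
        key=CANONICAL_POSITIONS.index,
    )
    if not start_labels:
        raise ValueError("no labelled trials to fit")
    keys = _catalogue_keys(start_labels, keying)
    missing = [k for k in keys if len(groups.get(k, [])) < min_trials]
    if missing:
        raise ValueError(
            f"regimes with fewer than {min_trials} trials: {missing}"
        )
    models = {}
    for key in keys:
        A, b, Q = fit_state_model(groups[key])
        H, p, V = fit_observation_model(groups[key], var_floor, diagonal_v)
        models[key] = RegimeModel(key=key, A=A, b=b, Q=Q, H=H, p=p, V=V)
    onsets = np.array(
        [t.positions[epoch_slice(t, "movement")][0] for t in trials if t.condition is not None]
    )
    initial_mean = onsets.mean(axis=0)
    initial_cov = _symmetrize(np.cov(onsets.T, bias=True)) + var_floor * np.eye(2)
    return ModelSet(
        keys=keys,
        models=models,
        initial_mean=initial_mean,
        initial_cov=initial_cov,
        keying=keying,
    )


class TrajectoryModelSet(BaseEstimator):
    """scikit-learn style estimator wrapping :func:`fit_model_set`.

    Parameters
    ----------
    keying : {"target_and_opening", "target_only"}
        Whether regimes distinguish the obstacle opening (M=6 per start)
        or only the target direction (M=3 per start).
    min_trials : int
        Minimum trials per regime required to fit.
    var_floor : float
        Floor on observation-noise variances (silent units).
    diagonal_v : bool
        Fit V as a diagonal covariance (default) or full.

    Attributes
    ----------
    model_set_ : ModelSet
        The fitted collection of regime models.
    """

    def __init__(
        self,
        keying: str = "target_and_opening",
        min_trials: int = 5,
        var_floor: float = 1e-6,
        diagonal_v: bool = True,
    ):
        self.keying = keying
        self.min_trials = min_trials
        self.var_floor = var_floor
        self.diagonal_v = diagonal_v

    def fit(self, trials: list[Trial], y=None) -> "TrajectoryModelSet":
        self.model_set_ = fit_model_set(
            trials,
            keying=self.keying,
            min_trials=self.min_trials,
            var_floor=self.var_floor,
            diagonal_v=self.diagonal_v,
        )
        self.n_regimes_ = self.model_set_.M
        self.n_units_ = self.model_set_.n_units
        return self
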