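"""Scoring decoded trajectories and comparing prior-knowledge conditions.

Decoded movement trajectories are scored against the recorded ones by

* CC  — Pearson correlation per coordinate, averaged over x and y;
* MSE — mean squared Euclidean error per bin, computed by default on
  workspace coordinates normalised to [0, 1] per axis so sessions are
  comparable;
* success — the decoded path must clear the obstacle rectangle (no
  segment between consecutive decoded points intersects it) and its final
  point must land within the target radius.

``compare_decoders`` reproduces the three-decoder comparison: the mixture
decoder is run with (1) no prior knowledge (uniform regime prior),
(2) the decoded target direction only, and (3) both target direction and
intended movement selection.  Priors and models are trained leave-one-out
so every trial is scored out-of-sample, and conditions are compared with
paired t-tests and percentage changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from shapely.geometry import LineString, Point, box

from .mtm import DecodeConfig, decode_trial
from .priors import (
    DelayWindowClassifier,
    combine_priors,
    expand_target_prior,
    extract_window_features,
    trial_class_label,
)
from .regime import fit_model_set
from .synthetic import Trial, epoch_slice
from .task import Condition, TaskGeometry, build_regime_catalogue

__all__ = [
    "trajectory_cc_mse",
    "success_check",
    "paired_ttest",
    "compare_decoders",
    "TrialResult",
    "SessionSummary",
    "normalize_positions",
    "DECODER_CONDITIONS",
]

DECODER_CONDITIONS = ("none", "target", "both")


def normalize_positions(positions: np.ndarray, geometry: TaskGeometry) -> np.ndarray:
    """Map workspace coordinates (cm) to the unit square per axis."""
    extent = np.asarray(geometry.workspace_extent, dtype=float)
    return (np.asarray(positions, dtype=float) + extent / 2.0) / extent


def trajectory_cc_mse(
    decoded: np.ndarray, true: np.ndarray
) -> tuple[float, float]:
    """Mean per-coordinate Pearson CC and per-bin mean squared error.

    A coordinate with zero variance in the true trajectory has no defined
    correlation; it is excluded from the CC average with a warning.  The
    MSE is computed on the coordinates as given (normalise beforehand for
    the unit-square convention).
    """
    decoded = np.asarray(decoded, dtype=float)
    true = np.asarray(true, dtype=float)
    if decoded.shape != true.shape or decoded.shape[0] < 3:
        raise ValueError("trajectories must have equal shape and at least 3 bins")
    ccs = []
    for k in range(true.shape[1]):
        if np.var(true[:, k]) == 0 or np.var(decoded[:, k]) == 0:
            warnings.warn(
                f"coordinate {k} has zero variance; excluded from CC", stacklevel=2
            )
            continue
        ccs.append(stats.pearsonr(decoded[:, k], true[:, k]).statistic)
    cc_mean = float(np.mean(ccs)) if ccs else float("nan")
    mse = float(np.mean(np.sum((decoded - true) ** 2, axis=1)))
    return cc_mean, mse


def success_check(
    decoded: np.ndarray, geometry: TaskGeometry, condition: Condition
) -> bool:
    """Did the decoded path avoid the obstacle and reach the target?"""
    decoded = np.asarray(decoded, dtype=float)
    if decoded.shape[0] < 2:
        raise ValueError("need at least 2 decoded points")
    obstacle = box(
        *geometry.obstacle_rectangle(condition.start_label, condition.target_label)
    )
    path = LineString(decoded)
    if path.intersects(obstacle):
        return False
    target = geometry.position(condition.target_label)
    return bool(Point(decoded[-1]).distance(Point(target)) <= geometry.target_radius)


def paired_ttest(scores_a, scores_b) -> float:
    """Two-sided paired Student's t-test p-value."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need equal-length paired score lists with n >= 2")
    diff = a - b
    if np.var(diff) == 0:
        if np.mean(diff) == 0:
            return 1.0
        raise ValueError("paired differences are constant and non-zero")
    return float(stats.ttest_rel(a, b).pvalue)


@dataclass
class TrialResult:
    """Scores of one decoded trial under one prior-knowledge condition."""

    trial_id: int
    decoder_condition: str
    cc_x: float
    cc_y: float
    cc_mean: float
    mse: float
    success: bool


@dataclass
class SessionSummary:
    """Aggregate three-decoder comparison over a session.

    Percentage changes follow the ascending/descending-rate convention:
    CC and success rate as (new - old) / old * 100 with "both" as new, MSE
    as (old - new) / old * 100.
    """

    results: dict[str, list[TrialResult]]
    mean_cc: dict[str, float] = field(init=False)
    mean_mse: dict[str, float] = field(init=False)
    success_rate: dict[str, float] = field(init=False)
    n_trials: int = field(init=False)
    p_values: dict[tuple, float] = field(init=False)
    pct_change: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean_cc = {}
        self.mean_mse = {}
        self.success_rate = {}
        for cond, rs in self.results.items():
            self.mean_cc[cond] = float(np.mean([r.cc_mean for r in rs]))
            self.mean_mse[cond] = float(np.mean([r.mse for r in rs]))
            self.success_rate[cond] = float(np.mean([r.success for r in rs]))
        self.n_trials = len(next(iter(self.results.values())))
        self.p_values = {}
        conds = list(self.results)
        for i, a in enumerate(conds):
            for b_ in conds[i + 1 :]:
                for metric, get in (
                    ("cc", lambda r: r.cc_mean),
                    ("mse", lambda r: r.mse),
                    ("success", lambda r: float(r.success)),
                ):
                    try:
                        p = paired_ttest(
                            [get(r) for r in self.results[a]],
                            [get(r) for r in self.results[b_]],
                        )
                    except ValueError:
                        p = float("nan")
                    self.p_values[(a, b_, metric)] = p
        self.pct_change = {}
        if "both" in self.results:
            for old in ("none", "target"):
                if old not in self.results:
                    continue
                self.pct_change[f"cc_vs_{old}"] = (
                    (self.mean_cc["both"] - self.mean_cc[old])
                    / abs(self.mean_cc[old])
                    * 100.0
                )
                self.pct_change[f"mse_vs_{old}"] = (
                    (self.mean_mse[old] - self.mean_mse["both"])
                    / self.mean_mse[old]
                    * 100.0
                )
                if self.success_rate[old] > 0:
                    self.pct_change[f"success_vs_{old}"] = (
                        (self.success_rate["both"] - self.success_rate[old])
                        / self.success_rate[old]
                        * 100.0
                    )


def _trial_priors(
    test: Trial,
    target_clf: DelayWindowClassifier,
    selection_clf: DelayWindowClassifier,
    catalogue,
) -> dict[str, np.ndarray | None]:
    tp = target_clf.predict_proba(extract_window_features(test, "target"))[0]
    sp = selection_clf.predict_proba(extract_window_features(test, "selection"))[0]
    return {
        "none": None,
        "target": expand_target_prior(tp, catalogue, list(target_clf.classes_)),
        "both": combine_priors(
            tp, sp, catalogue, list(target_clf.classes_), list(selection_clf.classes_)
        ),
    }


def compare_decoders(
    trials: list[Trial],
    geometry: TaskGeometry | None = None,
    conditions: tuple[str, ...] = DECODER_CONDITIONS,
    keying: str = "target_and_opening",
    weight_update: str = "likelihood",
    min_trials: int = 5,
    var_floor: float = 1e-6,
    prior_var_floor: float = 1e-4,
    loocv: bool = True,
    forced_priors: dict[str, list[np.ndarray | None]] | None = None,
) -> SessionSummary:
    """Three-decoder comparison on one (single-start) session.

    For every trial, regime models and delay-window classifiers are fitted
    on the remaining trials (LOOCV; set ``loocv=False`` to train once on
    the full session), the trial is decoded once per prior condition, and
    CC / MSE / success are recorded.  ``forced_priors`` overrides the
    decoded priors per condition (e.g. oracle or uniform controls): a map
    condition -> per-trial list of prior vectors (or None for uniform).
    """
    if geometry is None:
        geometry = TaskGeometry()
    if any(t.condition is None for t in trials):
        raise ValueError("success-rate evaluation requires condition labels on all trials")
    starts = {t.condition.start_label for t in trials}
    if len(starts) != 1:
        raise ValueError("compare_decoders expects a single-start session")
    start = starts.pop()
    catalogue = build_regime_catalogue(geometry, start_label=start)

    def _fit(train):
        model_set = fit_model_set(
            train, keying=keying, min_trials=min_trials, var_floor=var_floor
        )
        tX = np.array([extract_window_features(t, "target") for t in train])
        ty = [trial_class_label(t, "target") for t in train]
        sX = np.array([extract_window_features(t, "selection") for t in train])
        sy = [trial_class_label(t, "selection") for t in train]
        target_clf = DelayWindowClassifier(var_floor=prior_var_floor).fit(tX, ty)
        selection_clf = DelayWindowClassifier(var_floor=prior_var_floor).fit(sX, sy)
        return model_set, target_clf, selection_clf

    if not loocv:
        shared = _fit(trials)

    results: dict[str, list[TrialResult]] = {c: [] for c in conditions}
    for i, test in enumerate(trials):
        if loocv:
            model_set, target_clf, selection_clf = _fit(trials[:i] + trials[i + 1 :])
        else:
            model_set, target_clf, selection_clf = shared
        priors = _trial_priors(test, target_clf, selection_clf, catalogue)
        true = test.positions[epoch_slice(test, "movement")]
        true_norm = normalize_positions(true, geometry)
        for cond in conditions:
            if forced_priors is not None and cond in forced_priors:
                prior = forced_priors[cond][i]
            else:
                prior = priors[cond]
            res = decode_trial(
                test,
                model_set,
                DecodeConfig(prior_over_regimes=prior, weight_update=weight_update),
            )
            dec_norm = normalize_positions(res.means, geometry)
            ccs = []
            for k in range(2):
                if np.var(true_norm[:, k]) == 0 or np.var(dec_norm[:, k]) == 0:
                    ccs.append(float("nan"))
                else:
                    ccs.append(
                        float(stats.pearsonr(dec_norm[:, k], true_norm[:, k]).statistic)
                    )
            mse = float(np.mean(np.sum((dec_norm - true_norm) ** 2, axis=1)))
            results[cond].append(
                TrialResult(
                    trial_id=test.trial_id,
                    decoder_condition=cond,
                    cc_x=ccs[0],
                    cc_y=ccs[1],
                    cc_mean=float(np.nanmean(ccs)),
                    mse=mse,
                    success=success_check(res.means, geometry, test.condition),
                )
            )
    return SessionSummary(results=results)
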