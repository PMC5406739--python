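"""Population-vector and PCA views of planning activity.

The population vector (PV) summarises which direction the population is
"pointing": each unit contributes its velocity-tuning coefficient vector
(its unnormalised preferred direction — strongly tuned units weigh more)
scaled by how far its rate deviates from its rest-epoch baseline,

    PV = sum_i (rate_i - baseline_i) * c_i .

Tuning is fitted on movement-epoch bins (counts regressed on hand
velocity) and then applied to rest/delay bins, so delay-period activity
that pre-activates the upcoming movement shows up as a PV pointing at the
target while rest activity yields near-zero PVs.

PCA of the delay-2 selection-window bins (each 100 ms population vector
is one sample) visualises whether the two intended movement selections
(clockwise / counterclockwise) form separable clusters before movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .synthetic import BIN_WIDTH_MS, Trial, epoch_slice
from .priors import trial_class_label

__all__ = [
    "TuningModel",
    "PVSeries",
    "VelocityTuning",
    "fit_velocity_tuning",
    "population_vector",
    "pv_evolution",
    "pca_delay2",
    "Delay2PCA",
]


@dataclass
class TuningModel:
    """Per-unit velocity tuning: baseline rates and coefficient vectors.

    ``coef[i]`` (counts per cm/s) is unit i's regression coefficient on
    (v_x, v_y); its direction is the preferred direction and its magnitude
    the modulation weight.  ``baseline`` is the rest-epoch mean rate used
    for PV weighting; ``intercept`` the regression intercept.
    """

    baseline: np.ndarray
    intercept: np.ndarray
    coef: np.ndarray

    @property
    def weight(self) -> np.ndarray:
        return np.linalg.norm(self.coef, axis=1)

    @property
    def preferred_direction(self) -> np.ndarray:
        """Unit preferred-direction vectors (zero rows for untuned units)."""
        w = self.weight
        pd = np.zeros_like(self.coef)
        tuned = w > 0
        pd[tuned] = self.coef[tuned] / w[tuned, None]
        return pd


@dataclass
class PVSeries:
    """Per-bin population vectors across the pre-movement epochs."""

    vectors: np.ndarray  # (bins x 2)
    epoch_labels: list[str]


def fit_velocity_tuning(trials: list[Trial]) -> TuningModel:
    """Regress each unit's movement-epoch counts on hand velocity.

    Velocities are first differences of position divided by the bin width;
    coefficients are left unnormalised so strongly tuned units carry more
    weight in the PV.  Baselines are rest-epoch mean rates.
    """
    dt = BIN_WIDTH_MS / 1000.0
    vels, counts, rest = [], [], []
    for trial in trials:
        sl = epoch_slice(trial, "movement")
        pos = np.asarray(trial.positions[sl], dtype=float)
        cnt = np.asarray(trial.counts[sl], dtype=float)
        if pos.shape[0] >= 2:
            vels.append(np.diff(pos, axis=0) / dt)
            counts.append(cnt[1:])
        rest.append(np.asarray(trial.counts[epoch_slice(trial, "rest")], dtype=float))
    if not vels or sum(v.shape[0] for v in vels) < 3:
        raise ValueError("need at least 3 movement bins to fit velocity tuning")
    V = np.concatenate(vels)
    Y = np.concatenate(counts)
    design = np.column_stack([V, np.ones(V.shape[0])])
    W, *_ = np.linalg.lstsq(design, Y, rcond=None)
    baseline = np.concatenate(rest).mean(axis=0)
    return TuningModel(baseline=baseline, intercept=W[2], coef=W[:2].T)


def population_vector(bin_counts: np.ndarray, tuning: TuningModel) -> np.ndarray:
    """PV of one bin: baseline-deviation-weighted sum of coefficient vectors."""
    rates = np.asarray(bin_counts, dtype=float)
    if rates.shape != tuning.baseline.shape:
        raise ValueError("bin_counts length must equal the number of units")
    return (rates - tuning.baseline) @ tuning.coef


def pv_evolution(trials: list[Trial], tuning: TuningModel) -> PVSeries:
    """PV per pre-movement bin, summed across trials of one condition.

    Uses the last 5 rest bins, the 3 delay-1 bins and the first delay-2
    bin of each trial (9 bins); trials must share a condition.
    """
    conds = {
        (t.condition.start_label, t.condition.target_label, t.condition.opening_side)
        for t in trials
        if t.condition is not None
    }
    if len(conds) != 1 or any(t.condition is None for t in trials):
        raise ValueError("pv_evolution requires trials of a single condition")
    total = np.zeros((9, 2))
    for trial in trials:
        rest = trial.counts[epoch_slice(trial, "rest")][-5:]
        d1 = trial.counts[epoch_slice(trial, "delay1")]
        d2 = trial.counts[epoch_slice(trial, "delay2")][:1]
        window = np.vstack([rest, d1, d2])
        if window.shape[0] != 9:
            raise ValueError("trial has fewer than 5 rest bins")
        total += (np.asarray(window, dtype=float) - tuning.baseline) @ tuning.coef
    labels = ["rest"] * 5 + ["delay1"] * 3 + ["delay2"]
    return PVSeries(vectors=total, epoch_labels=labels)


class VelocityTuning(BaseEstimator):
    """scikit-learn style wrapper around the velocity-tuning fit.

    ``fit`` estimates per-unit tuning from movement epochs; ``transform``
    maps (bins x units) count matrices to (bins x 2) population vectors.
    """

    def fit(self, trials: list[Trial], y=None) -> "VelocityTuning":
        self.tuning_ = fit_velocity_tuning(trials)
        self.n_units_ = self.tuning_.coef.shape[0]
        return self

    def transform(self, counts: np.ndarray) -> np.ndarray:
        counts = np.atleast_2d(np.asarray(counts, dtype=float))
        return (counts - self.tuning_.baseline) @ self.tuning_.coef


@dataclass
class Delay2PCA:
    """PCA of selection-window activity: 2D scores plus labels."""

    scores: np.ndarray  # (samples x 2)
    labels: list
    loadings: np.ndarray  # (units x components)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca_delay2(
    trials: list[Trial],
    class_labels: list | None = None,
    n_components: int = 2,
) -> Delay2PCA:
    """Project selection-window bins onto their top principal components.

    Each sample is one 100 ms bin of the delay-2 selection window (bins
    2-5), labelled by the trial's intended movement selection.  The PCA is
    mean-centred, so projections are invariant to adding a constant
    pattern to all samples.
    """
    if class_labels is None:
        class_labels = [trial_class_label(t, "selection") for t in trials]
    samples, labels = [], []
    for trial, lab in zip(trials, class_labels):
        d2 = np.asarray(trial.counts[epoch_slice(trial, "delay2")], dtype=float)
        if d2.shape[0] < 5:
            raise ValueError("selection window needs delay-2 bins 2-5")
        for row in d2[1:5]:
            samples.append(row)
            labels.append(lab)
    X = np.array(samples)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 selection-window samples for PCA")
    k = min(n_components, X.shape[1], X.shape[0] - 1)
    pca = PCA(n_components=k).fit(X)
    return Delay2PCA(
        scores=pca.transform(X),
        labels=labels,
        loadings=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean=pca.mean_,
    )
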