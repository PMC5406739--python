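"""Synthetic delayed obstacle-avoidance sessions.

No public recordings exist for this task, so the generator emulates the
statistical structure the analysis pipeline assumes: a population of ~40
premotor units whose 100 ms spike counts are

* class-conditionally Gaussian during the delay epochs (per-unit mean and
  variance depending on the upcoming target during delay 1, and on the
  (target, obstacle-opening) movement regime during delay 2), and
* linear-Gaussian in hand position during the movement epoch with
  regime-specific parameters, ``y_t = H_m x_t + p_m + eps``,
  ``eps ~ N(0, V)``.

Each unit carries a 2D velocity-tuning vector ``c_i`` (counts per cm/s)
playing the role of an unnormalised preferred direction.  The
movement-epoch observation model of regime m is the projection of that
velocity tuning onto position along the regime's reference trajectory:
with ``v ~= B_m x + a_m`` the least-squares position-to-velocity map of
the path, ``H_m = C B_m`` and ``p_m = baseline + C a_m``.  Counts are
thus exactly linear-Gaussian in position within each regime — the model
the decoder assumes — while regimes differ in their observation maps the
way velocity-tuned populations do (at the shared start position the
expected rates already reflect the regime's planned movement direction).
Delay-epoch modulation projects the target direction (delay 1) and the
initial movement direction toward the obstacle opening (delay 2) onto the
same tuning vectors, scaled by planned-speed gains in cm/s, so planning
activity points the population toward the upcoming movement.

Counts are integerised (rounded, clipped at zero) by default; set
``integer_counts=False`` to obtain the raw Gaussian draws, for which the
configured means and variances are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .task import (
    CANONICAL_POSITIONS,
    EPOCH_NAMES,
    Condition,
    TaskGeometry,
    build_regime_catalogue,
    generate_trajectory,
)

__all__ = [
    "Trial",
    "GeneratorConfig",
    "SessionParameters",
    "generate_session",
    "draw_session_parameters",
    "validate_trial",
    "epoch_slice",
    "default_benchmark_config",
    "generate_benchmark_session",
    "BIN_WIDTH_MS",
]

#: Width of one spike-count bin, in milliseconds.
BIN_WIDTH_MS = 100.0


@dataclass
class Trial:
    """One trial: binned spike counts, hand positions and epoch boundaries.

    ``counts`` is (T bins x n units); ``positions`` is (T x 2) in cm.
    ``epochs`` maps each epoch name (rest, delay1, delay2, movement, hold)
    to a half-open bin range ``[start, end)``; 0-based, contiguous, covering
    all T bins.  ``condition`` may be ``None`` for unlabelled data (decoding
    is still possible; condition-dependent evaluation is not).
    """

    counts: np.ndarray
    positions: np.ndarray
    epochs: dict[str, tuple[int, int]]
    condition: Condition | None = None
    session_id: str = ""
    trial_id: int = 0

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]


def epoch_slice(trial: Trial, name: str) -> slice:
    """Slice of trial bins belonging to the named epoch."""
    lo, hi = trial.epochs[name]
    return slice(lo, hi)


def validate_trial(trial: Trial) -> None:
    """Check the structural invariants of a trial; raise ValueError if broken."""
    counts = np.asarray(trial.counts)
    positions = np.asarray(trial.positions)
    if counts.ndim != 2:
        raise ValueError("counts must be a (bins x units) matrix")
    if positions.shape != (counts.shape[0], 2):
        raise ValueError("positions must be (bins x 2) and match counts")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    expected = 0
    for name in EPOCH_NAMES:
        if name not in trial.epochs:
            raise ValueError(f"epoch {name!r} missing")
        lo, hi = trial.epochs[name]
        if lo != expected or hi <= lo:
            raise ValueError(
                f"epoch {name!r} range [{lo}, {hi}) is not contiguous with the "
                f"previous epoch (expected start {expected})"
            )
        expected = hi
    if expected != counts.shape[0]:
        raise ValueError("epoch ranges must cover all bins exactly")
    d1 = trial.epochs["delay1"]
    if d1[1] - d1[0] != 3:
        raise ValueError("delay1 must span exactly 3 bins (300 ms)")
    d2 = trial.epochs["delay2"]
    if not 5 <= d2[1] - d2[0] <= 8:
        raise ValueError("delay2 must span 5-8 bins (500-800 ms)")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    Epoch durations are in 100 ms bins.  Rate parameters are in counts per
    bin; tuning coefficients in counts per cm/s.  The delay gains are
    planned-speed equivalents in cm/s: a unit's delay-1 mean is
    ``baseline_i + delay1_gain * (c_i . u_target)`` with ``u_target`` the
    unit vector from start to target, as if the population were already
    driving a movement of that speed toward the target (analogously for
    delay 2, where the initial-movement direction toward the obstacle
    opening enters with ``delay2_select_gain`` and the target direction
    with the smaller ``delay2_target_gain``).
    """

    n_units: int = 40
    n_trials: int = 300
    seed: int = 0
    start_labels: tuple[str, ...] = ("bottom",)
    rest_bins: int = 5
    delay1_bins: int = 3
    delay2_bins: tuple[int, int] = (5, 8)
    movement_bins: tuple[int, int] = (10, 15)
    hold_bins: int = 5
    baseline_range: tuple[float, float] = (2.0, 6.0)
    tuning_magnitude_range: tuple[float, float] = (0.02, 0.10)
    delay1_gain: float = 12.0
    delay2_target_gain: float = 1.0
    delay2_select_gain: float = 6.0
    delay_noise_sd: float = 1.2
    obs_noise_sd: float = 4.5
    kinematic_noise_sd: float = 0.3
    start_jitter_sd: float = 0.15
    reference_bins: int = 12
    integer_counts: bool = True
    # optional explicit parameters (drawn from the seed when None)
    baselines: np.ndarray | None = None
    coefs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_trials < 1:
            raise ValueError("n_units and n_trials must be >= 1")
        if self.delay_noise_sd <= 0 or self.obs_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if self.delay1_bins != 3:
            raise ValueError("delay1 is fixed at 3 bins (300 ms)")
        lo, hi = self.delay2_bins
        if not (5 <= lo <= hi <= 8):
            raise ValueError("delay2_bins must lie within [5, 8]")
        for s in self.start_labels:
            if s not in CANONICAL_POSITIONS:
                raise ValueError(f"unknown start label {s!r}")


@dataclass
class SessionParameters:
    """Ground-truth parameters realised for one synthetic session.

    ``delay1_means[start][i, k]`` is unit i's delay-1 mean count for target
    class k (targets in catalogue order for that start);
    ``delay2_means[start][i, m-1]`` the delay-2 mean for regime m.
    ``obs_H[start][m-1]`` / ``obs_p[start][m-1]`` are regime m's movement
    observation matrix (n x 2) and bias (n,); the observation noise is
    ``V = obs_var * I`` for every regime.
    """

    baselines: np.ndarray
    coefs: np.ndarray
    delay1_means: dict[str, np.ndarray]
    delay2_means: dict[str, np.ndarray]
    obs_H: dict[str, list[np.ndarray]]
    obs_p: dict[str, list[np.ndarray]]
    delay_var: float
    obs_var: float


def draw_session_parameters(
    config: GeneratorConfig,
    geometry: TaskGeometry,
    rng: np.random.Generator,
) -> SessionParameters:
    """Realise per-unit tuning and the implied class-conditional delay means."""
    n = config.n_units
    if config.baselines is not None:
        baselines = np.asarray(config.baselines, dtype=float)
    else:
        baselines = rng.uniform(*config.baseline_range, size=n)
    if config.coefs is not None:
        coefs = np.asarray(config.coefs, dtype=float)
    else:
        mags = rng.uniform(*config.tuning_magnitude_range, size=n)
        angles = rng.uniform(0.0, 2 * np.pi, size=n)
        coefs = mags[:, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    if baselines.shape != (n,) or coefs.shape != (n, 2):
        raise ValueError("baselines/coefs dimensions inconsistent with n_units")

    dt = BIN_WIDTH_MS / 1000.0
    delay1_means: dict[str, np.ndarray] = {}
    delay2_means: dict[str, np.ndarray] = {}
    obs_H: dict[str, list[np.ndarray]] = {}
    obs_p: dict[str, list[np.ndarray]] = {}
    for start in config.start_labels:
        cat = build_regime_catalogue(geometry, start_label=start)
        targets = []
        for cond in cat:
            if cond.target_label not in targets:
                targets.append(cond.target_label)
        s = geometry.position(start)
        mu1 = np.empty((n, len(targets)))
        for k, tgt in enumerate(targets):
            u = geometry.position(tgt) - s
            u = u / np.linalg.norm(u)
            mu1[:, k] = baselines + config.delay1_gain * coefs @ u
        mu2 = np.empty((n, len(cat)))
        Hs: list[np.ndarray] = [None] * len(cat)
        ps: list[np.ndarray] = [None] * len(cat)
        for cond in cat:
            u_t = geometry.position(cond.target_label) - s
            u_t = u_t / np.linalg.norm(u_t)
            via = geometry.via_point(start, cond.target_label, cond.opening_side)
            u_i = via - s
            u_i = u_i / np.linalg.norm(u_i)
            mu2[:, cond.regime_id - 1] = (
                baselines
                + config.delay2_target_gain * coefs @ u_t
                + config.delay2_select_gain * coefs @ u_i
            )
            # project velocity tuning onto position along the reference path:
            # v ~= B x + a  =>  H = C B, p = baseline + C a
            ref = generate_trajectory(cond, geometry, config.reference_bins, 0.0)
            vel = np.diff(ref, axis=0) / dt
            design = np.column_stack([ref[1:], np.ones(vel.shape[0])])
            W, *_ = np.linalg.lstsq(design, vel, rcond=None)
            B, a = W[:2].T, W[2]
            Hs[cond.regime_id - 1] = coefs @ B
            ps[cond.regime_id - 1] = baselines + coefs @ a
        delay1_means[start] = mu1
        delay2_means[start] = mu2
        obs_H[start] = Hs
        obs_p[start] = ps
    return SessionParameters(
        baselines=baselines,
        coefs=coefs,
        delay1_means=delay1_means,
        delay2_means=delay2_means,
        obs_H=obs_H,
        obs_p=obs_p,
        delay_var=config.delay_noise_sd**2,
        obs_var=config.obs_noise_sd**2,
    )


def _discretise(counts: np.ndarray, integer_counts: bool) -> np.ndarray:
    if integer_counts:
        return np.clip(np.rint(counts), 0, None)
    return counts


def generate_session(
    config: GeneratorConfig,
    geometry: TaskGeometry | None = None,
    return_parameters: bool = False,
):
    """Generate a synthetic session (list of trials) from a config.

    Conditions are balanced across the catalogue of the configured start
    positions and presented in a random order.  The same config (including
    its ``seed``) always yields a bit-identical session.

    With ``return_parameters=True`` also returns the realised
    :class:`SessionParameters` (ground truth for recovery tests).
    """
    if geometry is None:
        geometry = TaskGeometry()
    rng = np.random.default_rng(config.seed)
    params = draw_session_parameters(config, geometry, rng)

    catalogue: list[Condition] = []
    for start in config.start_labels:
        catalogue.extend(build_regime_catalogue(geometry, start_label=start))
    reps = -(-config.n_trials // len(catalogue))
    conditions = (catalogue * reps)[: config.n_trials]
    order = rng.permutation(config.n_trials)
    conditions = [conditions[i] for i in order]

    targets_by_start = {}
    for start in config.start_labels:
        targets_by_start[start] = [
            p for p in CANONICAL_POSITIONS if p != start
        ]

    trials = []
    session_id = f"synthetic-seed{config.seed}"
    for trial_id, cond in enumerate(conditions):
        n_d2 = int(rng.integers(config.delay2_bins[0], config.delay2_bins[1] + 1))
        n_mov = int(rng.integers(config.movement_bins[0], config.movement_bins[1] + 1))
        lens = [config.rest_bins, config.delay1_bins, n_d2, n_mov, config.hold_bins]
        edges = np.concatenate([[0], np.cumsum(lens)])
        epochs = {
            name: (int(edges[i]), int(edges[i + 1]))
            for i, name in enumerate(EPOCH_NAMES)
        }
        T = int(edges[-1])

        start_pos = geometry.position(cond.start_label)
        target_pos = geometry.position(cond.target_label)
        positions = np.empty((T, 2))
        n_pre = config.rest_bins + config.delay1_bins + n_d2
        positions[:n_pre] = start_pos + rng.normal(
            0.0, config.start_jitter_sd, size=(n_pre, 2)
        )
        positions[n_pre : n_pre + n_mov] = generate_trajectory(
            cond, geometry, n_mov, config.kinematic_noise_sd, rng
        )
        positions[n_pre + n_mov :] = target_pos + rng.normal(
            0.0, config.start_jitter_sd, size=(config.hold_bins, 2)
        )

        mu1 = params.delay1_means[cond.start_label]
        mu2 = params.delay2_means[cond.start_label]
        k_target = targets_by_start[cond.start_label].index(cond.target_label)
        rates = np.empty((T, config.n_units))
        rates[: config.rest_bins] = params.baselines
        rates[config.rest_bins : config.rest_bins + 3] = mu1[:, k_target]
        rates[config.rest_bins + 3 : n_pre] = mu2[:, cond.regime_id - 1]
        # movement and hold bins follow the regime's linear-Gaussian
        # observation model
        H_m = params.obs_H[cond.start_label][cond.regime_id - 1]
        p_m = params.obs_p[cond.start_label][cond.regime_id - 1]
        rates[n_pre:] = positions[n_pre:] @ H_m.T + p_m
        noise_sd = np.full((T, 1), config.delay_noise_sd)
        noise_sd[n_pre:] = config.obs_noise_sd
        counts = rates + rng.normal(0.0, 1.0, size=rates.shape) * noise_sd
        counts = _discretise(counts, config.integer_counts)

        trials.append(
            Trial(
                counts=counts,
                positions=positions,
                epochs=epochs,
                condition=cond,
                session_id=session_id,
                trial_id=trial_id,
            )
        )
    if return_parameters:
        return trials, params
    return trials


def default_benchmark_config(seed: int = 0) -> GeneratorConfig:
    """Config of the default synthetic benchmark session.

    One start position (bottom), 6 movement regimes, 240 trials (40 per
    regime) and 40 units — the session size used throughout the evaluation
    examples.
    """
    return GeneratorConfig(n_units=40, n_trials=240, seed=seed, start_labels=("bottom",))


def generate_benchmark_session(seed: int = 0, **kwargs):
    """Generate the default benchmark session (see default_benchmark_config)."""
    config = replace(default_benchmark_config(seed), **kwargs) if kwargs else default_benchmark_config(seed)
    return generate_session(config)
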