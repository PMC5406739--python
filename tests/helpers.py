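"""Small builders shared across test modules."""

from __future__ import annotations

import numpy as np

from mtmdecode import Condition, RegimeModel, Trial


def make_trial(
    movement_positions: np.ndarray,
    movement_counts: np.ndarray,
    condition: Condition | None = None,
    pre_counts: float = 0.0,
) -> Trial:
    """Wrap movement-epoch data in a structurally valid Trial.

    Rest/delay/hold epochs are filled with constant positions (the first /
    last movement position) and constant counts.
    """
    movement_positions = np.asarray(movement_positions, dtype=float)
    movement_counts = np.atleast_2d(np.asarray(movement_counts, dtype=float))
    T, n = movement_counts.shape
    pre = 5 + 3 + 5  # rest + delay1 + delay2
    hold = 2
    counts = np.full((pre + T + hold, n), float(pre_counts))
    counts[pre : pre + T] = movement_counts
    positions = np.empty((pre + T + hold, 2))
    positions[:pre] = movement_positions[0]
    positions[pre : pre + T] = movement_positions
    positions[pre + T :] = movement_positions[-1]
    epochs = {
        "rest": (0, 5),
        "delay1": (5, 8),
        "delay2": (8, 13),
        "movement": (13, 13 + T),
        "hold": (13 + T, 13 + T + hold),
    }
    return Trial(counts=counts, positions=positions, epochs=epochs, condition=condition)


def random_regime_model(rng: np.random.Generator, d: int = 2, n: int = 4) -> RegimeModel:
    """A random, well-conditioned regime model for fuzzing."""
    A = np.eye(d) + 0.1 * rng.normal(size=(d, d))
    b = rng.normal(size=d)
    L = 0.3 * rng.normal(size=(d, d))
    Q = L @ L.T + 0.1 * np.eye(d)
    H = rng.normal(size=(n, d))
    p = rng.normal(size=n)
    V = np.diag(rng.uniform(0.5, 2.0, size=n))
    return RegimeModel(key=("fuzz",), A=A, b=b, Q=Q, H=H, p=p, V=V)
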