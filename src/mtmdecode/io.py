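"""Session serialisation: a JSON header plus one CSV per trial.

A session directory holds ``session.json`` (format version, bin width,
unit count, per-trial epoch ranges and condition labels) and one
``trial_NNNN.csv`` per trial with columns ``unit_0..unit_{n-1}, pos_x,
pos_y`` (one row per 100 ms bin).  The round-trip is lossless up to float
representation; files written by this module read back field-for-field
equal.

Condition labels are optional: a trial whose ``condition`` entry is null
reads back with ``condition=None`` ("unknown"), which permits decoding but
not condition-dependent evaluation (success rate, per-regime fits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BIN_WIDTH_MS, Trial, validate_trial
from .task import EPOCH_NAMES, Condition

__all__ = ["write_session", "read_session", "FORMAT_NAME", "FORMAT_VERSION"]

FORMAT_NAME = "mtmdecode-session"
FORMAT_VERSION = 1


def write_session(path: str | Path, trials: list[Trial]) -> None:
    """Write a session to a directory (created if needed)."""
    if not trials:
        raise ValueError("cannot write an empty session")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    n_units = trials[0].n_units
    entries = []
    for i, trial in enumerate(trials):
        validate_trial(trial)
        if trial.n_units != n_units:
            raise ValueError("all trials in a session must share n_units")
        fname = f"trial_{i:04d}.csv"
        cols = {f"unit_{j}": trial.counts[:, j] for j in range(n_units)}
        cols["pos_x"] = trial.positions[:, 0]
        cols["pos_y"] = trial.positions[:, 1]
        pd.DataFrame(cols).to_csv(path / fname, index=False)
        cond = trial.condition
        entries.append(
            {
                "trial_id": int(trial.trial_id),
                "file": fname,
                "epochs": {k: [int(a), int(b)] for k, (a, b) in trial.epochs.items()},
                "condition": None
                if cond is None
                else {
                    "start": cond.start_label,
                    "target": cond.target_label,
                    "opening": cond.opening_side,
                    "regime_id": int(cond.regime_id),
                },
            }
        )
    header = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "bin_width_ms": BIN_WIDTH_MS,
        "n_units": int(n_units),
        "session_id": trials[0].session_id,
        "trials": entries,
    }
    with open(path / "session.json", "w") as fh:
        json.dump(header, fh, indent=1)


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValueError(f"malformed session file: missing field {key!r} in {context}")
    return mapping[key]


def read_session(path: str | Path) -> list[Trial]:
    """Read a session directory written by :func:`write_session`.

    Raises ValueError naming the offending field on malformed input, and on
    a format-version mismatch.
    """
    path = Path(path)
    with open(path / "session.json") as fh:
        header = json.load(fh)
    if _require(header, "format", "header") != FORMAT_NAME:
        raise ValueError("malformed session file: unrecognised 'format'")
    version = _require(header, "version", "header")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"session format version mismatch: file has {version}, "
            f"reader supports {FORMAT_VERSION}"
        )
    n_units = int(_require(header, "n_units", "header"))
    session_id = header.get("session_id", "")
    trials = []
    for entry in _require(header, "trials", "header"):
        fname = _require(entry, "file", "trial entry")
        epochs_raw = _require(entry, "epochs", f"trial entry {fname}")
        try:
            epochs = {k: (int(v[0]), int(v[1])) for k, v in epochs_raw.items()}
        except (TypeError, IndexError) as exc:
            raise ValueError(
                f"malformed session file: bad 'epochs' in trial entry {fname}"
            ) from exc
        for name in EPOCH_NAMES:
            if name not in epochs:
                raise ValueError(
                    f"malformed session file: missing epoch {name!r} in {fname}"
                )
        cond_raw = entry.get("condition")
        condition = None
        if cond_raw is not None:
            condition = Condition(
                start_label=_require(cond_raw, "start", f"condition of {fname}"),
                target_label=_require(cond_raw, "target", f"condition of {fname}"),
                opening_side=_require(cond_raw, "opening", f"condition of {fname}"),
                regime_id=int(_require(cond_raw, "regime_id", f"condition of {fname}")),
            )
        frame = pd.read_csv(path / fname)
        unit_cols = [f"unit_{j}" for j in range(n_units)]
        for col in unit_cols + ["pos_x", "pos_y"]:
            if col not in frame.columns:
                raise ValueError(f"malformed session file: column {col!r} missing in {fname}")
        trial = Trial(
            counts=frame[unit_cols].to_numpy(dtype=float),
            positions=frame[["pos_x", "pos_y"]].to_numpy(dtype=float),
            epochs=epochs,
            condition=condition,
            session_id=session_id,
            trial_id=int(entry.get("trial_id", len(trials))),
        )
        validate_trial(trial)
        trials.append(trial)
    return trials
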