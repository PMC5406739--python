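"""Obstacle-avoidance task geometry, condition catalogue and reference trajectories.

The task is a delayed indirect-reaching task: a cursor is moved on a 2D
manipulandum workspace from one of four canonical start positions (bottom,
top, left, right) to one of the three remaining positions, around a
rectangular obstacle placed on the straight start-to-target segment.  The
obstacle leaves an opening on one side, so for every (start, target) pair
there are two avoidance paths — one passing the obstacle clockwise, one
counterclockwise.  With four start positions this yields 4 x 3 x 2 = 24
task conditions; conditioned on a fixed start there are 6 movement regimes.

Coordinates are centimetres in a workspace centred at (0, 0); time is
discretised in 100 ms bins throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskGeometry",
    "Condition",
    "CANONICAL_POSITIONS",
    "OPENING_SIDES",
    "build_regime_catalogue",
    "regime_index",
    "generate_trajectory",
    "min_jerk_profile",
]

#: Canonical position labels in their fixed catalogue order.
CANONICAL_POSITIONS = ("bottom", "left", "top", "right")

#: Opening sides in their fixed catalogue order.  "clockwise" means the path
#: goes around the obstacle clockwise (obstacle kept on the right of travel,
#: path passing on its left); "counterclockwise" keeps it on the left.
OPENING_SIDES = ("clockwise", "counterclockwise")

EPOCH_NAMES = ("rest", "delay1", "delay2", "movement", "hold")


def _rot90(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by +90 degrees (counterclockwise)."""
    return np.array([-v[1], v[0]])


@dataclass(frozen=True)
class TaskGeometry:
    """Workspace layout of the delayed obstacle-avoidance task.

    Parameters
    ----------
    workspace_extent : tuple of float
        Width and height of the manipulandum range in cm (default 20 x 20,
        centred at the origin).
    positions : dict
        Map of the four canonical labels to 2D coordinates (cm).
    target_radius : float
        Radius (cm) within which the cursor must end to count as having
        reached the target.
    hold_duration_ms : float
        Required hold time at the target, in milliseconds.
    obstacle_halfwidth : float
        Half-extent of the obstacle bar perpendicular to the start-target
        segment (cm).
    obstacle_thickness : float
        Full thickness of the obstacle bar along the segment (cm).
    via_clearance : float
        Distance from the segment midpoint to the via point used by the
        reference trajectory generator (cm); must exceed the obstacle's
        circumradius for the opening to exist.
    """

    workspace_extent: tuple[float, float] = (20.0, 20.0)
    positions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "bottom": (0.0, -8.0),
            "top": (0.0, 8.0),
            "left": (-8.0, 0.0),
            "right": (8.0, 0.0),
        }
    )
    target_radius: float = 2.0
    hold_duration_ms: float = 500.0
    obstacle_halfwidth: float = 2.0
    obstacle_thickness: float = 0.8
    via_clearance: float = 4.0

    def __post_init__(self) -> None:
        hw = np.asarray(self.workspace_extent) / 2.0
        for label in CANONICAL_POSITIONS:
            if label not in self.positions:
                raise ValueError(f"geometry is missing canonical position {label!r}")
            p = np.abs(np.asarray(self.positions[label]))
            if np.any(p > hw):
                raise ValueError(f"position {label!r} lies outside the workspace")
        if self.target_radius <= 0:
            raise ValueError("target_radius must be positive")

    def position(self, label: str) -> np.ndarray:
        return np.asarray(self.positions[label], dtype=float)

    def obstacle_rectangle(self, start_label: str, target_label: str) -> tuple[float, float, float, float]:
        """Axis-aligned obstacle bounds ``(xmin, ymin, xmax, ymax)`` for a pair.

        The obstacle is the axis-aligned bounding box of a bar centred at the
        midpoint of the start-target segment, oriented perpendicular to it.
        The midpoint is interior to the box, so the box always intersects the
        straight start-to-target segment: any successful trial must curve.
        """
        s = self.position(start_label)
        t = self.position(target_label)
        seg = t - s
        norm = np.linalg.norm(seg)
        if norm == 0:
            raise ValueError("start and target coincide")
        u = seg / norm
        n = _rot90(u)
        mid = (s + t) / 2.0
        corners = [
            mid + sw * self.obstacle_halfwidth * n + st * (self.obstacle_thickness / 2.0) * u
            for sw in (-1.0, 1.0)
            for st in (-1.0, 1.0)
        ]
        corners = np.array(corners)
        xmin, ymin = corners.min(axis=0)
        xmax, ymax = corners.max(axis=0)
        return (float(xmin), float(ymin), float(xmax), float(ymax))

    def via_point(self, start_label: str, target_label: str, opening_side: str) -> np.ndarray:
        """Way-point through the obstacle opening for the given condition.

        The via point sits ``via_clearance`` cm from the segment midpoint,
        perpendicular to the travel direction: on the right of travel for a
        counterclockwise pass, on the left for a clockwise pass.
        """
        if opening_side not in OPENING_SIDES:
            raise ValueError(f"unknown opening side {opening_side!r}")
        s = self.position(start_label)
        t = self.position(target_label)
        u = (t - s) / np.linalg.norm(t - s)
        side = 1.0 if opening_side == "clockwise" else -1.0
        via = (s + t) / 2.0 + side * self.via_clearance * _rot90(u)
        xmin, ymin, xmax, ymax = self.obstacle_rectangle(start_label, target_label)
        if xmin <= via[0] <= xmax and ymin <= via[1] <= ymax:
            raise ValueError(
                "no opening exists: the via point falls inside the obstacle "
                "(via_clearance too small for the obstacle size)"
            )
        return via


@dataclass(frozen=True)
class Condition:
    """One task condition: start, target and obstacle-opening side.

    ``regime_id`` identifies the movement regime among the 6 regimes of a
    fixed start position (1-based; see :func:`regime_index` for the ordering
    convention).
    """

    start_label: str
    target_label: str
    opening_side: str
    regime_id: int

    def __post_init__(self) -> None:
        if self.start_label == self.target_label:
            raise ValueError("start and target labels must differ")
        if self.opening_side not in OPENING_SIDES:
            raise ValueError(f"unknown opening side {self.opening_side!r}")


def _targets_for(start_label: str) -> list[str]:
    return [p for p in CANONICAL_POSITIONS if p != start_label]


def regime_index(start_label: str, target_label: str, opening_side: str) -> int:
    """1-based regime id for a (target, opening) pair at a fixed start.

    Targets are ordered by the canonical position order (bottom, left, top,
    right) with the start removed; openings by (clockwise, counterclockwise).
    ``regime_id = 2 * target_index + opening_index + 1``, so ids run 1..6 and
    the map (target, opening) <-> regime_id is a bijection for each start.
    """
    targets = _targets_for(start_label)
    if target_label not in targets:
        raise ValueError(f"{target_label!r} is not a valid target for start {start_label!r}")
    return 2 * targets.index(target_label) + OPENING_SIDES.index(opening_side) + 1


def build_regime_catalogue(
    geometry: TaskGeometry,
    start_label: str | None = None,
    target_label: str | None = None,
) -> list[Condition]:
    """Enumerate task conditions, optionally restricted to a start/target.

    The full catalogue holds 24 conditions (4 starts x 3 targets x 2
    openings); fixing the start yields the 6 movement regimes of that start.
    """
    starts = [start_label] if start_label is not None else list(CANONICAL_POSITIONS)
    catalogue = []
    for s in starts:
        if s not in CANONICAL_POSITIONS:
            raise ValueError(f"unknown start label {s!r}")
        for t in _targets_for(s):
            if target_label is not None and t != target_label:
                continue
            for o in OPENING_SIDES:
                catalogue.append(Condition(s, t, o, regime_index(s, t, o)))
    return catalogue


def min_jerk_profile(n: int) -> np.ndarray:
    """Minimum-jerk normalized arc-length profile s(tau) at n time points.

    s(0)=0, s(1)=1 with zero velocity and acceleration at both ends.
    """
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def generate_trajectory(
    condition: Condition,
    geometry: TaskGeometry,
    duration_bins: int,
    noise_scale: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reference avoidance trajectory for one condition, (duration_bins, 2) cm.

    The path is a quadratic Bezier from start to target whose control point
    is chosen so the curve passes exactly through the obstacle-opening via
    point at its midpoint; time is warped by a minimum-jerk profile so the
    speed is bell-shaped.  At ``noise_scale=0`` the path clears the obstacle
    by construction.  Gaussian positional noise of SD ``noise_scale`` cm is
    added to interior points (endpoints are kept exact).
    """
    if duration_bins < 3:
        raise ValueError("duration_bins must be at least 3")
    s = geometry.position(condition.start_label)
    t = geometry.position(condition.target_label)
    via = geometry.via_point(condition.start_label, condition.target_label, condition.opening_side)
    # control point so that B(1/2) = via for the quadratic Bezier
    c = 2.0 * via - (s + t) / 2.0
    tau = min_jerk_profile(duration_bins)[:, None]
    path = (1 - tau) ** 2 * s + 2 * tau * (1 - tau) * c + tau**2 * t
    if noise_scale > 0:
        if rng is None:
            rng = np.random.default_rng()
        noise = rng.normal(0.0, noise_scale, size=path.shape)
        noise[0] = 0.0
        noise[-1] = 0.0
        path = path + noise
    return path


def condition_from_labels(
    start_label: str, target_label: str, opening_side: str
) -> Condition:
    """Build a Condition with its canonical regime id."""
    return Condition(
        start_label,
        target_label,
        opening_side,
        regime_index(start_label, target_label, opening_side),
    )
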