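"""Social-avoidance trial analysis: zone times, interaction ratio, phenotype.

The test arena is 30x30 cm with a 9x9 cm cage against the midpoint of one
wall. Each mouse runs two consecutive 3-min sessions: first with the cage
empty, then with a caged novel target mouse. The interaction ratio

    int = t_f / t_e

divides the time spent within 15 cm of the occupied cage (t_f, second
session) by the time within 15 cm of the empty cage (t_e, first session).
Mice with int > 1.1 are classified resilient, int < 0.9 susceptible, and
ratios in between are left undefined and excluded from sleep analyses.

Note on the formula: some figure legends in this literature print the
ratio the other way up; t_f / t_e is the form under which "ratio > 1.1 =
resilient" matches resilient mice spending *more* time near the target,
and is the one implemented here.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

RESILIENT = "RESILIENT"
SUSCEPTIBLE = "SUSCEPTIBLE"
UNDEFINED = "UNDEFINED"

RESILIENT_THRESHOLD = 1.1
SUSCEPTIBLE_THRESHOLD = 0.9


@dataclass
class ArenaTrial:
    """Two 3-min sessions of (x, y) positions (cm) at a fixed sample rate.

    ``sessions[0]`` is the empty-cage session, ``sessions[1]`` the
    target-present session. The cage sits against the midpoint of the
    y = arena_cm wall.
    """

    sessions: tuple[np.ndarray, np.ndarray]
    sample_rate: float
    arena_cm: float = 30.0
    cage_cm: float = 9.0

    def __post_init__(self) -> None:
        self.sessions = tuple(np.asarray(s, dtype=float) for s in self.sessions)
        for s in self.sessions:
            if s.ndim != 2 or s.shape[1] != 2:
                raise ValueError("each session must be an (n, 2) position array")
            if s.size and (s.min() < 0 or s.max() > self.arena_cm):
                raise ValueError("positions fall outside the arena bounds")

    @property
    def cage_rect(self) -> tuple[float, float, float, float]:
        """(x_lo, y_lo, x_hi, y_hi) of the cage footprint."""
        half = self.cage_cm / 2.0
        cx = self.arena_cm / 2.0
        return (cx - half, self.arena_cm - self.cage_cm, cx + half, self.arena_cm)


@dataclass
class InteractionResult:
    """Zone times, ratio and phenotype label for one animal's trial."""

    t_e: float
    t_f: float
    ratio: float          # NaN when t_e == 0
    label: str
    distance_moved_cm: float
    ratio_defined: bool


def _dist_to_rect(xy: np.ndarray, rect: tuple[float, float, float, float]) -> np.ndarray:
    """Euclidean distance from each point to the nearest point of a rectangle."""
    x_lo, y_lo, x_hi, y_hi = rect
    dx = np.maximum(np.maximum(x_lo - xy[:, 0], 0.0), xy[:, 0] - x_hi)
    dy = np.maximum(np.maximum(y_lo - xy[:, 1], 0.0), xy[:, 1] - y_hi)
    return np.hypot(dx, dy)


def time_in_zone(session: np.ndarray, cage_rect: tuple[float, float, float, float],
                 sample_rate: float, radius_cm: float = 15.0,
                 reference: str = "wall") -> float:
    """Seconds spent within ``radius_cm`` of the cage.

    ``reference="wall"`` measures to the nearest point of the cage
    footprint (geometry-faithful reading of "within 15 cm of the cage");
    ``"center"`` measures to the cage center.
    """
    session = np.asarray(session, dtype=float)
    if session.size == 0:
        raise ValueError("empty trajectory: no position samples")
    if reference == "wall":
        d = _dist_to_rect(session, cage_rect)
    elif reference == "center":
        cx = (cage_rect[0] + cage_rect[2]) / 2.0
        cy = (cage_rect[1] + cage_rect[3]) / 2.0
        d = np.hypot(session[:, 0] - cx, session[:, 1] - cy)
    else:
        raise ValueError("reference must be 'wall' or 'center'")
    return float(np.count_nonzero(d <= radius_cm)) / sample_rate


def interaction_ratio(t_e: float, t_f: float) -> tuple[float, str, bool]:
    """Interaction ratio t_f / t_e with phenotype label.

    Returns ``(ratio, label, defined)``. A zero empty-cage time leaves the
    ratio undefined (NaN, label UNDEFINED, defined=False) rather than
    silently infinite. Thresholds are strict: both 0.9 and 1.1 exactly map
    to UNDEFINED.
    """
    if not (0 <= t_e) or not (0 <= t_f):
        raise ValueError("zone times must be nonnegative")
    if t_e == 0:
        return (math.nan, UNDEFINED, False)
    ratio = t_f / t_e
    if ratio > RESILIENT_THRESHOLD:
        label = RESILIENT
    elif ratio < SUSCEPTIBLE_THRESHOLD:
        label = SUSCEPTIBLE
    else:
        label = UNDEFINED
    return (ratio, label, True)


def distance_moved(session: np.ndarray) -> float:
    """Total path length (cm) of a trajectory."""
    session = np.asarray(session, dtype=float)
    if session.shape[0] < 2:
        raise ValueError("distance requires at least 2 samples")
    steps = np.diff(session, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def analyze_trial(trial: ArenaTrial, radius_cm: float = 15.0,
                  reference: str = "wall") -> InteractionResult:
    """Full analysis of one two-session avoidance trial."""
    t_e = time_in_zone(trial.sessions[0], trial.cage_rect, trial.sample_rate,
                       radius_cm, reference)
    t_f = time_in_zone(trial.sessions[1], trial.cage_rect, trial.sample_rate,
                       radius_cm, reference)
    ratio, label, defined = interaction_ratio(t_e, t_f)
    dist = sum(distance_moved(s) for s in trial.sessions if s.shape[0] >= 2)
    return InteractionResult(t_e=t_e, t_f=t_f, ratio=ratio, label=label,
                             distance_moved_cm=dist, ratio_defined=defined)
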