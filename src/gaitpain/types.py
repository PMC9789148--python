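"""Core in-memory containers for gait trials.

A trial is a vertical trunk-acceleration trace (:class:`RawGaitSignal`)
plus, once detected or supplied, the per-side heel-strike and toe-off
times (:class:`GaitEventSeries`).  Everything downstream (spatiotemporal
parameters, regularity, phase coordination, ...) is computed from these two
objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecValidationError

__all__ = ["RawGaitSignal", "GaitEventSeries"]


@dataclass
class RawGaitSignal:
    """One walking trial's vertical trunk acceleration.

    Attributes
    ----------
    samples : ndarray
        Vertical acceleration, in g or m/s^2 (units only need to be
        consistent within a trial; most derived features are unit-free).
    sampling_rate : float
        Hz.
    walk_distance : float
        Distance covered by the trial, metres.
    trial_id : str
        Identifier used in logs and output tables.
    first_side : str
        Which leg strikes first ("left" or "right"); used by event
        detection to assign sides by alternation.
    """

    samples: np.ndarray
    sampling_rate: float
    walk_distance: float
    trial_id: str = "trial"
    first_side: str = "left"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2:
            raise SpecValidationError("RawGaitSignal.samples needs >= 2 samples")
        if not self.sampling_rate > 0:
            raise SpecValidationError("RawGaitSignal.sampling_rate must be > 0")
        if not self.walk_distance > 0:
            raise SpecValidationError("RawGaitSignal.walk_distance must be > 0")
        if self.first_side not in ("left", "right"):
            raise SpecValidationError("RawGaitSignal.first_side must be 'left' or 'right'")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


def _ordered(name: str, arr) -> np.ndarray:
    a = np.asarray(arr, dtype=float)
    if a.size > 1 and not (np.diff(a) > 0).all():
        raise SpecValidationError(f"GaitEventSeries.{name} must be strictly increasing")
    return a


@dataclass
class GaitEventSeries:
    """Ordered per-side gait-event times, in seconds from trial start."""

    left_heel_strikes: np.ndarray
    right_heel_strikes: np.ndarray
    left_toe_offs: np.ndarray = field(default_factory=lambda: np.array([]))
    right_toe_offs: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.left_heel_strikes = _ordered("left_heel_strikes", self.left_heel_strikes)
        self.right_heel_strikes = _ordered("right_heel_strikes", self.right_heel_strikes)
        self.left_toe_offs = _ordered("left_toe_offs", self.left_toe_offs)
        self.right_toe_offs = _ordered("right_toe_offs", self.right_toe_offs)

    def merged_heel_strikes(self) -> tuple[np.ndarray, np.ndarray]:
        """All heel strikes in time order, with a parallel array of sides."""
        times = np.concatenate([self.left_heel_strikes, self.right_heel_strikes])
        sides = np.concatenate([
            np.repeat("left", self.left_heel_strikes.size),
            np.repeat("right", self.right_heel_strikes.size),
        ])
        order = np.argsort(times, kind="stable")
        return times[order], sides[order]

    @property
    def n_steps(self) -> int:
        return self.left_heel_strikes.size + self.right_heel_strikes.size

    def heel_strikes(self, side: str) -> np.ndarray:
        return self.left_heel_strikes if side == "left" else self.right_heel_strikes

    def toe_offs(self, side: str) -> np.ndarray:
        return self.left_toe_offs if side == "left" else self.right_toe_offs
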