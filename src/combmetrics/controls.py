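"""Randomized virtual stimuli used as control populations.

Each experiment compares measurements on real stimuli against the same
measurements on computer-placed virtual stimuli: a virtual pit is dropped
uniformly within 10.0 mm of the real pit it shadows; a virtual pit pair has
a uniform location and orientation with centre separation uniform on
[5.0, 6.0] mm; a virtual V has uniform location and orientation with splay
uniform on [90, 152.2] deg.  All draws come from a seeded generator so a
control population is reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, PitPairStimulus, PitStimulus, VStimulus

VIRTUAL_PIT_RADIUS_MM = 10.0          # max displacement of a virtual pit
PAIR_SEPARATION_RANGE_MM = (5.0, 6.0)
V_SPLAY_RANGE_DEG = (90.0, 152.2)
DEFAULT_V_ARM_MM = 6.0                # arm length; only the bisector enters the metric

_MAX_REJECTIONS = 1000


class PlacementError(RuntimeError):
    """Bounds too small to place a virtual stimulus."""


@dataclass(frozen=True)
class Bounds:
    """Axis-aligned tab rectangle in world millimetres."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("empty bounds")

    def contains(self, xy) -> bool:
        x, y = xy
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([rng.uniform(self.x_min, self.x_max),
                         rng.uniform(self.y_min, self.y_max)])

    def inset(self, margin: float) -> "Bounds":
        return Bounds(self.x_min + margin, self.y_min + margin,
                      self.x_max - margin, self.y_max - margin)


class RandomStream:
    """A seeded source of randomness; identical seed => identical controls."""

    def __init__(self, seed: int | np.random.Generator | None = 0):
        if isinstance(seed, np.random.Generator):
            self.seed = None
            self.rng = seed
        else:
            self.seed = seed
            self.rng = np.random.default_rng(seed)

    def spawn(self) -> "RandomStream":
        return RandomStream(np.random.default_rng(self.rng.integers(2**31)))


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, RandomStream):
        return rng.rng
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _uniform_in_disc(rng: np.random.Generator, radius: float) -> np.ndarray:
    """Uniform draw in a disc: radial density proportional to r."""
    r = radius * math.sqrt(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([r * math.cos(theta), r * math.sin(theta)])


def virtual_pit(real: PitStimulus, bounds: Bounds, rng) -> PitStimulus:
    """A virtual pit uniform in the 10.0 mm disc around the real pit, in bounds."""
    g = _as_rng(rng)
    if not bounds.contains(real.centre):
        raise PlacementError("real pit lies outside the tab bounds")
    for _ in range(_MAX_REJECTIONS):
        c = np.asarray(real.centre) + _uniform_in_disc(g, VIRTUAL_PIT_RADIUS_MM)
        if bounds.contains(c):
            return PitStimulus(tuple(c), real.gauge_diameter_mm)
    raise PlacementError(
        f"no valid virtual-pit placement in {_MAX_REJECTIONS} rejections"
    )


def virtual_pit_pair(bounds: Bounds, rng) -> PitPairStimulus:
    """A virtual pit pair: uniform midpoint/orientation, separation U[5,6] mm."""
    g = _as_rng(rng)
    for _ in range(_MAX_REJECTIONS):
        mid = bounds.sample(g)
        theta = math.radians(g.uniform(0.0, 180.0))
        sep = g.uniform(*PAIR_SEPARATION_RANGE_MM)
        half = 0.5 * sep * np.array([math.cos(theta), math.sin(theta)])
        a, b = mid - half, mid + half
        if bounds.contains(a) and bounds.contains(b):
            return PitPairStimulus(tuple(a), tuple(b))
    raise PlacementError(
        f"no valid virtual-pair placement in {_MAX_REJECTIONS} rejections"
    )


def virtual_v(bounds: Bounds, rng, arm_mm: float = DEFAULT_V_ARM_MM) -> VStimulus:
    """A virtual V: uniform apex and bisector orientation, splay U[90, 152.2] deg.

    Arm length is a marking convenience only — the bisector orientation, not
    the arm extent, enters the divergence metric — so arms are allowed to
    poke past the tab bounds; only the apex is constrained.
    """
    g = _as_rng(rng)
    if arm_mm <= 0:
        raise GeometryError("arm length must be positive")
    for _ in range(_MAX_REJECTIONS):
        apex = bounds.sample(g)
        bis = g.uniform(0.0, 360.0)
        splay = g.uniform(*V_SPLAY_RANGE_DEG)
        a_ang = math.radians(bis + splay / 2.0)
        b_ang = math.radians(bis - splay / 2.0)
        end_a = apex + arm_mm * np.array([math.cos(a_ang), math.sin(a_ang)])
        end_b = apex + arm_mm * np.array([math.cos(b_ang), math.sin(b_ang)])
        if bounds.contains(apex):
            return VStimulus(tuple(end_a), tuple(apex), tuple(end_b))
    raise PlacementError(f"no valid virtual-V placement in {_MAX_REJECTIONS} rejections")


__all__ = [
    "Bounds", "RandomStream", "PlacementError", "virtual_pit",
    "virtual_pit_pair", "virtual_v", "VIRTUAL_PIT_RADIUS_MM",
    "PAIR_SEPARATION_RANGE_MM", "V_SPLAY_RANGE_DEG", "DEFAULT_V_ARM_MM",
]
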