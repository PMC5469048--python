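"""Shooting-task environment: joystick-to-cursor mappings, targets, screen geometry.

The task is one-dimensional: a target appears on a horizontal line and the
subject steers an invisible cursor with a joystick, then "shoots".  Each block
uses a fresh affine mapping ``c = m*j + s`` from joystick position ``j`` to
cursor position ``c``.  The block's optimal policy is ``j = w*·x + b*`` with
``w* = 1/m`` and ``b* = -s/m``; blocks are drawn by sampling ``w*`` and ``b*``
uniformly, so the learner-facing parameters (not ``m``/``s``) are uniform.
All dynamics live in screen coordinates spanning [-5, 5]; centimetres are a
display-only conversion.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "W_STAR_RANGE",
    "B_STAR_RANGE",
    "M_RANGE",
    "S_RANGE",
    "TARGET_BOUND",
    "TARGET_BOUND_ANALYTIC",
    "Mapping",
    "ScreenGeometry",
    "Block",
    "ExperimentDesign",
    "sample_mapping",
    "sample_targets",
    "apply_mapping",
    "optimal_action",
    "coord_to_cm",
]

#: Range of the optimal weight w* = 1/m (uniform sampling range and clip box).
W_STAR_RANGE = (0.25, 1.75)
#: Range of the optimal bias b* = -s/m.
B_STAR_RANGE = (-0.25, 0.25)
#: Induced range of the magnification m = 1/w*.
M_RANGE = (1.0 / W_STAR_RANGE[1], 1.0 / W_STAR_RANGE[0])  # 4/7 .. 4
#: Induced range of the shift s = -b*/w*.
S_RANGE = (-B_STAR_RANGE[1] / W_STAR_RANGE[0], B_STAR_RANGE[1] / W_STAR_RANGE[0])
#: Operative half-width of the target range, as used by the task program.
TARGET_BOUND = 0.4286
#: The exact always-reachable bound (1 - b*_max) / w*_max; exposed for analytics.
TARGET_BOUND_ANALYTIC = (1.0 - B_STAR_RANGE[1]) / W_STAR_RANGE[1]

_TOL = 1e-9


@dataclass(frozen=True)
class Mapping:
    """One block's joystick-to-cursor law ``c = m*j + s``.

    Parameters
    ----------
    m : float
        Magnification (dimensionless), in [4/7, 4].
    s : float
        Shift, in screen coordinates, in [-1, 1].
    """

    m: float
    s: float

    def __post_init__(self) -> None:
        if not (M_RANGE[0] - _TOL <= self.m <= M_RANGE[1] + _TOL):
            raise ValueError(f"magnification m={self.m} outside {M_RANGE}")
        if not (S_RANGE[0] - _TOL <= self.s <= S_RANGE[1] + _TOL):
            raise ValueError(f"shift s={self.s} outside {S_RANGE}")
        # m and s are coupled through (w*, b*); check the induced box too.
        w, b = 1.0 / self.m, -self.s / self.m
        if not (W_STAR_RANGE[0] - _TOL <= w <= W_STAR_RANGE[1] + _TOL):
            raise ValueError(f"implied w*={w} outside {W_STAR_RANGE}")
        if not (B_STAR_RANGE[0] - _TOL <= b <= B_STAR_RANGE[1] + _TOL):
            raise ValueError(f"implied b*={b} outside {B_STAR_RANGE}")

    @classmethod
    def from_optimal(cls, w_star: float, b_star: float) -> "Mapping":
        """Build a mapping from its optimal policy parameters."""
        return cls(m=1.0 / w_star, s=-b_star / w_star)

    @property
    def w_star(self) -> float:
        """Optimal weight 1/m."""
        return 1.0 / self.m

    @property
    def b_star(self) -> float:
        """Optimal bias -s/m."""
        return -self.s / self.m


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen coordinate system: [-5, 5] spans the 53-cm wide display."""

    coord_min: float = -5.0
    coord_max: float = 5.0
    width_cm: float = 53.0
    joystick_range_cm: float = 13.6

    @property
    def cm_per_unit(self) -> float:
        return self.width_cm / (self.coord_max - self.coord_min)


def sample_mapping(rng: np.random.Generator) -> Mapping:
    """Draw a block mapping: w* ~ U(0.25, 1.75), b* ~ U(-0.25, 0.25)."""
    w_star = rng.uniform(*W_STAR_RANGE)
    b_star = rng.uniform(*B_STAR_RANGE)
    return Mapping.from_optimal(w_star, b_star)


def sample_targets(rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` target positions uniformly from [-0.4286, 0.4286]."""
    if n < 1:
        raise ValueError(f"need at least one target, got n={n}")
    return rng.uniform(-TARGET_BOUND, TARGET_BOUND, size=n)


def apply_mapping(mapping: Mapping, j):
    """Cursor position for joystick position ``j`` (physically bounded to [-1, 1])."""
    j = np.asarray(j, dtype=float)
    if np.any(np.abs(j) > 1.0 + _TOL):
        raise ValueError("joystick position outside its physical range [-1, 1]")
    c = mapping.m * j + mapping.s
    return float(c) if c.ndim == 0 else c


def optimal_action(mapping: Mapping, x):
    """Joystick position that puts the cursor exactly on target ``x``."""
    x = np.asarray(x, dtype=float)
    j = (x - mapping.s) / mapping.m
    return float(j) if j.ndim == 0 else j


def coord_to_cm(geometry: ScreenGeometry, delta_coord: float) -> float:
    """Convert a coordinate distance to centimetres on the physical screen."""
    return delta_coord * geometry.cm_per_unit


# ---------------------------------------------------------------------------
# Experiment design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """A mapping plus its fixed target sequence."""

    mapping: Mapping
    targets: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", np.asarray(self.targets, dtype=float))
        if np.any(np.abs(self.targets) > TARGET_BOUND + _TOL):
            raise ValueError("targets outside the reachable range")

    @property
    def n_shots(self) -> int:
        return len(self.targets)


@dataclass
class ExperimentDesign:
    """The fixed block/mapping/target sequence shared by a subject and its doppelgangers.

    The protocol is 6 warmup blocks (excluded from analysis), 24 test blocks
    of 15 shots, and one 100-shot long block run after test block
    ``long_block_position`` (14 by default).
    """

    warmup_blocks: list = field(default_factory=list)
    test_blocks: list = field(default_factory=list)
    long_block: Block = None
    long_block_position: int = 14

    def __post_init__(self) -> None:
        for blk in self.test_blocks:
            if blk.n_shots != 15:
                raise ValueError("test blocks must have 15 shots")
        if self.long_block is not None and self.long_block.n_shots != 100:
            raise ValueError("the long block must have 100 shots")

    @property
    def n_warmup(self) -> int:
        return len(self.warmup_blocks)

    @property
    def n_test(self) -> int:
        return len(self.test_blocks)

    # -- construction -------------------------------------------------------

    @classmethod
    def sample(
        cls,
        rng: np.random.Generator,
        n_test: int = 24,
        n_warmup: int = 6,
        shots_per_block: int = 15,
        long_shots: int = 100,
        long_block_position: int = 14,
    ) -> "ExperimentDesign":
        """Draw a full design from the task distributions."""

        def _block(n):
            return Block(sample_mapping(rng), sample_targets(rng, n))

        warmup = [_block(shots_per_block) for _ in range(n_warmup)]
        test = [_block(shots_per_block) for _ in range(n_test)]
        long_block = _block(long_shots)
        return cls(warmup, test, long_block, long_block_position)

    # -- arrays used by the vectorized engine -------------------------------

    def test_arrays(self):
        """(m, s, targets) arrays over the 24 test blocks; targets is (24, 15)."""
        m = np.array([b.mapping.m for b in self.test_blocks])
        s = np.array([b.mapping.s for b in self.test_blocks])
        x = np.stack([b.targets for b in self.test_blocks])
        return m, s, x

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        def _blk(b: Block) -> dict:
            return {"m": b.mapping.m, "s": b.mapping.s, "targets": b.targets.tolist()}

        return {
            "warmup_blocks": [_blk(b) for b in self.warmup_blocks],
            "test_blocks": [_blk(b) for b in self.test_blocks],
            "long_block": _blk(self.long_block) if self.long_block else None,
            "long_block_position": self.long_block_position,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        def _blk(b):
            return Block(Mapping(b["m"], b["s"]), np.array(b["targets"]))

        return cls(
            [_blk(b) for b in d["warmup_blocks"]],
            [_blk(b) for b in d["test_blocks"]],
            _blk(d["long_block"]) if d["long_block"] else None,
            d["long_block_position"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentDesign":
        return cls.from_dict(json.loads(text))
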