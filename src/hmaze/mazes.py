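"""Maze geometries, ball kinematics and trial generation.

The H-maze is a two-level decision tree: a ball travels invisibly down an
entry hallway, turns left or right along a horizontal arm, then up or down
along a vertical arm, and stops at one of four exits (LU, LD, RU, RD).
Auditory clicks mark the junctions, so the two inter-click intervals carry
all the information about the traversed path.

Two geometry regimes are supported:

* ``human`` — arm lengths in degrees of visual angle (dva) drawn from
  {3..7} with each arm pair (L+R, LU+LD, RU+RD) summing to 10 dva, and ball
  speed 8 or 12 dva/s.  The shortest and longest arms (3 and 7 dva) thus map
  to traversal times of 0.25 and 0.875 s.
* ``rnn`` — six arm lengths i.i.d. uniform on {4,5,6,7} in abstract length
  units, speed fixed at 1 unit per timestep (4^6 = 4096 geometries).

Task variant 1 replaces the maze with four independent arms, each carrying a
ball that reflects off the arm ends; the agent must report which ball is at
an endpoint when the second cue sounds.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HUMAN_LENGTHS = (3, 4, 5, 6, 7)
HUMAN_PAIRS = ((3, 7), (4, 6), (5, 5), (6, 4), (7, 3))
HUMAN_SPEEDS = (8.0, 12.0)
RNN_LENGTHS = (4, 5, 6, 7)

ARM_NAMES = ("L", "R", "LU", "LD", "RU", "RD")


class UnsatisfiableConfigurationError(RuntimeError):
    """No valid trial exists for the requested variant-1 configuration."""


@dataclass(frozen=True)
class MazeGeometry:
    """Six arm lengths plus ball speed.

    Serialization order is fixed as (L, R, LU, LD, RU, RD).
    """

    arm_L: float
    arm_R: float
    arm_LU: float
    arm_LD: float
    arm_RU: float
    arm_RD: float
    speed: float
    regime: str = "human"

    def __post_init__(self) -> None:
        if self.regime == "human":
            for a in self.arms:
                if a not in HUMAN_LENGTHS:
                    raise ValueError(f"human-regime arm length {a} not in {HUMAN_LENGTHS}")
            for a, b in ((self.arm_L, self.arm_R), (self.arm_LU, self.arm_LD),
                         (self.arm_RU, self.arm_RD)):
                if a + b != 10:
                    raise ValueError("human-regime arm pairs must sum to 10 dva")
            if self.speed not in HUMAN_SPEEDS:
                raise ValueError(f"human-regime speed must be one of {HUMAN_SPEEDS}")
        elif self.regime == "rnn":
            for a in self.arms:
                if a not in RNN_LENGTHS:
                    raise ValueError(f"rnn-regime arm length {a} not in {RNN_LENGTHS}")
        else:
            raise ValueError(f"unknown regime {self.regime!r}")

    @property
    def arms(self) -> tuple[float, ...]:
        return (self.arm_L, self.arm_R, self.arm_LU, self.arm_LD,
                self.arm_RU, self.arm_RD)

    def arm(self, name: str) -> float:
        return self.arms[ARM_NAMES.index(name)]

    def horizontal_time(self, side: str) -> float:
        """Traversal time of horizontal arm 'L' or 'R'."""
        return traverse_time(self.arm(side), self.speed)

    def vertical_time(self, exit: str) -> float:
        """Traversal time of vertical arm 'LU', 'LD', 'RU' or 'RD'."""
        return traverse_time(self.arm(exit), self.speed)

    def exit_times(self) -> np.ndarray:
        """(t_h, t_v) per exit in order LU, LD, RU, RD; shape (4, 2)."""
        t_L, t_R = self.horizontal_time("L"), self.horizontal_time("R")
        return np.array([
            [t_L, self.vertical_time("LU")],
            [t_L, self.vertical_time("LD")],
            [t_R, self.vertical_time("RU")],
            [t_R, self.vertical_time("RD")],
        ])


@dataclass(frozen=True)
class Path:
    """True ball path: horizontal side then vertical direction."""

    horizontal: str  # 'L' or 'R'
    vertical: str    # 'U' or 'D'

    def __post_init__(self) -> None:
        if self.horizontal not in ("L", "R"):
            raise ValueError("horizontal must be 'L' or 'R'")
        if self.vertical not in ("U", "D"):
            raise ValueError("vertical must be 'U' or 'D'")

    @property
    def exit(self) -> str:
        return self.horizontal + self.vertical


ALL_PATHS = (Path("L", "U"), Path("L", "D"), Path("R", "U"), Path("R", "D"))


@dataclass(frozen=True)
class Trial:
    """One maze trial with ground-truth and measured inter-click intervals."""

    geometry: MazeGeometry
    true_path: Path
    ts1: float
    ts2: float
    tm1: float
    tm2: float
    seed_tag: int = 0


@dataclass(frozen=True)
class Variant1Trial:
    """Four independent reflecting-ball arms; one ball is at an endpoint."""

    lengths: tuple[float, float, float, float]
    speed: float
    target_arm: int
    n_reversals: int
    elapsed_time: float
    margin: float = 0.5

    def positions(self, t: float) -> np.ndarray:
        return np.array([variant1_position(a, self.speed, t) for a in self.lengths])


def traverse_time(length: float, speed: float) -> float:
    """Time for the ball to traverse an arm: length / speed.

    At the task's extremes, (3 dva, 12 dva/s) -> 0.25 s and
    (7 dva, 8 dva/s) -> 0.875 s.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if length < 0:
        raise ValueError("length must be non-negative")
    return length / speed


def sample_human_maze(rng: np.random.Generator) -> MazeGeometry:
    """Sample a human-regime H-maze uniformly over the 250 geometry×speed cells.

    Each of the three arm-pair slots (L/R, LU/LD, RU/RD) draws an ordered pair
    uniformly from (3,7), (4,6), (5,5), (6,4), (7,3); speed is 8 or 12 dva/s
    with equal probability.
    """
    (L, R) = HUMAN_PAIRS[rng.integers(len(HUMAN_PAIRS))]
    (LU, LD) = HUMAN_PAIRS[rng.integers(len(HUMAN_PAIRS))]
    (RU, RD) = HUMAN_PAIRS[rng.integers(len(HUMAN_PAIRS))]
    speed = HUMAN_SPEEDS[rng.integers(2)]
    return MazeGeometry(L, R, LU, LD, RU, RD, speed, regime="human")


def enumerate_human_mazes() -> list[MazeGeometry]:
    """All 250 human-regime geometry×speed combinations, lexicographic."""
    out = []
    for (L, R), (LU, LD), (RU, RD) in itertools.product(HUMAN_PAIRS, repeat=3):
        for speed in HUMAN_SPEEDS:
            out.append(MazeGeometry(L, R, LU, LD, RU, RD, speed, regime="human"))
    return out


def enumerate_rnn_mazes() -> list[MazeGeometry]:
    """All 4^6 = 4096 rnn-regime geometries, lexicographic in (L,R,LU,LD,RU,RD)."""
    return [
        MazeGeometry(*arms, speed=1.0, regime="rnn")
        for arms in itertools.product(RNN_LENGTHS, repeat=6)
    ]


def split_rnn_mazes(
    rng: np.random.Generator,
) -> tuple[list[MazeGeometry], list[MazeGeometry]]:
    """Random disjoint 75/25 split of the 4096 geometries: 3072 train, 1024 test."""
    mazes = enumerate_rnn_mazes()
    idx = rng.permutation(len(mazes))
    n_train = int(0.75 * len(mazes))
    train = [mazes[i] for i in idx[:n_train]]
    test = [mazes[i] for i in idx[n_train:]]
    return train, test


def sample_measured_intervals(
    ts: np.ndarray, w: float, rng: np.random.Generator
) -> np.ndarray:
    """Scalar-noise measurements tm = ts (1 + w eps), eps ~ N(0,1).

    Non-positive draws are rejected and resampled so measured intervals stay
    positive while preserving the scalar-noise shape near zero.
    """
    ts = np.asarray(ts, dtype=float)
    if w < 0:
        raise ValueError("Weber fraction must be non-negative")
    tm = ts * (1.0 + w * rng.standard_normal(ts.shape))
    bad = tm <= 0
    while np.any(bad):
        tm[bad] = ts[bad] * (1.0 + w * rng.standard_normal(int(bad.sum())))
        bad = tm <= 0
    return tm


def generate_trial(
    geometry: MazeGeometry,
    true_path: Path,
    w: float,
    rng: np.random.Generator,
    seed_tag: int = 0,
) -> Trial:
    """Generate one trial: ground-truth intervals from the true path's arms,
    measured intervals corrupted by scalar Gaussian noise with Weber fraction w.
    """
    ts1 = geometry.horizontal_time(true_path.horizontal)
    ts2 = geometry.vertical_time(true_path.exit)
    tm1, tm2 = sample_measured_intervals(np.array([ts1, ts2]), w, rng)
    return Trial(geometry, true_path, ts1, ts2, float(tm1), float(tm2), seed_tag)


def variant1_position(arm_length: float, speed: float, t) -> float | np.ndarray:
    """Position of a reflecting ball along its arm at time t.

    The ball starts at 0 moving in the positive direction and reverses at
    both ends, producing a triangle wave with period 2*arm_length/speed.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    d = np.mod(speed * t, 2.0 * arm_length)
    pos = np.where(d <= arm_length, d, 2.0 * arm_length - d)
    return float(pos) if pos.ndim == 0 else pos


def _endpoint_time(arm_length: float, speed: float, n_reversals: int) -> float:
    """Time at which the ball is at an endpoint after exactly n reversals."""
    return (n_reversals + 1) * arm_length / speed


def generate_variant1_trial(
    lengths: Sequence[float],
    speed: float,
    target_arm: int,
    rng: np.random.Generator,
    n_reversals: int | None = None,
    max_reversals: int = 3,
    margin: float = 0.5,
) -> Variant1Trial:
    """Build a variant-1 trial: the target ball is at an endpoint while the
    other three balls are interior by at least ``margin``.

    ``n_reversals`` fixes the number of direction reversals of the target
    ball before its endpoint arrival; when None, one of the valid reversal
    counts in [0, max_reversals] is chosen uniformly.
    """
    lengths = tuple(float(a) for a in lengths)
    if len(lengths) != 4:
        raise ValueError("variant 1 requires exactly four arms")
    if not 0 <= target_arm < 4:
        raise ValueError("target_arm must be in 0..3")

    candidates = ([n_reversals] if n_reversals is not None
                  else list(range(max_reversals + 1)))
    valid = []
    for k in candidates:
        t = _endpoint_time(lengths[target_arm], speed, k)
        others = [variant1_position(lengths[i], speed, t)
                  for i in range(4) if i != target_arm]
        if all(margin <= p <= lengths[i] - margin
               for p, i in zip(others, [i for i in range(4) if i != target_arm])):
            valid.append((k, t))
    if not valid:
        raise UnsatisfiableConfigurationError(
            f"no endpoint time with <= {max_reversals} reversals keeps the "
            f"other balls interior by {margin}")
    k, t = valid[rng.integers(len(valid))] if len(valid) > 1 else valid[0]
    return Variant1Trial(lengths, speed, target_arm, k, t, margin)


# ---------------------------------------------------------------------------
# Trial tables (CSV) and batch generation (JSON config)
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "trial_id", "regime", "arm_L", "arm_R", "arm_LU", "arm_LD", "arm_RU",
    "arm_RD", "speed", "true_h", "true_v", "ts1", "ts2", "tm1", "tm2", "seed",
]


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    rows = []
    for i, tr in enumerate(trials):
        g = tr.geometry
        rows.append({
            "trial_id": i, "regime": g.regime,
            "arm_L": g.arm_L, "arm_R": g.arm_R, "arm_LU": g.arm_LU,
            "arm_LD": g.arm_LD, "arm_RU": g.arm_RU, "arm_RD": g.arm_RD,
            "speed": g.speed, "true_h": tr.true_path.horizontal,
            "true_v": tr.true_path.vertical, "ts1": tr.ts1, "ts2": tr.ts2,
            "tm1": tr.tm1, "tm2": tr.tm2, "seed": tr.seed_tag,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[Trial]:
    out = []
    for _, row in df.iterrows():
        g = MazeGeometry(row.arm_L, row.arm_R, row.arm_LU, row.arm_LD,
                         row.arm_RU, row.arm_RD, row.speed, regime=row.regime)
        out.append(Trial(g, Path(row.true_h, row.true_v), row.ts1, row.ts2,
                         row.tm1, row.tm2, int(row.seed)))
    return out


def write_trials(trials: Iterable[Trial], path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def read_trials(path) -> list[Trial]:
    return frame_to_trials(pd.read_csv(path))


def generate_trial_batch(
    n_trials: int,
    w: float,
    seed: int,
    regime: str = "human",
) -> list[Trial]:
    """Generate a batch of trials per a JSON-style config (n_trials, regime, w, seed)."""
    rng = np.random.default_rng(seed)
    trials = []
    rnn_mazes = enumerate_rnn_mazes() if regime == "rnn" else None
    for i in range(n_trials):
        if regime == "human":
            g = sample_human_maze(rng)
        elif regime == "rnn":
            g = rnn_mazes[rng.integers(len(rnn_mazes))]
        else:
            raise ValueError(f"unknown regime {regime!r}")
        path = ALL_PATHS[rng.integers(4)]
        trials.append(generate_trial(g, path, w, rng, seed_tag=seed))
    return trials


def generate_from_config(config: dict | str) -> list[Trial]:
    """Batch generation from a JSON config string or dict with keys
    n_trials, regime, w, seed."""
    if isinstance(config, str):
        config = json.loads(config)
    return generate_trial_batch(
        n_trials=int(config["n_trials"]),
        w=float(config["w"]),
        seed=int(config["seed"]),
        regime=config.get("regime", "human"),
    )
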