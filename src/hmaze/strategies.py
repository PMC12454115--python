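"""Cognitive strategy models for the H-maze: optimal, hierarchical,
postdictive, counterfactual and mixed, plus the variant-1 ideal observer.

All strategies receive the two measured inter-click intervals (tm1, tm2), the
maze geometry and a Weber fraction w, and return one of the four exits
LU, LD, RU, RD:

* optimal — argmax of the joint likelihood p(tm1|t_h) p(tm2|t_v) over the
  four paths.
* hierarchical — commit to the horizontal arm from tm1 alone, then choose
  the committed side's vertical arm from tm2; no revision.
* postdictive — the horizontal commitment compares side-summed joint
  likelihoods; the vertical stage is hierarchical.
* counterfactual — hierarchical, but when the committed side's best vertical
  likelihood falls below a threshold theta, the intervals are recalled from
  memory (with noise mean beta and scalar sd alpha*tm) and the decision
  switches to the other side.
* mixed — hierarchical when the horizontal log-likelihood ratio is decisive
  (|LLR| > theta); otherwise uncommitted, choosing the exit whose vertical
  arm best matches tm2.

Ties are broken by the fixed exit order (LU, LD, RU, RD) in the scalar API,
and uniformly at random (seeded) inside Monte-Carlo choice distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from hmaze.mazes import MazeGeometry, Path, Variant1Trial, \
    sample_measured_intervals
from hmaze.timing import scalar_likelihood, scalar_loglik

EXITS = ("LU", "LD", "RU", "RD")
STRATEGIES = ("optimal", "hierarchical", "postdictive", "counterfactual", "mixed")

PROB_FLOOR = 1e-4  # per-exit floor before renormalization (finite-MC NLL guard)


@dataclass(frozen=True)
class StrategyParams:
    """Free parameters of the parameterized strategies.

    theta is the revision threshold of the counterfactual model on the
    log-likelihood scale (or the evidence threshold of the mixed model, in
    |log-likelihood-ratio| units); alpha scales the recall noise sd with the
    recalled interval; beta is the recall-noise mean bias in seconds.
    ``revise_trigger`` selects how revision is triggered: ``"threshold"``
    (default; revise when the committed side's best vertical log-likelihood
    is below theta) or ``"compare"`` (revise when the other side's best
    joint likelihood under the recalled intervals beats the committed
    side's — with perfect recall this reproduces the optimal model).
    """

    theta: float = -np.inf
    alpha: float = 0.0
    beta: float = 0.0
    revise_trigger: str = "threshold"

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.revise_trigger not in ("threshold", "compare"):
            raise ValueError("revise_trigger must be 'threshold' or 'compare'")


@dataclass(frozen=True)
class Decision:
    exit: str
    first_choice: str
    revised: bool = False
    recalled_tm1: Optional[float] = None
    recalled_tm2: Optional[float] = None

    def __post_init__(self):
        if self.revised and self.first_choice == self.exit[0]:
            raise ValueError("a revised decision must switch horizontal side")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _times(geometry: MazeGeometry):
    """(t_L, t_R, [t_LU, t_LD, t_RU, t_RD])."""
    t_L = geometry.horizontal_time("L")
    t_R = geometry.horizontal_time("R")
    t_v = np.array([geometry.vertical_time(e) for e in EXITS])
    return t_L, t_R, t_v


def joint_likelihood(tm1, tm2, path: Path, geometry: MazeGeometry, w: float):
    """Joint likelihood of both measurements under one path, assuming the two
    measurements are conditionally independent:
    p(tm1|t_h) * p(tm2|t_v)."""
    t_h = geometry.horizontal_time(path.horizontal)
    t_v = geometry.vertical_time(path.exit)
    return scalar_likelihood(tm1, t_h, w) * scalar_likelihood(tm2, t_v, w)


# ---------------------------------------------------------------------------
# vectorized batch deciders: tm1, tm2 are arrays (n,), return exit index (n,)
# ---------------------------------------------------------------------------

def _exit_logliks(tm1, tm2, geometry, w):
    """(n, 4) joint log-likelihood per exit in order LU, LD, RU, RD."""
    t_L, t_R, t_v = _times(geometry)
    ll1 = np.stack([scalar_loglik(tm1, t_L, w), scalar_loglik(tm1, t_R, w)], axis=-1)
    ll2 = np.stack([scalar_loglik(tm2, tv, w) for tv in t_v], axis=-1)
    side = np.array([0, 0, 1, 1])  # exit -> horizontal index
    return ll1[..., side] + ll2


def _argmax_tiebreak(scores: np.ndarray, rng: Optional[np.random.Generator]):
    """Row-wise argmax; ties go to the lowest index, or uniformly at random
    among the tied entries when an rng is supplied."""
    if rng is None:
        return np.argmax(scores, axis=-1)
    is_max = scores == scores.max(axis=-1, keepdims=True)
    noise = rng.random(scores.shape)
    return np.argmax(is_max * (1.0 + noise), axis=-1)


def optimal_decide_batch(tm1, tm2, geometry, w, rng=None):
    return _argmax_tiebreak(_exit_logliks(tm1, tm2, geometry, w), rng)


def _horizontal_stage(tm1, geometry, w, rng=None):
    """0 for left, 1 for right, by comparing p(tm1|t_L) vs p(tm1|t_R)."""
    t_L, t_R, _ = _times(geometry)
    ll = np.stack([scalar_loglik(tm1, t_L, w), scalar_loglik(tm1, t_R, w)], axis=-1)
    return _argmax_tiebreak(ll, rng)


def _vertical_stage(tm2, geometry, w, side, rng=None):
    """Exit index given a committed side (0=left, 1=right), from tm2 alone."""
    _, _, t_v = _times(geometry)
    ll2 = np.stack([scalar_loglik(tm2, tv, w) for tv in t_v], axis=-1)
    left = 2 * side  # base exit index of the committed side
    pair = np.stack([np.take_along_axis(ll2, left[..., None], axis=-1)[..., 0],
                     np.take_along_axis(ll2, left[..., None] + 1, axis=-1)[..., 0]],
                    axis=-1)
    return left + _argmax_tiebreak(pair, rng)


def hierarchical_decide_batch(tm1, tm2, geometry, w, rng=None):
    side = _horizontal_stage(tm1, geometry, w, rng)
    return _vertical_stage(tm2, geometry, w, side, rng)


def postdictive_decide_batch(tm1, tm2, geometry, w, rng=None):
    ll = _exit_logliks(tm1, tm2, geometry, w)
    # side-summed joint likelihoods (log-sum-exp per side)
    left = np.logaddexp(ll[..., 0], ll[..., 1])
    right = np.logaddexp(ll[..., 2], ll[..., 3])
    side = _argmax_tiebreak(np.stack([left, right], axis=-1), rng)
    return _vertical_stage(tm2, geometry, w, side, rng)


def counterfactual_decide_batch(
    tm1, tm2, geometry, w, params: StrategyParams,
    recall_eps1=None, recall_eps2=None, rng=None,
):
    """Counterfactual decisions on a batch.

    Recall noise draws can be supplied (``recall_eps``, standard normal) for
    common-random-number reuse across parameter values; otherwise they are
    drawn from ``rng``.
    """
    tm1 = np.asarray(tm1, float)
    tm2 = np.asarray(tm2, float)
    n = tm1.shape[0]
    if recall_eps1 is None:
        src = rng if rng is not None else np.random.default_rng()
        recall_eps1 = src.standard_normal(n)
        recall_eps2 = src.standard_normal(n)

    side = _horizontal_stage(tm1, geometry, w, rng)
    _, _, t_v = _times(geometry)
    ll2 = np.stack([scalar_loglik(tm2, tv, w) for tv in t_v], axis=-1)
    left = 2 * side
    chosen_pair = np.stack(
        [np.take_along_axis(ll2, left[..., None], axis=-1)[..., 0],
         np.take_along_axis(ll2, left[..., None] + 1, axis=-1)[..., 0]], axis=-1)
    X = chosen_pair.max(axis=-1)  # committed side's best vertical log-likelihood

    # recalled intervals: tm' = tm + Normal(beta, alpha * tm)
    rtm1 = tm1 + params.beta + params.alpha * tm1 * recall_eps1
    rtm2 = tm2 + params.beta + params.alpha * tm2 * recall_eps2

    if params.revise_trigger == "threshold":
        revise = X < params.theta
    else:  # "compare": switch when the other side's best joint beats ours
        llj = _exit_logliks(tm1, tm2, geometry, w)
        llj_recalled = _exit_logliks(rtm1, rtm2, geometry, w)
        own_best = np.where(side == 0, np.maximum(llj[..., 0], llj[..., 1]),
                            np.maximum(llj[..., 2], llj[..., 3]))
        other_best = np.where(side == 0,
                              np.maximum(llj_recalled[..., 2], llj_recalled[..., 3]),
                              np.maximum(llj_recalled[..., 0], llj_recalled[..., 1]))
        revise = other_best > own_best

    exit_stay = left + _argmax_tiebreak(chosen_pair, rng)
    other_side = 1 - side
    exit_switch = _vertical_stage(rtm2, geometry, w, other_side, rng)
    return np.where(revise, exit_switch, exit_stay), revise, rtm1, rtm2


def mixed_decide_batch(tm1, tm2, geometry, w, theta, rng=None):
    t_L, t_R, t_v = _times(geometry)
    llr = scalar_loglik(tm1, t_L, w) - scalar_loglik(tm1, t_R, w)
    side = _horizontal_stage(tm1, geometry, w, rng)
    hier = _vertical_stage(tm2, geometry, w, side, rng)
    ll2 = np.stack([scalar_loglik(tm2, tv, w) for tv in t_v], axis=-1)
    vert_only = _argmax_tiebreak(ll2, rng)
    return np.where(np.abs(llr) > theta, hier, vert_only)


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def _as_decision(exit_idx: int, first_side: int, revised=False,
                 rtm1=None, rtm2=None) -> Decision:
    return Decision(EXITS[exit_idx], "LR"[first_side], bool(revised),
                    rtm1, rtm2)


def optimal_decide(tm1, tm2, geometry, w) -> Decision:
    idx = int(optimal_decide_batch(np.atleast_1d(tm1), np.atleast_1d(tm2),
                                   geometry, w)[0])
    return _as_decision(idx, idx // 2)


def hierarchical_decide(tm1, tm2, geometry, w) -> Decision:
    idx = int(hierarchical_decide_batch(np.atleast_1d(tm1), np.atleast_1d(tm2),
                                        geometry, w)[0])
    return _as_decision(idx, idx // 2)


def postdictive_decide(tm1, tm2, geometry, w) -> Decision:
    idx = int(postdictive_decide_batch(np.atleast_1d(tm1), np.atleast_1d(tm2),
                                       geometry, w)[0])
    return _as_decision(idx, idx // 2)


def counterfactual_decide(
    tm1, tm2, geometry, params: StrategyParams, w: float,
    rng: Optional[np.random.Generator] = None,
) -> Decision:
    rng = rng if rng is not None else np.random.default_rng()
    first = int(_horizontal_stage(np.atleast_1d(tm1), geometry, w)[0])
    eps1 = rng.standard_normal(1)
    eps2 = rng.standard_normal(1)
    idx, revised, rtm1, rtm2 = counterfactual_decide_batch(
        np.atleast_1d(tm1), np.atleast_1d(tm2), geometry, w, params,
        recall_eps1=eps1, recall_eps2=eps2)
    revised = bool(revised[0])
    return Decision(EXITS[int(idx[0])], "LR"[first], revised,
                    float(rtm1[0]) if revised else None,
                    float(rtm2[0]) if revised else None)


def mixed_decide(tm1, tm2, geometry, w, theta) -> Decision:
    idx = int(mixed_decide_batch(np.atleast_1d(tm1), np.atleast_1d(tm2),
                                 geometry, w, theta)[0])
    return _as_decision(idx, idx // 2)


def decide_batch(strategy: str, tm1, tm2, geometry, w,
                 params: Optional[StrategyParams] = None,
                 recall_eps1=None, recall_eps2=None, rng=None) -> np.ndarray:
    """Uniform entry point: exit indices for a batch of measurements."""
    if strategy == "optimal":
        return optimal_decide_batch(tm1, tm2, geometry, w, rng)
    if strategy == "hierarchical":
        return hierarchical_decide_batch(tm1, tm2, geometry, w, rng)
    if strategy == "postdictive":
        return postdictive_decide_batch(tm1, tm2, geometry, w, rng)
    if strategy == "counterfactual":
        params = params if params is not None else StrategyParams()
        idx, _, _, _ = counterfactual_decide_batch(
            tm1, tm2, geometry, w, params, recall_eps1, recall_eps2, rng)
        return idx
    if strategy == "mixed":
        theta = params.theta if params is not None else 0.0
        return mixed_decide_batch(tm1, tm2, geometry, w, theta, rng)
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def choice_distribution(
    strategy: str,
    geometry: MazeGeometry,
    true_path: Path,
    w: float,
    params: Optional[StrategyParams] = None,
    n_mc: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    floor: float = PROB_FLOOR,
) -> np.ndarray:
    """Monte-Carlo exit-choice probabilities of a strategy on one condition.

    Simulates n_mc scalar-noise measurement pairs from the true path, applies
    the strategy (with seeded uniform tie-breaks), floors each cell at
    ``floor`` and renormalizes so a finite sample never yields a zero
    probability.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    ts1 = geometry.horizontal_time(true_path.horizontal)
    ts2 = geometry.vertical_time(true_path.exit)
    tm = sample_measured_intervals(
        np.tile([ts1, ts2], (n_mc, 1)), w, rng)
    idx = decide_batch(strategy, tm[:, 0], tm[:, 1], geometry, w, params, rng=rng)
    p = np.bincount(idx, minlength=4) / n_mc
    p = np.maximum(p, floor)
    return p / p.sum()


def choice_probability_table(
    geometries,
    strategies=STRATEGIES,
    w: float = 0.15,
    params: Optional[StrategyParams] = None,
    n_mc: int = 4000,
    seed: int = 0,
):
    """Exit-choice probabilities per (geometry, true path, strategy), as a
    table ready for CSV export."""
    import pandas as pd
    from hmaze.mazes import ALL_PATHS
    rows = []
    for gi, g in enumerate(geometries):
        for path in ALL_PATHS:
            for strat in strategies:
                rng = np.random.default_rng([seed, gi])
                p = choice_distribution(strat, g, path, w, params=params,
                                        n_mc=n_mc, rng=rng)
                rows.append({
                    "arm_L": g.arm_L, "arm_R": g.arm_R, "arm_LU": g.arm_LU,
                    "arm_LD": g.arm_LD, "arm_RU": g.arm_RU,
                    "arm_RD": g.arm_RD, "speed": g.speed,
                    "true_h": path.horizontal, "true_v": path.vertical,
                    "strategy": strat,
                    **{f"p_{e}": p[i] for i, e in enumerate(EXITS)},
                })
    return pd.DataFrame(rows)


def variant1_ideal_likelihoods(
    trial: Variant1Trial, w: float,
    tm_elapsed: Optional[float] = None,
    max_reversals: int = 3,
) -> np.ndarray:
    """Ideal-observer arm likelihoods for the four-reflecting-balls task.

    For each arm, endpoint-arrival times are enumerated up to
    ``max_reversals`` reversals and the scalar-noise likelihood of the
    (measured) elapsed time is summed over them.  ``tm_elapsed`` defaults to
    the trial's true elapsed time (a noiseless observer).
    """
    tm = trial.elapsed_time if tm_elapsed is None else tm_elapsed
    out = np.zeros(4)
    for i, a in enumerate(trial.lengths):
        taus = [(k + 1) * a / trial.speed for k in range(max_reversals + 1)]
        out[i] = sum(scalar_likelihood(tm, tau, w) for tau in taus)
    return out
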