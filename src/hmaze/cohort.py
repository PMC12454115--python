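"""End-to-end synthetic behavioural datasets for every task in the family.

A :class:`ParticipantProfile` bundles one simulated participant's cognitive
strategy, timing noise (Weber fraction w), lapse rate and session spec, and
:func:`simulate_session` produces the response table the corresponding
analysis consumes:

* ``tmaze`` — two-interval discrimination; choices from the criterion rule
  with scalar noise and lapses (the dataset the Weber-fraction fit expects).
* ``hmaze`` — four-exit maze inference; choices from the profile's strategy.
* ``variant1`` — four independent reflecting balls; the profile acts as an
  ideal observer with scalar noise on the elapsed time.
* ``variant2_c1`` / ``variant2_c2`` — half-maze discrimination; condition 2
  (cues before maze) inflates the condition-level noise, emulating
  counterfactual processing noise.
* ``variant3`` — half-maze with an optional reveal of the hidden side;
  reveal decisions follow a bounded-rationality policy whose threshold
  decreases with the profile's recall-noise scale alpha.

Session sizes default to the human task battery: 168 T-maze, 540 H-maze,
170 variant-1, 160 trials per variant-2 condition, 324 variant-3 trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from hmaze.mazes import (
    ALL_PATHS, HUMAN_LENGTHS, HUMAN_PAIRS, HUMAN_SPEEDS,
    generate_trial, generate_variant1_trial, sample_human_maze,
    sample_measured_intervals,
)
from hmaze.strategies import (
    EXITS, STRATEGIES, StrategyParams, decide_batch, variant1_ideal_likelihoods,
)
from hmaze.timing import likelihood_crossing, scalar_loglik
from hmaze.fitting import attach_choices

__all__ = ["ParticipantProfile", "simulate_session", "simulate_cohort",
           "variant3_reveal_policy", "SESSION_SIZES"]

SESSION_SIZES = {
    "tmaze": 168, "hmaze": 540, "variant1": 170,
    "variant2_c1": 160, "variant2_c2": 160, "variant3": 324,
}

TASKS = tuple(SESSION_SIZES)


@dataclass
class ParticipantProfile:
    """One simulated participant: strategy, noise parameters and session spec."""

    strategy: str = "counterfactual"
    params: StrategyParams = field(default_factory=StrategyParams)
    w: float = 0.15
    lapse: float = 0.0
    task: str = "hmaze"
    n_trials: Optional[int] = None
    seed: int = 0
    sigma_c1: float = 0.08        # variant-2 condition-1 noise (s)
    sigma_inflation: float = 1.2  # condition-2 noise multiplier
    reveal_theta0: float = 0.5    # variant-3 policy intercept (log-lik units)
    reveal_slope: float = 4.0     # policy sensitivity to recall-noise alpha

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected {TASKS}")
        if self.n_trials is None:
            self.n_trials = SESSION_SIZES[self.task]
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")

    def to_json(self) -> dict:
        d = asdict(self)
        d["params"] = {k: (None if isinstance(v, float) and not np.isfinite(v)
                           else v)
                       for k, v in d["params"].items()}
        return d


def variant3_reveal_policy(
    X: float, alpha: float, theta0: float = 0.5, slope: float = 4.0,
) -> bool:
    """Bounded-rationality reveal rule for the optional-reveal task.

    Reveal the hidden half iff the visible side's best vertical
    log-likelihood X falls below a threshold that decreases linearly with
    the recall-noise scale alpha: reveal iff X < theta0 - slope * alpha.
    Noisier counterfactual processing therefore lowers the reveal rate.
    """
    return bool(X < theta0 - slope * alpha)


def _sample_pair_times(rng) -> tuple[float, float, float]:
    """One arm pair and speed; returns (t_a, t_b, speed) in seconds."""
    a, b = HUMAN_PAIRS[rng.integers(len(HUMAN_PAIRS))]
    speed = HUMAN_SPEEDS[rng.integers(2)]
    return a / speed, b / speed, speed


def _simulate_tmaze(profile: ParticipantProfile, rng) -> pd.DataFrame:
    rows = []
    for i in range(profile.n_trials):
        ta, tb, speed = _sample_pair_times(rng)
        t1, t2 = min(ta, tb), max(ta, tb)
        true_arm = int(rng.integers(2)) + 1  # 1 -> t1 is the true interval
        ts = t1 if true_arm == 1 else t2
        tm = float(sample_measured_intervals(np.array([ts]), profile.w, rng)[0])
        if rng.random() < profile.lapse:
            choice = int(rng.integers(2)) + 1
        else:
            tc = likelihood_crossing(t1, t2, profile.w)
            if t1 == t2:
                choice = int(rng.integers(2)) + 1
            else:
                choice = 1 if tm < tc else 2
        rows.append({"trial_id": i, "t1": t1, "t2": t2, "speed": speed,
                     "true_arm": true_arm, "choice": choice,
                     "correct": choice == true_arm})
    return pd.DataFrame(rows)


def _simulate_hmaze(profile: ParticipantProfile, rng) -> pd.DataFrame:
    trials, choices = [], []
    for i in range(profile.n_trials):
        g = sample_human_maze(rng)
        path = ALL_PATHS[rng.integers(4)]
        tr = generate_trial(g, path, profile.w, rng, seed_tag=profile.seed)
        idx = decide_batch(profile.strategy, np.array([tr.tm1]),
                           np.array([tr.tm2]), g, profile.w,
                           profile.params, rng=rng)
        trials.append(tr)
        choices.append(EXITS[int(idx[0])])
    df = attach_choices(trials, choices)
    df["correct"] = df["choice"] == df["true_h"].str.cat(df["true_v"])
    return df


def _simulate_variant1(profile: ParticipantProfile, rng) -> pd.DataFrame:
    rows = []
    for i in range(profile.n_trials):
        while True:
            lengths = [HUMAN_LENGTHS[rng.integers(len(HUMAN_LENGTHS))]
                       for _ in range(4)]
            speed = HUMAN_SPEEDS[rng.integers(2)]
            target = int(rng.integers(4))
            try:
                tr = generate_variant1_trial(lengths, speed, target, rng)
                break
            except Exception:
                continue
        tm = float(sample_measured_intervals(
            np.array([tr.elapsed_time]), profile.w, rng)[0])
        lik = variant1_ideal_likelihoods(tr, profile.w, tm_elapsed=tm)
        lik = lik * (1.0 + 1e-12 * rng.random(4))  # uniform tie-break
        choice = int(np.argmax(lik))
        rows.append({"trial_id": i, "len_0": lengths[0], "len_1": lengths[1],
                     "len_2": lengths[2], "len_3": lengths[3], "speed": speed,
                     "target_arm": target, "n_reversals": tr.n_reversals,
                     "elapsed_time": tr.elapsed_time, "tm_elapsed": tm,
                     "choice": choice, "correct": choice == target})
    return pd.DataFrame(rows)


def _simulate_variant2(profile: ParticipantProfile, rng,
                       condition: int) -> pd.DataFrame:
    sigma = profile.sigma_c1 * (profile.sigma_inflation if condition == 2 else 1.0)
    rows = []
    for i in range(profile.n_trials):
        ta, tb, speed = _sample_pair_times(rng)
        t1, t2 = min(ta, tb), max(ta, tb)
        from hmaze.timing import variant2_correct_prob
        p = float(variant2_correct_prob(t1, t2, sigma))
        rows.append({"trial_id": i, "condition": condition, "t1": t1, "t2": t2,
                     "speed": speed, "correct": bool(rng.random() < p)})
    return pd.DataFrame(rows)


def _simulate_variant3(profile: ParticipantProfile, rng) -> pd.DataFrame:
    """Half-maze with optional reveal; the hidden side is always the right."""
    rows = []
    alpha = profile.params.alpha
    beta = profile.params.beta
    for i in range(profile.n_trials):
        g = sample_human_maze(rng)
        path = ALL_PATHS[rng.integers(4)]
        tr = generate_trial(g, path, profile.w, rng, seed_tag=profile.seed)
        # visible side is left: exits LU, LD at indices 0, 1
        t_vis = [g.vertical_time("LU"), g.vertical_time("LD")]
        ll_vis = [float(scalar_loglik(tr.tm2, t, profile.w)) for t in t_vis]
        X = max(ll_vis)
        reveal = variant3_reveal_policy(X, alpha, profile.reveal_theta0,
                                        profile.reveal_slope)
        if not reveal:
            choice = EXITS[int(np.argmax(ll_vis + 1e-12 * rng.random(2)))]
        else:
            # counterfactual evaluation of the revealed side with recall noise
            rtm2 = tr.tm2 + beta + alpha * tr.tm2 * rng.standard_normal()
            t_hid = [g.vertical_time("RU"), g.vertical_time("RD")]
            ll_hid = [float(scalar_loglik(rtm2, t, profile.w)) for t in t_hid]
            scores = np.array(ll_vis + ll_hid) + 1e-12 * rng.random(4)
            choice = EXITS[[0, 1, 2, 3][int(np.argmax(scores))]]
        true_exit = path.exit
        rows.append({"trial_id": i, "arm_L": g.arm_L, "arm_R": g.arm_R,
                     "arm_LU": g.arm_LU, "arm_LD": g.arm_LD,
                     "arm_RU": g.arm_RU, "arm_RD": g.arm_RD,
                     "speed": g.speed, "true_exit": true_exit,
                     "hidden_correct": path.horizontal == "R",
                     "X_visible": X, "reveal": reveal, "choice": choice,
                     "correct": choice == true_exit})
    return pd.DataFrame(rows)


def simulate_session(profile: ParticipantProfile) -> pd.DataFrame:
    """Simulate one participant session; reproducible from the profile seed."""
    rng = np.random.default_rng([profile.seed, TASKS.index(profile.task)])
    if profile.task == "tmaze":
        return _simulate_tmaze(profile, rng)
    if profile.task == "hmaze":
        return _simulate_hmaze(profile, rng)
    if profile.task == "variant1":
        return _simulate_variant1(profile, rng)
    if profile.task == "variant2_c1":
        return _simulate_variant2(profile, rng, condition=1)
    if profile.task == "variant2_c2":
        return _simulate_variant2(profile, rng, condition=2)
    if profile.task == "variant3":
        return _simulate_variant3(profile, rng)
    raise ValueError(f"unknown task {profile.task!r}")


def simulate_cohort(
    profiles: Sequence[ParticipantProfile],
) -> tuple[list[pd.DataFrame], dict]:
    """Simulate a cohort; returns per-participant tables and a manifest."""
    tables = [simulate_session(p) for p in profiles]
    manifest = {"n_participants": len(profiles),
                "profiles": [p.to_json() for p in profiles]}
    return tables, manifest


def cohort_from_json(spec: str | list) -> list[ParticipantProfile]:
    """Parse a cohort spec (JSON string or list of dicts) into profiles."""
    if isinstance(spec, str):
        spec = json.loads(spec)
    out = []
    for d in spec:
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            p = {k: (v if v is not None else -np.inf)
                 for k, v in d["params"].items()}
            d["params"] = StrategyParams(**p)
        out.append(ParticipantProfile(**d))
    return out
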