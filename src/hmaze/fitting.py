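"""Maximum-likelihood fitting of strategy parameters and cross-validated
negative-log-likelihood model comparison.

The Weber fraction w is measured independently (T-maze) and held fixed here,
so the optimal, hierarchical and postdictive strategies have no free
parameters and are evaluated predictively.  The counterfactual strategy fits
its revision threshold theta and recall-noise parameters (alpha, beta); the
mixed strategy fits its evidence threshold.

The per-trial choice model p(exit | geometry, true path, strategy, params)
is estimated by Monte Carlo over scalar-noise measurement draws.  Draws are
cached per unique trial condition and reused across parameter values (common
random numbers), which makes the negative log-likelihood deterministic given
the seed and cheap to re-evaluate inside the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from hmaze.mazes import Trial, sample_measured_intervals, \
    trials_to_frame
from hmaze.strategies import EXITS, STRATEGIES, PROB_FLOOR, StrategyParams
from hmaze.timing import scalar_loglik

__all__ = ["ModelComparisonResult", "ChoiceModelCache", "response_nll",
           "fit_strategy", "crossval_compare", "attach_choices"]

_TIE_SCALE = 1e-9  # magnitude of the random tie-breaking jitter on log-likelihoods

FREE_PARAMS = {
    "optimal": (), "hierarchical": (), "postdictive": (),
    "counterfactual": ("theta", "alpha", "beta"), "mixed": ("theta",),
}


@dataclass
class ModelComparisonResult:
    """Cross-validated model comparison over a set of strategies."""

    strategies: list[str]
    mean_heldout_nll: dict[str, float]          # nats per trial
    fold_params: dict[str, list[dict]]          # fitted parameters per fold
    fold_nll: dict[str, list[float]]            # held-out NLL (total) per fold
    fold_assignment: np.ndarray                 # fold index per trial
    seed: int

    def best(self) -> str:
        return min(self.mean_heldout_nll, key=self.mean_heldout_nll.get)


def attach_choices(trials: Sequence[Trial], choices: Sequence[str]) -> pd.DataFrame:
    """Response table: trial table plus an exit-choice column."""
    df = trials_to_frame(trials)
    df["choice"] = list(choices)
    return df


class ChoiceModelCache:
    """Monte-Carlo choice-model evaluator over a response dataset.

    Groups trials by unique condition (geometry x true path), draws ``n_mc``
    scalar-noise measurement pairs and recall-noise deviates per condition,
    and evaluates each strategy's exit-choice probabilities vectorized over
    all conditions at once.  Exact likelihood ties (symmetric mazes) are
    broken by a pre-drawn jitter far below any genuine likelihood difference,
    so tied exits are chosen uniformly.
    """

    def __init__(self, dataset: pd.DataFrame, w: float, n_mc: int, seed: int):
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        if "choice" in dataset.columns:
            bad = ~dataset["choice"].isin(EXITS)
            if bad.any():
                raise ValueError(f"choices outside exit vocabulary: "
                                 f"{dataset.loc[bad, 'choice'].unique()}")
        self.w = float(w)
        self.n_mc = int(n_mc)
        self.seed = int(seed)
        self.df = dataset.reset_index(drop=True)

        arm_cols = ["arm_L", "arm_R", "arm_LU", "arm_LD", "arm_RU", "arm_RD"]
        cond_mat = np.column_stack([
            self.df[arm_cols].to_numpy(float),
            self.df["speed"].to_numpy(float),
            (self.df["true_h"] == "R").to_numpy(float),
            (self.df["true_v"] == "D").to_numpy(float),
        ])
        conds, self.trial_to_cond = np.unique(cond_mat, axis=0,
                                              return_inverse=True)
        U = len(conds)

        speed = conds[:, 6]
        self.t_h = conds[:, 0:2] / speed[:, None]
        self.t_v = conds[:, 2:6] / speed[:, None]
        true_right = conds[:, 7].astype(int)
        true_down = conds[:, 8].astype(int)
        ts1 = self.t_h[np.arange(U), true_right]
        ts2 = self.t_v[np.arange(U), 2 * true_right + true_down]

        rng = np.random.default_rng([seed, 0x5eed])
        self.tm1 = sample_measured_intervals(
            np.tile(ts1[:, None], (1, n_mc)), w, rng)
        self.tm2 = sample_measured_intervals(
            np.tile(ts2[:, None], (1, n_mc)), w, rng)
        self.eps1 = rng.standard_normal((U, n_mc))
        self.eps2 = rng.standard_normal((U, n_mc))
        tie1 = rng.random((U, n_mc, 2)) * _TIE_SCALE
        tie2 = rng.random((U, n_mc, 4)) * _TIE_SCALE

        # params-independent precomputations, all (U, n_mc, .)
        self.ll1 = np.stack([scalar_loglik(self.tm1, self.t_h[:, [i]], w)
                             for i in range(2)], axis=-1) + tie1
        self.ll2 = np.stack([scalar_loglik(self.tm2, self.t_v[:, [i]], w)
                             for i in range(4)], axis=-1) + tie2
        self.tie2 = tie2
        self.side = np.argmax(self.ll1, axis=-1)                    # (U, n_mc)
        self.llr = self.ll1[..., 0] - self.ll1[..., 1]
        base = 2 * self.side
        pair = np.stack([np.take_along_axis(self.ll2, base[..., None], -1)[..., 0],
                         np.take_along_axis(self.ll2, base[..., None] + 1, -1)[..., 0]],
                        axis=-1)
        self.X = pair.max(axis=-1)            # committed side's best vertical ll
        self.exit_hier = base + np.argmax(pair, axis=-1)
        joint = self.ll1[..., [0, 0, 1, 1]] + self.ll2
        self.exit_optimal = np.argmax(joint, axis=-1)
        side_post = np.argmax(np.stack(
            [np.logaddexp(joint[..., 0], joint[..., 1]),
             np.logaddexp(joint[..., 2], joint[..., 3])], axis=-1), axis=-1)
        basep = 2 * side_post
        pairp = np.stack([np.take_along_axis(self.ll2, basep[..., None], -1)[..., 0],
                          np.take_along_axis(self.ll2, basep[..., None] + 1, -1)[..., 0]],
                         axis=-1)
        self.exit_postdictive = basep + np.argmax(pairp, axis=-1)
        self.exit_vertical_only = np.argmax(self.ll2, axis=-1)
        # opposite-side vertical base times, for counterfactual switches
        self.other_base = 2 * (1 - self.side)
        self.t_other_up = np.take_along_axis(
            np.broadcast_to(self.t_v[:, None, :], self.ll2.shape),
            self.other_base[..., None], -1)[..., 0]
        self.t_other_dn = np.take_along_axis(
            np.broadcast_to(self.t_v[:, None, :], self.ll2.shape),
            self.other_base[..., None] + 1, -1)[..., 0]
        self._memo: dict = {}

    # -- strategy exit samples -------------------------------------------------

    def _counterfactual_exits(self, theta, alpha, beta):
        revise = self.X < theta
        rtm2 = self.tm2 + beta + alpha * self.tm2 * self.eps2
        ll_up = scalar_loglik(rtm2, self.t_other_up, self.w) + \
            np.take_along_axis(self.tie2, self.other_base[..., None], -1)[..., 0]
        ll_dn = scalar_loglik(rtm2, self.t_other_dn, self.w) + \
            np.take_along_axis(self.tie2, self.other_base[..., None] + 1, -1)[..., 0]
        exit_switch = self.other_base + (ll_dn > ll_up)
        return np.where(revise, exit_switch, self.exit_hier)

    def exit_samples(self, strategy: str, params: Optional[StrategyParams]) -> np.ndarray:
        if strategy == "optimal":
            return self.exit_optimal
        if strategy == "hierarchical":
            return self.exit_hier
        if strategy == "postdictive":
            return self.exit_postdictive
        if strategy == "mixed":
            theta = params.theta if params is not None else 0.0
            return np.where(np.abs(self.llr) > theta,
                            self.exit_hier, self.exit_vertical_only)
        if strategy == "counterfactual":
            p = params if params is not None else StrategyParams()
            return self._counterfactual_exits(p.theta, p.alpha, p.beta)
        raise ValueError(f"unknown strategy {strategy!r}; expected {STRATEGIES}")

    def probs(self, strategy: str, params: Optional[StrategyParams] = None,
              floor: float = PROB_FLOOR) -> np.ndarray:
        """(U, 4) exit-choice probabilities per unique condition."""
        key = (strategy, None if params is None
               else (round(params.theta, 12), round(params.alpha, 12),
                     round(params.beta, 12), params.revise_trigger))
        if key in self._memo:
            return self._memo[key]
        exits = self.exit_samples(strategy, params)
        U = exits.shape[0]
        flat = (np.arange(U)[:, None] * 4 + exits).ravel()
        p = np.bincount(flat, minlength=U * 4).reshape(U, 4) / self.n_mc
        p = np.maximum(p, floor)
        p /= p.sum(axis=1, keepdims=True)
        self._memo[key] = p
        return p

    def nll(self, strategy: str, params: Optional[StrategyParams] = None,
            trial_mask: Optional[np.ndarray] = None) -> float:
        """Total NLL of the dataset's observed choices (nats)."""
        choice_idx = self.df["choice"].map({e: i for i, e in enumerate(EXITS)})
        choice_idx = choice_idx.to_numpy(int)
        p = self.probs(strategy, params)
        per_trial = -np.log(p[self.trial_to_cond, choice_idx])
        if trial_mask is not None:
            per_trial = per_trial[trial_mask]
        return float(per_trial.sum())


def response_nll(
    strategy: str,
    params: Optional[StrategyParams],
    dataset: pd.DataFrame,
    w: float,
    n_mc: int = 4000,
    seed: int = 0,
    cache: Optional[ChoiceModelCache] = None,
) -> float:
    """Negative log-likelihood (nats) of observed exit choices under a strategy.

    Deterministic given the seed: measurement and recall-noise draws are
    cached per unique trial condition.
    """
    cache = cache if cache is not None else ChoiceModelCache(dataset, w, n_mc, seed)
    return cache.nll(strategy, params)


def _fit_counterfactual(cache: ChoiceModelCache, mask, maxiter=120):
    # coarse grid over theta at quantiles of the committed side's best
    # vertical log-likelihood (the NLL is piecewise-flat in theta)
    xs = cache.X if mask is None else cache.X[np.unique(cache.trial_to_cond[mask])]
    qs = np.quantile(xs, np.linspace(0.02, 0.98, 13))
    best = None
    for theta in qs:
        for alpha in (0.05, 0.3):
            nll = cache.nll("counterfactual",
                            StrategyParams(theta, alpha, 0.0), mask)
            if best is None or nll < best[1]:
                best = ((theta, alpha, 0.0), nll)

    def objective(x):
        theta, a, beta = x
        return cache.nll("counterfactual",
                         StrategyParams(theta, abs(a), beta), mask)

    res = optimize.minimize(objective, np.array(best[0]), method="Nelder-Mead",
                            options={"maxfev": maxiter, "xatol": 1e-3,
                                     "fatol": 1e-3})
    x = res.x if res.fun < best[1] else np.array(best[0])
    nll = min(float(res.fun), best[1])
    return StrategyParams(float(x[0]), float(abs(x[1])), float(x[2])), nll, \
        bool(res.success or res.fun >= best[1])


def _fit_mixed(cache: ChoiceModelCache, mask, maxiter=60):
    xs = np.abs(cache.llr if mask is None
                else cache.llr[np.unique(cache.trial_to_cond[mask])])
    qs = np.concatenate([[0.0], np.quantile(xs, np.linspace(0.05, 0.98, 12))])
    nlls = [cache.nll("mixed", StrategyParams(theta=t), mask) for t in qs]
    i = int(np.argmin(nlls))
    lo = qs[max(i - 1, 0)]
    hi = qs[min(i + 1, len(qs) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda t: cache.nll("mixed", StrategyParams(theta=t), mask),
            bounds=(lo, hi), method="bounded",
            options={"maxiter": maxiter, "xatol": 1e-3})
        if res.fun < nlls[i]:
            return StrategyParams(theta=float(res.x)), float(res.fun), True
    return StrategyParams(theta=float(qs[i])), float(nlls[i]), True


def fit_strategy(
    strategy: str,
    dataset: pd.DataFrame,
    w_fixed: float,
    n_mc: int = 4000,
    seed: int = 0,
    cache: Optional[ChoiceModelCache] = None,
    trial_mask: Optional[np.ndarray] = None,
) -> tuple[StrategyParams | None, float, bool]:
    """Fit a strategy's free parameters by (Monte-Carlo) maximum likelihood.

    Returns (params, nll, converged).  The optimal, hierarchical and
    postdictive strategies have no free parameters (params is None) and are
    evaluated predictively with the externally supplied Weber fraction.
    """
    if w_fixed <= 0:
        raise ValueError("w_fixed must be positive")
    cache = cache if cache is not None else ChoiceModelCache(
        dataset, w_fixed, n_mc, seed)
    if strategy in ("optimal", "hierarchical", "postdictive"):
        return None, cache.nll(strategy, None, trial_mask), True
    if strategy == "counterfactual":
        return _fit_counterfactual(cache, trial_mask)
    if strategy == "mixed":
        return _fit_mixed(cache, trial_mask)
    raise ValueError(f"unknown strategy {strategy!r}")


def stratified_folds(dataset: pd.DataFrame, k: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Random k-fold assignment stratified by horizontal difficulty |L - R|.

    Fold sizes differ by at most one.
    """
    n = len(dataset)
    if k > n:
        raise ValueError("k exceeds dataset size")
    if k < 2:
        raise ValueError("k must be >= 2")
    diff = (dataset["arm_L"] - dataset["arm_R"]).abs().to_numpy()
    order = []
    for d in np.unique(diff):
        idx = np.flatnonzero(diff == d)
        order.extend(rng.permutation(idx))
    order = np.asarray(order)
    folds = np.empty(n, dtype=int)
    labels = rng.permutation(k)
    folds[order] = [labels[i % k] for i in range(n)]
    return folds


def crossval_compare(
    dataset: pd.DataFrame,
    w_fixed: float,
    strategies: Sequence[str] = STRATEGIES,
    k: int = 10,
    n_mc: int = 4000,
    seed: int = 0,
) -> ModelComparisonResult:
    """k-fold cross-validated strategy comparison on one response dataset.

    Free parameters are fit on each training split and the held-out NLL is
    accumulated on the corresponding test split; the report is the mean
    held-out NLL per trial for every strategy.
    """
    rng = np.random.default_rng([seed, 0xcf])
    folds = stratified_folds(dataset, k, rng)
    cache = ChoiceModelCache(dataset, w_fixed, n_mc, seed)
    mean_nll: dict[str, float] = {}
    fold_params: dict[str, list[dict]] = {}
    fold_nll: dict[str, list[float]] = {}
    for strat in strategies:
        params_per_fold, nll_per_fold = [], []
        total = 0.0
        for f in range(k):
            train = folds != f
            test = ~train
            params, _, _ = fit_strategy(strat, dataset, w_fixed, n_mc, seed,
                                        cache=cache, trial_mask=train)
            nll_test = cache.nll(strat, params, test)
            total += nll_test
            nll_per_fold.append(nll_test)
            params_per_fold.append(
                {} if params is None else
                {"theta": params.theta, "alpha": params.alpha,
                 "beta": params.beta})
        mean_nll[strat] = total / len(dataset)
        fold_params[strat] = params_per_fold
        fold_nll[strat] = nll_per_fold
    return ModelComparisonResult(list(strategies), mean_nll, fold_params,
                                 fold_nll, folds, seed)
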