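"""Scalar-timing signal detection: likelihoods, T-maze choice model, Weber
fraction MLE, and the condition-level noise estimator for the order-reversal
variant.

Timing measurements follow scalar variability: a measured interval tm given a
base interval t is Gaussian with mean t and standard deviation w*t, where w is
the Weber fraction.  In a two-interval discrimination (T-maze) the optimal
rule compares the two scaled likelihoods, which reduces to a criterion t_c on
tm at the crossing point of the two conditional densities.  The behavioural
model adds a lapse rate: with probability Gamma the choice is a coin flip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "WeberFit", "SigmaFit", "scalar_likelihood", "scalar_loglik",
    "likelihood_crossing", "tmaze_choice_prob", "fit_weber",
    "variant2_correct_prob", "fit_sigma", "percent_change",
]

LIK_FLOOR = 1e-12  # per-trial probability floor against infinite NLL


@dataclass
class WeberFit:
    """Maximum-likelihood fit of the T-maze choice model.

    w is the Weber fraction, t_c_bias a shared additive shift (seconds) of the
    per-pair likelihood-crossing criterion, gamma the lapse rate.
    """

    w: float
    t_c_bias: float
    gamma: float
    nll: float
    converged: bool = True
    boundary: bool = False

    def to_json(self) -> dict:
        return asdict(self)


@dataclass
class SigmaFit:
    """Condition-level timing-noise fit (cumulative-Gaussian psychometric)."""

    sigma: float
    nll: float
    boundary: bool = False

    def to_json(self) -> dict:
        return asdict(self)


def scalar_loglik(tm, t, w):
    """Log density of a scalar-noise measurement: Normal(tm; t, w*t)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("base interval t must be positive")
    if np.any(np.asarray(w) <= 0):
        raise ValueError("Weber fraction w must be positive")
    sd = w * t
    z = (np.asarray(tm, dtype=float) - t) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def scalar_likelihood(tm, t, w):
    """Density of a scalar-noise measurement: Normal(tm; t, w*t)."""
    return np.exp(scalar_loglik(tm, t, w))


def likelihood_crossing(t1: float, t2: float, w: float) -> float:
    """Criterion t_c where the two scaled likelihoods cross, for t1 < t2.

    Solves Normal(t_c; t1, w t1) = Normal(t_c; t2, w t2) for the root between
    t1 and t2.  For t1 == t2 the crossing is degenerate and t1 is returned.
    """
    t1, t2 = float(min(t1, t2)), float(max(t1, t2))
    if t1 <= 0:
        raise ValueError("intervals must be positive")
    if t1 == t2:
        return t1
    # equal log-densities: (tm-t1)^2/t1^2 - (tm-t2)^2/t2^2 = 2 w^2 log(t2/t1)
    a = 1.0 / t1**2 - 1.0 / t2**2
    b = -2.0 * (1.0 / t1 - 1.0 / t2)
    c = -2.0 * w**2 * np.log(t2 / t1)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots > t1) & (roots < t2)]
    if inside.size:
        return float(inside[0])
    # w large enough that the crossing leaves (t1, t2); take the nearest root
    return float(roots[np.argmin(np.abs(roots - 0.5 * (t1 + t2)))])


def tmaze_choice_prob(t1, t2, w, t_c, gamma):
    """Choice probabilities in the two-arm timing discrimination.

    Returns (p_choose_t1_given_true_t1, p_choose_t2_given_true_t2) where the
    agent chooses the short arm when tm < t_c, with lapse rate gamma:

        p(choose t1 | true t1) = 0.5 gamma + (1-gamma) Phi((t_c - t1)/(w t1))
        p(choose t2 | true t2) = 0.5 gamma + (1-gamma) (1 - Phi((t_c - t2)/(w t2)))
    """
    t1, t2 = np.asarray(t1, float), np.asarray(t2, float)
    p1 = 0.5 * gamma + (1 - gamma) * stats.norm.cdf((t_c - t1) / (w * t1))
    p2 = 0.5 * gamma + (1 - gamma) * stats.norm.sf((t_c - t2) / (w * t2))
    return p1, p2


def _tmaze_nll(params: np.ndarray, t1, t2, true_is_t1, chose_t1,
               crossing_cache: dict) -> float:
    w, bias, gamma = params
    key = round(float(w), 10)
    if key not in crossing_cache:
        pairs = {(a, b) for a, b in zip(t1, t2)}
        crossing_cache[key] = {
            p: likelihood_crossing(p[0], p[1], w) for p in pairs
        }
    tc = np.array([crossing_cache[key][(a, b)] for a, b in zip(t1, t2)]) + bias
    p1_true1 = 0.5 * gamma + (1 - gamma) * stats.norm.cdf((tc - t1) / (w * t1))
    p1_true2 = 0.5 * gamma + (1 - gamma) * stats.norm.cdf((tc - t2) / (w * t2))
    p_choose1 = np.where(true_is_t1, p1_true1, p1_true2)
    p_obs = np.where(chose_t1, p_choose1, 1.0 - p_choose1)
    return -np.sum(np.log(np.maximum(p_obs, LIK_FLOOR)))


def fit_weber(
    responses: pd.DataFrame,
    n_starts: int = 8,
    seed: int = 0,
    criterion: str = "pair_crossing",
) -> WeberFit:
    """Maximum-likelihood estimate of (w, t_c bias, lapse) from T-maze choices.

    ``responses`` needs columns t1, t2 (the two candidate intervals with
    t1 <= t2; relabelled if not), true_arm in {1, 2} and choice in {1, 2}.

    The criterion is modelled per interval pair at the likelihood crossing,
    shifted by a single shared bias (``criterion='pair_crossing'``), which
    keeps three free parameters across heterogeneous pairs.  A single global
    criterion (``criterion='global'``) is available as an alternative.
    """
    df = responses.copy()
    flip = df["t1"] > df["t2"]
    if flip.any():
        df.loc[flip, ["t1", "t2"]] = df.loc[flip, ["t2", "t1"]].values
        df.loc[flip, "true_arm"] = 3 - df.loc[flip, "true_arm"]
        df.loc[flip, "choice"] = 3 - df.loc[flip, "choice"]
    t1 = df["t1"].to_numpy(float)
    t2 = df["t2"].to_numpy(float)
    true_is_t1 = df["true_arm"].to_numpy(int) == 1
    chose_t1 = df["choice"].to_numpy(int) == 1

    if len({(a, b) for a, b in zip(t1, t2)}) < 2:
        warnings.warn("fewer than 2 distinct (t1, t2) conditions: "
                      "fit may be unidentifiable", RuntimeWarning)

    span = t2.max() - t1.min()
    bounds = [(0.01, 1.0), (-span, span), (0.0, 0.5)]
    if criterion == "global":
        lo, hi = t1.min(), t2.max()
        bounds[1] = (lo - span, hi + span)

        def nll(p):
            w, tc, gamma = p
            p1_true1 = 0.5 * gamma + (1 - gamma) * stats.norm.cdf((tc - t1) / (w * t1))
            p1_true2 = 0.5 * gamma + (1 - gamma) * stats.norm.cdf((tc - t2) / (w * t2))
            p_choose1 = np.where(true_is_t1, p1_true1, p1_true2)
            p_obs = np.where(chose_t1, p_choose1, 1.0 - p_choose1)
            return -np.sum(np.log(np.maximum(p_obs, LIK_FLOOR)))
    elif criterion == "pair_crossing":
        cache: dict = {}

        def nll(p):
            return _tmaze_nll(p, t1, t2, true_is_t1, chose_t1, cache)
    else:
        raise ValueError(f"unknown criterion mode {criterion!r}")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        x0 = np.array([rng.uniform(0.05, 0.5),
                       rng.uniform(bounds[1][0] * 0.2, bounds[1][1] * 0.2),
                       rng.uniform(0.01, 0.2)])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    w, bias, gamma = best.x
    at_bound = bool(np.isclose(w, bounds[0][0]) or np.isclose(w, bounds[0][1]))
    if at_bound:
        warnings.warn("Weber fraction estimate at search bound", RuntimeWarning)
    return WeberFit(float(w), float(bias), float(gamma), float(best.fun),
                    converged=bool(best.success), boundary=at_bound)


def variant2_correct_prob(t1, t2, sigma):
    """Probability of a correct choice under condition-level noise sigma.

    Cumulative-Gaussian psychometric: Phi(|t1 - t2| / sigma), i.e. the mass of
    Normal(t_d; |t1-t2|, sigma) on t_d > 0.
    """
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")
    d = np.abs(np.asarray(t1, float) - np.asarray(t2, float))
    return stats.norm.cdf(d / sigma)


def fit_sigma(
    responses: pd.DataFrame,
    bounds: tuple[float, float] = (1e-4, 2.0),
) -> SigmaFit:
    """MLE of the condition-level noise sigma from correct/incorrect responses.

    ``responses`` needs columns t1, t2 and boolean ``correct``.
    """
    t1 = responses["t1"].to_numpy(float)
    t2 = responses["t2"].to_numpy(float)
    correct = responses["correct"].to_numpy(bool)

    def nll(log_sigma):
        p = variant2_correct_prob(t1, t2, np.exp(log_sigma))
        p_obs = np.where(correct, p, 1.0 - p)
        return -np.sum(np.log(np.maximum(p_obs, LIK_FLOOR)))

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded")
    sigma = float(np.exp(res.x))
    # a perfectly separable dataset (e.g. all correct) leaves the likelihood
    # flat below some sigma; flag that alongside genuine boundary estimates
    at_bound = bool(sigma <= bounds[0] * 1.05 or sigma >= bounds[1] * 0.95
                    or res.fun < 1e-9)
    if at_bound:
        warnings.warn("sigma estimate unidentifiable or at search bound "
                      "(e.g. all-correct data)", RuntimeWarning)
    return SigmaFit(sigma, float(res.fun), boundary=at_bound)


def percent_change(sigma_c1: float, sigma_c2: float) -> float:
    """Percentage change in estimated noise: 100 (sigma_c2 - sigma_c1)/sigma_c1."""
    return 100.0 * (sigma_c2 - sigma_c1) / sigma_c1
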