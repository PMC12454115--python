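"""Cognitive strategy models against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from hmaze.mazes import ALL_PATHS, MazeGeometry, Path, generate_variant1_trial, \
    sample_human_maze, generate_trial
from hmaze.strategies import (
    EXITS, StrategyParams, choice_distribution, counterfactual_decide,
    counterfactual_decide_batch, hierarchical_decide, joint_likelihood,
    mixed_decide, optimal_decide, postdictive_decide,
    variant1_ideal_likelihoods,
)

W = 0.15


def oracle_logliks(tm1, tm2, g, w):
    """Independent per-exit joint log-likelihoods via scipy normal pdfs."""
    out = []
    for e in EXITS:
        th = g.arm(e[0]) / g.speed
        tv = g.arm(e) / g.speed
        out.append(stats.norm.logpdf(tm1, th, w * th) +
                   stats.norm.logpdf(tm2, tv, w * tv))
    return np.array(out)


def random_distinct_geometry(rng):
    """Human geometry where all pairwise-relevant arms differ (no exact ties)."""
    while True:
        g = sample_human_maze(rng)
        if g.arm_L != g.arm_R and g.arm_LU != g.arm_LD and \
                g.arm_RU != g.arm_RD:
            return g


class TestJointLikelihood:
    def test_product_of_marginals(self, rng):
        g = sample_human_maze(rng)
        tm1, tm2 = 0.51, 0.62
        for path in ALL_PATHS:
            th = g.arm(path.horizontal) / g.speed
            tv = g.arm(path.exit) / g.speed
            expected = stats.norm.pdf(tm1, th, W * th) * \
                stats.norm.pdf(tm2, tv, W * tv)
            assert joint_likelihood(tm1, tm2, path, g, W) == \
                pytest.approx(expected, rel=1e-12)

    def test_symmetric_geometry_equal_likelihoods(self):
        g = MazeGeometry(5, 5, 5, 5, 5, 5, 8)
        vals = [joint_likelihood(0.6, 0.7, p, g, W) for p in ALL_PATHS]
        assert np.ptp(vals) < 1e-15

    def test_peaks_at_true_intervals(self, rng):
        g = MazeGeometry(3, 7, 4, 6, 5, 5, 8)
        path = Path("L", "U")
        th, tv = 3 / 8, 4 / 8
        peak = joint_likelihood(th, tv, path, g, W)
        for d1, d2 in [(0.05, 0), (0, 0.05), (-0.03, 0.02)]:
            assert joint_likelihood(th + d1, tv + d2, path, g, W) <= peak


class TestDecidersAgainstOracles:
    def test_optimal_matches_bruteforce_on_1000_trials(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            g = random_distinct_geometry(rng)
            tm1, tm2 = rng.uniform(0.2, 1.0, 2)
            d = optimal_decide(tm1, tm2, g, W)
            assert d.exit == EXITS[np.argmax(oracle_logliks(tm1, tm2, g, W))]

    def test_hierarchical_matches_two_stage_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(1000):
            g = random_distinct_geometry(rng)
            tm1, tm2 = rng.uniform(0.2, 1.0, 2)
            tL, tR = g.arm_L / g.speed, g.arm_R / g.speed
            side = "L" if stats.norm.logpdf(tm1, tL, W * tL) > \
                stats.norm.logpdf(tm1, tR, W * tR) else "R"
            pair = [side + "U", side + "D"]
            tv = [g.arm(e) / g.speed for e in pair]
            vert = pair[0] if stats.norm.logpdf(tm2, tv[0], W * tv[0]) > \
                stats.norm.logpdf(tm2, tv[1], W * tv[1]) else pair[1]
            d = hierarchical_decide(tm1, tm2, g, W)
            assert d.exit == vert
            assert d.first_choice == side
            assert not d.revised

    def test_postdictive_matches_summed_oracle(self):
        rng = np.random.default_rng(44)
        for _ in range(1000):
            g = random_distinct_geometry(rng)
            tm1, tm2 = rng.uniform(0.2, 1.0, 2)
            ll = oracle_logliks(tm1, tm2, g, W)
            left = np.exp(ll[0]) + np.exp(ll[1])
            right = np.exp(ll[2]) + np.exp(ll[3])
            side = "L" if left > right else "R"
            pair = [side + "U", side + "D"]
            tv = [g.arm(e) / g.speed for e in pair]
            vert = pair[int(stats.norm.logpdf(tm2, tv[1], W * tv[1]) >
                            stats.norm.logpdf(tm2, tv[0], W * tv[0]))]
            assert postdictive_decide(tm1, tm2, g, W).exit == vert

    def test_mixed_matches_two_branch_oracle(self):
        rng = np.random.default_rng(45)
        theta = 1.0
        for _ in range(1000):
            g = random_distinct_geometry(rng)
            tm1, tm2 = rng.uniform(0.2, 1.0, 2)
            tL, tR = g.arm_L / g.speed, g.arm_R / g.speed
            llr = stats.norm.logpdf(tm1, tL, W * tL) - \
                stats.norm.logpdf(tm1, tR, W * tR)
            if abs(llr) > theta:
                expected = hierarchical_decide(tm1, tm2, g, W).exit
            else:
                tv = [g.arm(e) / g.speed for e in EXITS]
                lls = [stats.norm.logpdf(tm2, t, W * t) for t in tv]
                expected = EXITS[int(np.argmax(lls))]
            assert mixed_decide(tm1, tm2, g, W, theta).exit == expected

    def test_exact_measurement_recovers_true_path(self):
        g = MazeGeometry(3, 7, 4, 6, 6, 4, 8)  # all within-pair arms distinct
        for path in [Path("L", "U"), Path("R", "D")]:
            th = g.arm(path.horizontal) / g.speed
            tv = g.arm(path.exit) / g.speed
            for decide in (optimal_decide, hierarchical_decide,
                           postdictive_decide):
                assert decide(th, tv, g, 0.01).exit == path.exit


class TestCounterfactualLimits:
    def test_theta_neg_inf_equals_hierarchical(self):
        rng = np.random.default_rng(46)
        params = StrategyParams(theta=-np.inf)
        for _ in range(300):
            g = random_distinct_geometry(rng)
            tm1, tm2 = rng.uniform(0.2, 1.0, 2)
            d = counterfactual_decide(tm1, tm2, g, params, W, rng)
            assert not d.revised
            assert d.exit == hierarchical_decide(tm1, tm2, g, W).exit

    def test_theta_pos_inf_always_revises(self):
        rng = np.random.default_rng(47)
        params = StrategyParams(theta=np.inf, alpha=0.0, beta=0.0)
        for _ in range(300):
            g = random_distinct_geometry(rng)
            tm1, tm2 = rng.uniform(0.2, 1.0, 2)
            d = counterfactual_decide(tm1, tm2, g, params, W, rng)
            first = hierarchical_decide(tm1, tm2, g, W).first_choice
            assert d.revised
            assert d.exit[0] != first

    def test_compare_trigger_with_perfect_recall_equals_optimal(self):
        # on a dense measurement grid, perfect-memory revision triggered by
        # the side comparison reproduces the optimal decisions exactly
        params = StrategyParams(theta=0.0, alpha=0.0, beta=0.0,
                                revise_trigger="compare")
        g = MazeGeometry(4, 6, 3, 7, 5, 5, 8)
        grid = np.linspace(0.15, 1.1, 40)
        eps = np.zeros(1)
        for tm1 in grid:
            for tm2 in grid:
                idx, _, _, _ = counterfactual_decide_batch(
                    np.array([tm1]), np.array([tm2]), g, W, params,
                    recall_eps1=eps, recall_eps2=eps)
                assert EXITS[int(idx[0])] == optimal_decide(tm1, tm2, g, W).exit


class TestChoiceDistribution:
    def test_degenerate_at_small_noise(self, rng):
        g = MazeGeometry(3, 7, 4, 6, 5, 5, 8)
        p = choice_distribution("optimal", g, Path("L", "U"), 0.01,
                                n_mc=500, rng=rng)
        assert p[0] > 0.98

    def test_symmetric_maze_uniform(self):
        rng = np.random.default_rng(48)
        g = MazeGeometry(5, 5, 5, 5, 5, 5, 8)
        n = 20_000
        p = choice_distribution("optimal", g, Path("L", "U"), W,
                                n_mc=n, rng=rng)
        se = 3 * np.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(p - 0.25) < se)

    def test_easier_geometry_more_accurate(self):
        rng = np.random.default_rng(49)
        hard = MazeGeometry(5, 5, 5, 5, 5, 5, 8)
        easy = MazeGeometry(7, 3, 7, 3, 7, 3, 8)
        p_hard = choice_distribution("optimal", hard, Path("L", "U"), W,
                                     n_mc=20_000, rng=rng)
        p_easy = choice_distribution("optimal", easy, Path("L", "U"), W,
                                     n_mc=20_000, rng=rng)
        assert p_easy[0] > p_hard[0]

    def test_matches_2d_quadrature(self):
        # semi-analytic oracle: integrate the decision regions over the
        # scalar-noise measurement density on a fine grid
        rng = np.random.default_rng(50)
        from hmaze.strategies import decide_batch
        from hmaze.mazes import sample_measured_intervals
        for _ in range(5):
            g = random_distinct_geometry(rng)
            path = ALL_PATHS[rng.integers(4)]
            ts1 = g.arm(path.horizontal) / g.speed
            ts2 = g.arm(path.exit) / g.speed
            m = 241
            q1 = np.linspace(ts1 * (1 - 5 * W), ts1 * (1 + 5 * W), m)
            q2 = np.linspace(ts2 * (1 - 5 * W), ts2 * (1 + 5 * W), m)
            w1 = stats.norm.pdf(q1, ts1, W * ts1)
            w2 = stats.norm.pdf(q2, ts2, W * ts2)
            w1 /= w1.sum()
            w2 /= w2.sum()
            G1, G2 = np.meshgrid(q1, q2, indexing="ij")
            idx = decide_batch("optimal", G1.ravel(), G2.ravel(), g, W)
            mass = (w1[:, None] * w2[None, :]).ravel()
            p_quad = np.bincount(idx, weights=mass, minlength=4)
            p_mc = choice_distribution("optimal", g, path, W, n_mc=40_000,
                                       rng=rng)
            assert np.all(np.abs(p_quad - p_mc) < 0.012)

    def test_unknown_strategy_raises(self, rng):
        g = sample_human_maze(rng)
        with pytest.raises(ValueError):
            choice_distribution("bayesian", g, Path("L", "U"), W, n_mc=10,
                                rng=rng)


class TestAccuracyOrdering:
    def test_optimal_geq_counterfactual_geq_hierarchical(self):
        # perfect-memory counterfactual with a *fitted* threshold sits
        # between the optimal and hierarchical strategies in accuracy; theta
        # is chosen on the same geometry batch by grid search (theta -> -inf
        # recovers hierarchical, so the fitted value can never do worse)
        rng = np.random.default_rng(51)
        n_geo, n_mc = 25, 3000
        thetas = [-np.inf, -3.0, -1.0, 0.0, 0.5, 1.0]
        acc = {"optimal": 0.0, "hierarchical": 0.0}
        acc_cf = np.zeros(len(thetas))
        for _ in range(n_geo):
            g = sample_human_maze(rng)
            path = ALL_PATHS[rng.integers(4)]
            true_idx = EXITS.index(path.exit)
            for strat in ("optimal", "hierarchical"):
                p = choice_distribution(strat, g, path, W, n_mc=n_mc, rng=rng)
                acc[strat] += p[true_idx] / n_geo
            for j, th in enumerate(thetas):
                p = choice_distribution(
                    "counterfactual", g, path, W,
                    params=StrategyParams(theta=th), n_mc=n_mc, rng=rng)
                acc_cf[j] += p[true_idx] / n_geo
        best_cf = acc_cf.max()
        se = 3 / np.sqrt(n_geo * n_mc)
        assert acc["optimal"] >= best_cf - se
        assert best_cf >= acc["hierarchical"] - se


class TestVariant1IdealObserver:
    def test_noiseless_target_is_argmax(self, rng):
        tr = generate_variant1_trial([4, 5, 6, 7], 8.0, 2, rng)
        lik = variant1_ideal_likelihoods(tr, 0.02)
        assert int(np.argmax(lik)) == 2

    def test_equal_arms_equal_likelihood(self, rng):
        tr = generate_variant1_trial([4, 4, 6, 7], 8.0, 3, rng)
        lik = variant1_ideal_likelihoods(tr, W)
        assert lik[0] == pytest.approx(lik[1], rel=1e-12)

    def test_matches_dense_endpoint_oracle(self, rng):
        tr = generate_variant1_trial([4, 5, 6, 7], 12.0, 1, rng)
        tm = tr.elapsed_time * 1.07
        lik = variant1_ideal_likelihoods(tr, W, tm_elapsed=tm,
                                         max_reversals=3)
        for i, a in enumerate(tr.lengths):
            taus = [(k + 1) * a / tr.speed for k in range(4)]
            expected = sum(stats.norm.pdf(tm, tau, W * tau) for tau in taus)
            assert lik[i] == pytest.approx(expected, rel=1e-10)


class TestChoiceProbabilityTable:
    def test_rows_and_normalization(self):
        from hmaze.strategies import choice_probability_table
        g = MazeGeometry(3, 7, 4, 6, 5, 5, 8)
        df = choice_probability_table([g], ["optimal", "hierarchical"],
                                      n_mc=500, seed=1)
        assert len(df) == 4 * 2  # paths x strategies
        probs = df[[f"p_{e}" for e in EXITS]].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0)


class TestDecisionInvariants:
    def test_every_strategy_returns_one_exit(self, rng):
        params = StrategyParams(theta=0.5, alpha=0.2, beta=0.01)
        for _ in range(100):
            g = sample_human_maze(rng)
            tm1, tm2 = rng.uniform(0.2, 1.0, 2)
            for d in [optimal_decide(tm1, tm2, g, W),
                      hierarchical_decide(tm1, tm2, g, W),
                      postdictive_decide(tm1, tm2, g, W),
                      counterfactual_decide(tm1, tm2, g, params, W, rng),
                      mixed_decide(tm1, tm2, g, W, 1.0)]:
                assert d.exit in EXITS
                if d.revised:
                    assert d.first_choice != d.exit[0]
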