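"""Model densities, conjugate updates, diagnostics, and sampler behaviour.

The log-posterior oracles here are deliberately naive re-implementations
(explicit loops, scipy.stats densities) kept independent of the package's
vectorized code paths.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from broodsel import bayes_rsf as br
from broodsel.bayes_rsf import (
    AGE_LEVELS,
    RSF4_SLOPE_COLS,
    McmcConfig,
    _RSF3Data,
    _RSF4Data,
    init_state_rsf3,
    init_state_rsf4,
    linear_predictor_rsf3,
    log_posterior_rsf3,
    log_posterior_rsf4,
    random_walk_metropolis,
    rhat,
    summarize_posterior,
    update_precision_conjugate,
)
from broodsel.choice_design import AGE_COLS, SLOPE_COLS


def toy_design_rsf3(n_sets=3, n_broods=2, seed=5, card=6):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sets):
        for i in range(card):
            row = {"locid": s, "brood_id": f"B{s % n_broods}", "used": int(i == 0)}
            for c in SLOPE_COLS + AGE_COLS:
                row[c] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


def toy_design_rsf4(n_pairs=5, seed=5):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_pairs):
        age = AGE_LEVELS[p % 3]
        for used in (1, 0):
            row = {
                "pair_id": p,
                "brood_id": f"B{p % 2}",
                "age_class": age,
                "used": used,
                "season": rng.normal(),
            }
            for c in RSF4_SLOPE_COLS:
                row[c] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


def norm_prec_lpdf(x, mean, prec):
    return stats.norm.logpdf(np.asarray(x), mean, np.sqrt(1.0 / prec)).sum()


def gamma_lpdf(x, shape, rate):
    return stats.gamma.logpdf(np.asarray(x), a=shape, scale=1.0 / rate).sum()


def naive_log_posterior_rsf3(state, design):
    """Explicit row-by-row sum over the model's likelihood and priors."""
    lp = 0.0
    broods = sorted(design["brood_id"].unique())
    strata = sorted(design["locid"].unique())
    for _, row in design.iterrows():
        j = broods.index(row["brood_id"])
        s = strata.index(row["locid"])
        eta = state["b0"][s] + state["eps"][j]
        for m, c in enumerate(AGE_COLS):
            eta += state["a"][m] * row[c]
        for k, c in enumerate(SLOPE_COLS):
            eta += state["beta"][k, j] * row[c]
        p = 1.0 / (1.0 + np.exp(-eta))
        lp += np.log(p if row["used"] == 1 else 1.0 - p)
    lp += norm_prec_lpdf(state["b0"], 0.0, state["tau_locid"])
    lp += norm_prec_lpdf(state["a"], 0.0, 0.001)
    for k in range(len(SLOPE_COLS)):
        lp += norm_prec_lpdf(state["beta"][k], state["mu"][k], state["tau_k"][k])
    lp += norm_prec_lpdf(state["mu"], 0.0, 0.001)
    lp += norm_prec_lpdf(state["eps"], 0.0, state["tau_brood"])
    lp += gamma_lpdf(state["tau_k"], 0.1, 0.1)
    lp += gamma_lpdf(state["tau_locid"], 0.1, 0.1)
    lp += gamma_lpdf(state["tau_brood"], 0.1, 0.1)
    return lp


def naive_log_posterior_rsf4(state, design):
    lp = 0.0
    broods = sorted(design["brood_id"].unique())
    pairs = sorted(design["pair_id"].unique())
    for _, row in design.iterrows():
        a = AGE_LEVELS.index(row["age_class"])
        eta = (
            state["bA"][a]
            + state["gamma_season"] * row["season"]
            + state["eps_brood"][broods.index(row["brood_id"])]
            + state["eps_pair"][pairs.index(row["pair_id"])]
        )
        for k, c in enumerate(RSF4_SLOPE_COLS):
            eta += state["beta"][k, a] * row[c]
        p = 1.0 / (1.0 + np.exp(-eta))
        lp += np.log(p if row["used"] == 1 else 1.0 - p)
    lp += norm_prec_lpdf(state["bA"], 0.0, 0.001)
    for k in range(len(RSF4_SLOPE_COLS)):
        lp += norm_prec_lpdf(state["beta"][k], state["mu"][k], state["tau_k"][k])
    lp += norm_prec_lpdf(state["mu"], 0.0, 0.001)
    lp += norm_prec_lpdf(state["gamma_season"], 0.0, 0.001)
    lp += norm_prec_lpdf(state["eps_brood"], 0.0, state["tau_brood"])
    lp += norm_prec_lpdf(state["eps_pair"], 0.0, state["tau_pair"])
    lp += gamma_lpdf(state["tau_k"], 0.1, 0.1)
    lp += gamma_lpdf(state["tau_brood"], 0.1, 0.1)
    lp += gamma_lpdf(state["tau_pair"], 0.1, 0.1)
    return lp


class TestLinearPredictor:
    def test_zero_covariates_give_intercepts(self, rng):
        design = toy_design_rsf3()
        for c in SLOPE_COLS + AGE_COLS:
            design[c] = 0.0
        data = _RSF3Data(design)
        state = init_state_rsf3(data, rng)
        eta = linear_predictor_rsf3(state, data)
        want = state["b0"][data.strat_idx] + state["eps"][data.brood_idx]
        np.testing.assert_allclose(eta, want)

    def test_all_zero_params_give_half_probability(self, rng):
        data = _RSF3Data(toy_design_rsf3())
        state = init_state_rsf3(data, rng)
        for key in ("b0", "a", "beta", "mu", "eps"):
            state[key] = np.zeros_like(state[key])
        np.testing.assert_allclose(linear_predictor_rsf3(state, data), 0.0)

    def test_matches_naive_term_sum(self, rng):
        design = toy_design_rsf3(n_sets=4, n_broods=3)
        data = _RSF3Data(design)
        state = init_state_rsf3(data, rng)
        eta = linear_predictor_rsf3(state, data)
        d = design.sort_values(["locid", "used"], ascending=[True, False])
        broods = sorted(design["brood_id"].unique())
        for i, (_, row) in enumerate(d.iterrows()):
            j = broods.index(row["brood_id"])
            want = state["b0"][int(row["locid"])] + state["eps"][j]
            want += sum(state["a"][m] * row[c] for m, c in enumerate(AGE_COLS))
            want += sum(state["beta"][k, j] * row[c] for k, c in enumerate(SLOPE_COLS))
            assert eta[i] == pytest.approx(want, rel=1e-12)


class TestLogPosterior:
    def test_single_used_record_closed_form(self, rng):
        design = toy_design_rsf3(n_sets=1, n_broods=1, card=1)
        for c in SLOPE_COLS + AGE_COLS:
            design[c] = 0.0
        data = _RSF3Data(design)
        state = init_state_rsf3(data, rng)
        for key in ("b0", "a", "beta", "mu", "eps"):
            state[key] = np.zeros_like(state[key])
        state["tau_k"] = np.ones_like(state["tau_k"])
        state["tau_locid"] = state["tau_brood"] = 1.0
        got = log_posterior_rsf3(state, data)
        K = len(SLOPE_COLS)
        want = (
            np.log(0.5)
            + norm_prec_lpdf(0.0, 0.0, 1.0) * 2  # b0 and eps at 0, precision 1
            + norm_prec_lpdf(np.zeros(2), 0.0, 0.001)  # age offsets
            + norm_prec_lpdf(np.zeros(K), 0.0, 1.0)  # slopes given mu=0, tau=1
            + norm_prec_lpdf(np.zeros(K), 0.0, 0.001)  # mu
            + gamma_lpdf(np.ones(K), 0.1, 0.1)
            + gamma_lpdf(1.0, 0.1, 0.1) * 2  # tau_locid, tau_brood
        )
        assert got == pytest.approx(want, rel=1e-12)

    def test_likelihood_additivity_under_duplication(self, rng):
        design = toy_design_rsf3(n_sets=2, n_broods=1)
        doubled = pd.concat(
            [design, design.assign(locid=design["locid"] + 2)], ignore_index=True
        )
        data1, data2 = _RSF3Data(design), _RSF3Data(doubled)
        state1 = init_state_rsf3(data1, rng)
        state2 = dict(state1)
        state2["b0"] = np.concatenate([state1["b0"], state1["b0"]])
        lik1 = log_posterior_rsf3(state1, data1) - log_posterior_rsf3(
            state1, data1, lik_weight=0.0
        )
        lik2 = log_posterior_rsf3(state2, data2) - log_posterior_rsf3(
            state2, data2, lik_weight=0.0
        )
        assert lik2 == pytest.approx(2 * lik1, rel=1e-10)

    def test_rsf3_matches_naive_oracle(self, rng):
        design = toy_design_rsf3(n_sets=3, n_broods=2)  # 18 records
        data = _RSF3Data(design)
        state = init_state_rsf3(data, rng)
        got = log_posterior_rsf3(state, data)
        want = naive_log_posterior_rsf3(state, design)
        assert got == pytest.approx(want, abs=1e-10)

    def test_rsf4_all_zero_params(self, rng):
        design = toy_design_rsf4(n_pairs=4)
        data = _RSF4Data(design)
        state = init_state_rsf4(data, rng)
        for key in ("bA", "beta", "mu", "eps_brood", "eps_pair"):
            state[key] = np.zeros_like(state[key])
        state["gamma_season"] = 0.0
        lik = log_posterior_rsf4(state, data) - log_posterior_rsf4(
            state, data, lik_weight=0.0
        )
        assert lik == pytest.approx(2 * 4 * np.log(0.5), rel=1e-12)

    def test_rsf4_matches_naive_oracle(self, rng):
        design = toy_design_rsf4(n_pairs=5)
        data = _RSF4Data(design)
        state = init_state_rsf4(data, rng)
        got = log_posterior_rsf4(state, data)
        want = naive_log_posterior_rsf4(state, design)
        assert got == pytest.approx(want, abs=1e-10)

    def test_rsf4_age_label_symmetry(self, rng):
        # with identical slopes/intercepts across ages, relabelling the age
        # of a pair leaves the likelihood unchanged
        design = toy_design_rsf4(n_pairs=5)
        data = _RSF4Data(design)
        state = init_state_rsf4(data, rng)
        state["bA"] = np.full_like(state["bA"], 0.3)
        state["beta"] = np.tile(state["beta"][:, :1], (1, 3))
        base = log_posterior_rsf4(state, data)
        relabeled = design.copy()
        relabeled["age_class"] = "chick"
        assert log_posterior_rsf4(state, _RSF4Data(relabeled)) == pytest.approx(
            base, rel=1e-12
        )

    def test_non_finite_state_rejected(self, rng):
        data = _RSF3Data(toy_design_rsf3())
        state = init_state_rsf3(data, rng)
        state["mu"][0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            log_posterior_rsf3(state, data)


class TestConjugateUpdate:
    def test_no_deviations_returns_prior(self):
        assert update_precision_conjugate(np.array([])) == (0.1, 0.1)

    def test_hand_example(self):
        shape, rate = update_precision_conjugate(np.array([1.0, -1.0]))
        assert (shape, rate) == (1.1, 1.1)
        assert shape / rate == pytest.approx(1.0)  # posterior-mean identity

    def test_distributional_check_against_gamma_cdf(self, rng):
        devs = rng.normal(0, 2.0, size=17)
        shape, rate = update_precision_conjugate(devs)
        draws = rng.gamma(shape, 1.0 / rate, size=10_000)
        ks = stats.kstest(draws, stats.gamma(a=shape, scale=1.0 / rate).cdf)
        assert ks.statistic < 0.02


class TestRhat:
    def test_identical_chains(self, rng):
        x = rng.normal(size=500)
        assert rhat(np.vstack([x, x, x])) <= 1.0 + 1e-6

    def test_separated_chains_match_hand_psrf(self, rng):
        n = 1000
        chains = np.vstack([rng.normal(0, 1, n), rng.normal(5, 1, n)])
        got = rhat(chains)
        w = chains.var(axis=1, ddof=1).mean()
        b_over_n = chains.mean(axis=1).var(ddof=1)
        want = np.sqrt(((n - 1) / n * w + b_over_n) / w)
        assert got == pytest.approx(want, rel=1e-12)
        assert got > 1.5

    def test_affine_invariance(self, rng):
        chains = rng.normal(size=(3, 200))
        assert rhat(chains) == pytest.approx(rhat(4.2 * chains - 7.0), rel=1e-9)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            rhat(rng.normal(size=(1, 100)))

    def test_agrees_with_arviz_on_which_side_of_threshold(self, rng):
        az = pytest.importorskip("arviz")
        mixed = rng.normal(size=(3, 400))
        split = np.vstack([rng.normal(0, 1, 400), rng.normal(6, 1, 400)])
        for chains in (mixed, split):
            ours = rhat(chains)
            theirs = float(az.rhat(chains))
            assert (ours < 1.1) == (theirs < 1.1)


class TestSummarize:
    def test_all_positive_f_is_one(self, rng):
        s = summarize_posterior(rng.random(500) + 0.1)
        assert s["f"] == 1.0

    def test_symmetric_two_point_sample(self):
        s = summarize_posterior(np.array([-1.0, 1.0]))
        assert s["mean"] == 0.0 and s["f"] == 0.5

    def test_quantiles_median_unbiased_on_1_to_100(self):
        s = summarize_posterior(np.arange(1.0, 101.0))
        # median-unbiased empirical quantiles computed by hand:
        # h = (n + 1/3) p + 1/3 -> interpolate order statistics
        assert s["q2.5"] == pytest.approx(2.8417, abs=5e-4)
        assert s["q50"] == pytest.approx(50.5)
        assert s["q97.5"] == pytest.approx(98.1583, abs=5e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(np.array([]))


class TestSummaryProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=200,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_quantile_order_and_f_bounds(self, xs):
        s = summarize_posterior(np.asarray(xs))
        assert s["q2.5"] <= s["q50"] <= s["q97.5"]
        assert 0.0 <= s["f"] <= 1.0
        assert min(xs) <= s["q50"] <= max(xs)


class TestRandomWalkKernel:
    def test_moments_match_quadrature_on_toy_posterior(self):
        # 2-parameter non-Gaussian target with quadrature-computed moments
        def logp(v):
            x, y = v
            return -0.5 * (x**2 + y**2) - 0.25 * (x * y) ** 2

        grid = np.linspace(-6, 6, 401)
        gx, gy = np.meshgrid(grid, grid)
        dens = np.exp(-0.5 * (gx**2 + gy**2) - 0.25 * (gx * gy) ** 2)
        dens /= dens.sum()
        want_ex2 = float((gx**2 * dens).sum())
        want_exy = float((gx * gy * dens).sum())

        rng = np.random.default_rng(11)
        draws = random_walk_metropolis(logp, [0.0, 0.0], 120_000, 1.2, rng)[2000:]
        ex2 = (draws[:, 0] ** 2).mean()
        exy = (draws[:, 0] * draws[:, 1]).mean()
        # 3 batch-means standard errors
        bm = draws[: 118_000].reshape(59, 2000, 2)
        se_ex2 = (bm[:, :, 0] ** 2).mean(axis=1).std(ddof=1) / np.sqrt(59)
        se_exy = (bm[:, :, 0] * bm[:, :, 1]).mean(axis=1).std(ddof=1) / np.sqrt(59)
        assert abs(ex2 - want_ex2) < 3 * se_ex2
        assert abs(exy - want_exy) < 3 * se_exy


class TestMcmcConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            McmcConfig(seed=1, n_chains=0)
        with pytest.raises(ValueError):
            McmcConfig(seed=1, rhat_threshold=0.9)

    def test_model_defaults(self):
        c3 = McmcConfig.rsf3_default(seed=1)
        c4 = McmcConfig.rsf4_default(seed=1)
        assert (c3.n_chains, c3.thin, c3.burn_in, c3.increment) == (3, 3, 500, 5000)
        assert (c4.burn_in, c4.increment) == (1000, 10000)
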