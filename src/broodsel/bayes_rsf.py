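"""Hierarchical Bayesian resource-selection models and their MCMC engine.

Two models, both with Bernoulli likelihood on a logit link and BUGS-style
parameterization throughout — Normal(mean, *precision*), Gamma(shape, rate);
"Normal(0, 0.001)" is a diffuse prior with variance 1000.

Third order (use-availability choice sets, 1 used : 5 available)::

    logit(theta_i) = b0_{s(i)} + a . Z_i + sum_k beta_{k, j(i)} X_{ik} + eps_{j(i)}

with stratum (choice set) intercepts b0_s ~ N(0, tau_locid), fixed age
offsets a ~ N(0, 0.001) (neonate reference fixed at 0), brood-specific
slopes beta_{k,j} ~ N(mu_k, tau_k) around population means mu_k ~ N(0,
0.001), brood intercepts eps_j ~ N(0, tau_brood), and Gamma(0.1, 0.1)
hyperpriors on every precision.

Fourth order (paired roost vs available, 1:1)::

    logit(theta_i) = bA_{A(i)} + sum_k beta_{k, A(i)} X_{ik}
                     + gamma * Season_i + eps_{j(i)} + eps_pair_{p(i)}

with one intercept and one slope per covariate per age class (neonate,
chick, juvenile), the age-specific slopes sharing a hierarchical
N(mu_k, tau_k) prior across age classes, a global season coefficient,
and brood- and pair-level random intercepts (tau.brood, tau.pair).

The sampler is Metropolis-within-Gibbs: adaptive Gaussian random-walk
proposals for all location parameters (blocks that touch disjoint rows are
proposed and accepted in parallel), conjugate Gibbs draws for every
precision.  Proposal scales are tuned toward a 0.35 acceptance rate during
the burn-in/adaptation phase only, so the post-adaptation chain is a fixed
Markov kernel.  Chains are extended in increments until the Gelman-Rubin
Rhat of every monitored parameter drops below the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .choice_design import AGE_COLS, SLOPE_COLS

RSF4_SLOPE_COLS = [
    "temp_mean",
    "woody",
    "grass",
    "temp_cv",
    "bareness",
    "obscurity",
    "woody_season",
]
AGE_LEVELS = ["neonate", "chick", "juvenile"]

DIFFUSE_PREC = 0.001  # precision of the diffuse normal priors
GAMMA_SHAPE = 0.1
GAMMA_RATE = 0.1


@dataclass
class McmcConfig:
    """Chain settings; defaults follow the analysis protocol (3 chains,
    thinning 3, Rhat < 1.1), with the burn-in/adaptation length and the
    extension increment differing between the two models."""

    seed: int
    n_chains: int = 3
    thin: int = 3
    burn_in: int = 500
    increment: int = 5000
    max_increments: int = 6
    rhat_threshold: float = 1.1
    target_accept: float = 0.35
    adapt_every: int = 50

    def __post_init__(self) -> None:
        for name in ("n_chains", "thin", "burn_in", "increment", "max_increments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rhat_threshold <= 1:
            raise ValueError("rhat_threshold must exceed 1")

    @classmethod
    def rsf3_default(cls, seed: int, **kw) -> "McmcConfig":
        kw.setdefault("burn_in", 500)
        kw.setdefault("increment", 5000)
        return cls(seed=seed, **kw)

    @classmethod
    def rsf4_default(cls, seed: int, **kw) -> "McmcConfig":
        kw.setdefault("burn_in", 1000)
        kw.setdefault("increment", 10000)
        return cls(seed=seed, **kw)

    def reduced(self, increment: int = 2500, max_increments: int = 6) -> "McmcConfig":
        """Desk-scale settings for simulation studies."""
        return replace(self, increment=increment, max_increments=max_increments)


@dataclass
class FitResult:
    samples: pd.DataFrame  # columns: chain, draw, <monitored parameters>
    summary: pd.DataFrame  # index: parameter; mean, q2.5, q50, q97.5, f, rhat
    converged: bool
    n_iterations: int  # post-burn-in iterations per chain
    monitored: list[str] = field(default_factory=list)

    def chains_of(self, name: str) -> np.ndarray:
        """(n_chains, n_draws) array of one monitored parameter."""
        wide = self.samples.pivot_table(
            index="draw", columns="chain", values=name, sort=True
        )
        return wide.to_numpy().T


# ---------------------------------------------------------------------------
# densities and diagnostics


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-row log-likelihood of y ~ Bernoulli(inv_logit(eta))."""
    return y * eta - _log1pexp(eta)


def normal_logpdf_prec(x, mean, prec) -> np.ndarray:
    """Normal log density under the (mean, precision) parameterization."""
    x = np.asarray(x, dtype=float)
    return 0.5 * (np.log(prec) - np.log(2 * np.pi)) - 0.5 * prec * (x - mean) ** 2


def gamma_logpdf(x, shape, rate) -> np.ndarray:
    from scipy.special import gammaln

    x = np.asarray(x, dtype=float)
    return shape * np.log(rate) + (shape - 1) * np.log(x) - rate * x - gammaln(shape)


def update_precision_conjugate(
    deviations: np.ndarray, prior_shape: float = GAMMA_SHAPE, prior_rate: float = GAMMA_RATE
) -> tuple[float, float]:
    """Exact Gamma conditional of a precision given Normal deviations.

    Returns (shape + n/2, rate + sum(dev^2)/2)."""
    if prior_shape <= 0 or prior_rate <= 0:
        raise ValueError("prior shape and rate must be positive")
    dev = np.asarray(deviations, dtype=float)
    return prior_shape + dev.size / 2.0, prior_rate + float(np.sum(dev**2)) / 2.0


def rhat(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains``: (n_chains, n_draws), n_chains >= 2, n_draws >= 4.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 4:
        raise ValueError("need chains of length >= 4")
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = chains.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def summarize_posterior(samples: np.ndarray, rhat_value: float = np.nan) -> dict:
    """Mean, 2.5/50/97.5 empirical percentiles (median-unbiased), and the
    f statistic: share of draws with the same sign as the posterior mean
    (exact zeros count as matching; an exactly-zero mean reports f = 0.5).
    """
    s = np.asarray(samples, dtype=float)
    if s.size == 0:
        raise ValueError("empty sample")
    mean = float(s.mean())
    q = np.quantile(s, [0.025, 0.5, 0.975], method="median_unbiased")
    if mean == 0.0:
        f = 0.5
    else:
        f = float(np.mean((np.sign(s) == np.sign(mean)) | (s == 0.0)))
    return {
        "mean": mean,
        "q2.5": float(q[0]),
        "q50": float(q[1]),
        "q97.5": float(q[2]),
        "f": f,
        "rhat": rhat_value,
    }


def random_walk_metropolis(logpdf, x0, n_iter: int, scale, rng) -> np.ndarray:
    """Plain joint Gaussian random-walk Metropolis on a small vector state.

    The same accept/reject rule the model samplers use, exposed as a
    standalone kernel so its detailed-balance behaviour can be checked
    against quadrature on toy targets.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    lp = float(logpdf(x))
    out = np.empty((n_iter, x.size))
    for i in range(n_iter):
        prop = x + rng.normal(0.0, scale, size=x.size)
        lp_prop = float(logpdf(prop))
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
        out[i] = x
    return out


# ---------------------------------------------------------------------------
# shared random-walk block update


def _grouped_rw_update(
    eta: np.ndarray,
    y: np.ndarray,
    contrib: np.ndarray,
    group_idx: np.ndarray,
    values: np.ndarray,
    scales: np.ndarray,
    prior_mean,
    prior_prec,
    rng: np.random.Generator,
    lik_weight: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Parallel random-walk update of one parameter per group.

    Each group's parameter enters the linear predictor additively as
    ``values[group] * contrib`` on its own disjoint set of rows, so all
    groups can be proposed and accepted independently in one pass.
    Returns (accept mask, updated eta); ``values`` is modified in place.
    """
    n_groups = values.size
    delta = rng.normal(0.0, scales, size=n_groups)
    d_eta = delta[group_idx] * contrib
    d_ll_rows = bernoulli_loglik(eta + d_eta, y) - bernoulli_loglik(eta, y)
    d_ll = np.bincount(group_idx, weights=d_ll_rows, minlength=n_groups)
    new = values + delta
    d_prior = -0.5 * prior_prec * ((new - prior_mean) ** 2 - (values - prior_mean) ** 2)
    accept = np.log(rng.random(n_groups)) < lik_weight * d_ll + d_prior
    values[accept] = new[accept]
    eta = eta + np.where(accept[group_idx], d_eta, 0.0)
    return accept, eta


class _Adapter:
    """Robbins-Monro-style proposal-scale tuning toward a target rate."""

    def __init__(self, shape, target: float, every: int):
        self.scales = np.full(shape, 0.3)
        self.target = target
        self.every = every
        self.acc = np.zeros(shape)
        self.count = 0

    def record(self, accept: np.ndarray) -> None:
        self.acc += accept
        self.count += 1
        if self.count >= self.every:
            rate = self.acc / self.count
            self.scales *= np.exp(1.5 * (rate - self.target))
            np.clip(self.scales, 1e-4, 50.0, out=self.scales)
            self.acc[:] = 0.0
            self.count = 0


# ---------------------------------------------------------------------------
# third-order model


class _RSF3Data:
    def __init__(self, design: pd.DataFrame):
        d = design.sort_values(["locid", "used"], ascending=[True, False], kind="stable")
        counts = d.groupby("locid").size()
        if not (counts == counts.iloc[0]).all():
            raise ValueError("all choice sets must have the same cardinality")
        if not (d.groupby("locid")["used"].sum() == 1).all():
            raise ValueError("each choice set needs exactly one used record")
        self.y = d["used"].to_numpy(dtype=float)
        self.X = d[SLOPE_COLS].to_numpy(dtype=float)
        self.Z = d[AGE_COLS].to_numpy(dtype=float)
        strat, self.strat_idx = np.unique(d["locid"].to_numpy(), return_inverse=True)
        broods, self.brood_idx = np.unique(d["brood_id"].to_numpy(), return_inverse=True)
        self.n_strata = strat.size
        self.n_broods = broods.size
        self.brood_labels = broods
        self.n = len(d)


def init_state_rsf3(data: _RSF3Data, rng: np.random.Generator) -> dict:
    K = len(SLOPE_COLS)
    return {
        "b0": rng.normal(0, 0.1, data.n_strata),
        "a": rng.normal(0, 0.1, len(AGE_COLS)),
        "beta": rng.normal(0, 0.1, (K, data.n_broods)),
        "mu": rng.normal(0, 0.1, K),
        "tau_k": np.ones(K),
        "eps": rng.normal(0, 0.1, data.n_broods),
        "tau_locid": 1.0,
        "tau_brood": 1.0,
    }


def linear_predictor_rsf3(state: dict, data: _RSF3Data) -> np.ndarray:
    """The model's linear predictor for every design row."""
    eta = (
        state["b0"][data.strat_idx]
        + data.Z @ state["a"]
        + np.einsum("nk,kn->n", data.X, state["beta"][:, data.brood_idx])
        + state["eps"][data.brood_idx]
    )
    return eta


def log_posterior_rsf3(
    state: dict, data: _RSF3Data, lik_weight: float = 1.0
) -> float:
    """Joint log posterior density (likelihood + all priors/hyperpriors)."""
    for v in state.values():
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite parameter in state")
    eta = linear_predictor_rsf3(state, data)
    lp = lik_weight * bernoulli_loglik(eta, data.y).sum()
    lp += normal_logpdf_prec(state["b0"], 0.0, state["tau_locid"]).sum()
    lp += normal_logpdf_prec(state["a"], 0.0, DIFFUSE_PREC).sum()
    lp += normal_logpdf_prec(
        state["beta"], state["mu"][:, None], state["tau_k"][:, None]
    ).sum()
    lp += normal_logpdf_prec(state["mu"], 0.0, DIFFUSE_PREC).sum()
    lp += normal_logpdf_prec(state["eps"], 0.0, state["tau_brood"]).sum()
    lp += gamma_logpdf(state["tau_k"], GAMMA_SHAPE, GAMMA_RATE).sum()
    lp += gamma_logpdf(state["tau_locid"], GAMMA_SHAPE, GAMMA_RATE).sum()
    lp += gamma_logpdf(state["tau_brood"], GAMMA_SHAPE, GAMMA_RATE).sum()
    return float(lp)


def _draw_gamma(rng, shape, rate):
    return rng.gamma(shape, 1.0 / rate)


def _sweep_rsf3(state, data, adapters, rng, adapt: bool, lik_weight: float) -> None:
    eta = linear_predictor_rsf3(state, data)
    ones = np.ones(data.n)
    # stratum intercepts (disjoint rows -> parallel update)
    acc, eta = _grouped_rw_update(
        eta, data.y, ones, data.strat_idx, state["b0"], adapters["b0"].scales,
        0.0, state["tau_locid"], rng, lik_weight,
    )
    if adapt:
        adapters["b0"].record(acc)
    # fixed age offsets (global blocks: single group over all rows)
    zero_idx = np.zeros(data.n, dtype=int)
    for m in range(len(AGE_COLS)):
        val = state["a"][m : m + 1]
        acc, eta = _grouped_rw_update(
            eta, data.y, data.Z[:, m], zero_idx, val, adapters["a"].scales[m : m + 1],
            0.0, DIFFUSE_PREC, rng, lik_weight,
        )
        if adapt:
            adapters["a"].acc[m] += acc[0]
    if adapt:
        adapters["a"].count += 1
        if adapters["a"].count >= adapters["a"].every:
            rate = adapters["a"].acc / adapters["a"].count
            adapters["a"].scales *= np.exp(1.5 * (rate - adapters["a"].target))
            adapters["a"].acc[:] = 0
            adapters["a"].count = 0
    # brood-specific slopes, one covariate at a time (broods partition rows)
    for k in range(len(SLOPE_COLS)):
        acc, eta = _grouped_rw_update(
            eta, data.y, data.X[:, k], data.brood_idx, state["beta"][k],
            adapters["beta"].scales[k], state["mu"][k], state["tau_k"][k],
            rng, lik_weight,
        )
        if adapt:
            adapters["beta"].acc[k] += acc
    if adapt:
        adapters["beta"].count += 1
        ad = adapters["beta"]
        if ad.count >= ad.every:
            rate = ad.acc / ad.count
            ad.scales *= np.exp(1.5 * (rate - ad.target))
            np.clip(ad.scales, 1e-4, 50.0, out=ad.scales)
            ad.acc[:] = 0
            ad.count = 0
    # brood intercepts
    acc, eta = _grouped_rw_update(
        eta, data.y, ones, data.brood_idx, state["eps"], adapters["eps"].scales,
        0.0, state["tau_brood"], rng, lik_weight,
    )
    if adapt:
        adapters["eps"].record(acc)
    # conjugate Gibbs: population means and all precisions
    J = data.n_broods
    post_prec = DIFFUSE_PREC + J * state["tau_k"]
    post_mean = state["tau_k"] * state["beta"].sum(axis=1) / post_prec
    state["mu"] = rng.normal(post_mean, 1.0 / np.sqrt(post_prec))
    dev = state["beta"] - state["mu"][:, None]
    sh = GAMMA_SHAPE + J / 2.0
    state["tau_k"] = _draw_gamma(rng, sh, GAMMA_RATE + 0.5 * (dev**2).sum(axis=1))
    sh_l, rt_l = update_precision_conjugate(state["b0"])
    state["tau_locid"] = _draw_gamma(rng, sh_l, rt_l)
    sh_b, rt_b = update_precision_conjugate(state["eps"])
    state["tau_brood"] = _draw_gamma(rng, sh_b, rt_b)


def _monitored_rsf3(state: dict) -> dict:
    out = {c: state["mu"][i] for i, c in enumerate(SLOPE_COLS)}
    out.update({c: state["a"][i] for i, c in enumerate(AGE_COLS)})
    out["tau.brood"] = state["tau_brood"]
    out["tau.locid"] = state["tau_locid"]
    return out


def _new_adapters_rsf3(data: _RSF3Data, cfg: McmcConfig) -> dict:
    return {
        "b0": _Adapter(data.n_strata, cfg.target_accept, cfg.adapt_every),
        "a": _Adapter(len(AGE_COLS), cfg.target_accept, cfg.adapt_every),
        "beta": _Adapter((len(SLOPE_COLS), data.n_broods), cfg.target_accept, cfg.adapt_every),
        "eps": _Adapter(data.n_broods, cfg.target_accept, cfg.adapt_every),
    }


def _run_chains(data, cfg, init_fn, sweep_fn, monitor_fn, new_adapters_fn, lik_weight):
    """Generic increment-until-converged driver shared by both models."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    rngs = [np.random.default_rng(s) for s in seeds]
    states, adapters = [], []
    for rng in rngs:
        st = init_fn(data, rng)
        ad = new_adapters_fn(data, cfg)
        for _ in range(cfg.burn_in):
            sweep_fn(st, data, ad, rng, True, lik_weight)
        states.append(st)
        adapters.append(ad)
    names = list(monitor_fn(states[0]).keys())
    draws: list[list[dict]] = [[] for _ in range(cfg.n_chains)]
    converged = False
    total_iters = 0
    for _ in range(cfg.max_increments):
        for c in range(cfg.n_chains):
            rng, st, ad = rngs[c], states[c], adapters[c]
            for it in range(cfg.increment):
                sweep_fn(st, data, ad, rng, False, lik_weight)
                if (total_iters + it + 1) % cfg.thin == 0:
                    draws[c].append(monitor_fn(st))
        total_iters += cfg.increment
        chains = {
            nm: np.array([[d[nm] for d in draws[c]] for c in range(cfg.n_chains)])
            for nm in names
        }
        rhats = {nm: rhat(ch) for nm, ch in chains.items()}
        if max(rhats.values()) < cfg.rhat_threshold:
            converged = True
            break
    if not converged:
        worst = max(rhats, key=rhats.get)
        warnings.warn(
            f"chains not converged after {total_iters} iterations; worst "
            f"Rhat {rhats[worst]:.3f} ({worst})",
            RuntimeWarning,
        )
    frames = []
    for c in range(cfg.n_chains):
        df = pd.DataFrame(draws[c])
        df.insert(0, "draw", np.arange(len(df)))
        df.insert(0, "chain", c)
        frames.append(df)
    samples = pd.concat(frames, ignore_index=True)
    pooled = {nm: samples[nm].to_numpy() for nm in names}
    summary = pd.DataFrame(
        {nm: summarize_posterior(pooled[nm], rhats[nm]) for nm in names}
    ).T
    return FitResult(samples, summary, converged, total_iters, names)


def fit_rsf3(
    design: pd.DataFrame, config: McmcConfig, lik_weight: float = 1.0
) -> FitResult:
    """Fit the third-order model to a standardized choice-set design.

    ``design`` needs columns locid, brood_id, used plus the standardized
    covariates of :data:`broodsel.choice_design.DESIGN_COLS`.  Monitored
    parameters are the population slope means (named after their covariate),
    the chick/juvenile age offsets, and tau.brood / tau.locid.
    """
    data = _RSF3Data(design)
    return _run_chains(
        data, config, init_state_rsf3, _sweep_rsf3, _monitored_rsf3,
        _new_adapters_rsf3, lik_weight,
    )


# ---------------------------------------------------------------------------
# fourth-order model


class _RSF4Data:
    def __init__(self, design: pd.DataFrame):
        d = design.sort_values(["pair_id", "used"], ascending=[True, False], kind="stable")
        sizes = d.groupby("pair_id").size()
        if not (sizes == 2).all():
            raise ValueError("each pair must have exactly 2 records")
        if not (d.groupby("pair_id")["used"].sum() == 1).all():
            raise ValueError("each pair needs exactly one used (roost) record")
        self.y = d["used"].to_numpy(dtype=float)
        self.X = d[RSF4_SLOPE_COLS].to_numpy(dtype=float)
        self.season = d["season"].to_numpy(dtype=float)
        ages = d["age_class"].to_numpy()
        unknown = set(ages) - set(AGE_LEVELS)
        if unknown:
            raise ValueError(f"unknown age classes: {sorted(unknown)}")
        self.age_idx = np.array([AGE_LEVELS.index(a) for a in ages])
        pairs, self.pair_idx = np.unique(d["pair_id"].to_numpy(), return_inverse=True)
        broods, self.brood_idx = np.unique(d["brood_id"].to_numpy(), return_inverse=True)
        self.n_pairs = pairs.size
        self.n_broods = broods.size
        self.n = len(d)


def init_state_rsf4(data: _RSF4Data, rng: np.random.Generator) -> dict:
    K = len(RSF4_SLOPE_COLS)
    return {
        "bA": rng.normal(0, 0.1, len(AGE_LEVELS)),
        "beta": rng.normal(0, 0.1, (K, len(AGE_LEVELS))),
        "mu": rng.normal(0, 0.1, K),
        "tau_k": np.ones(K),
        "gamma_season": rng.normal(0, 0.1),
        "eps_brood": rng.normal(0, 0.1, data.n_broods),
        "eps_pair": rng.normal(0, 0.1, data.n_pairs),
        "tau_brood": 1.0,
        "tau_pair": 1.0,
    }


def linear_predictor_rsf4(state: dict, data: _RSF4Data) -> np.ndarray:
    return (
        state["bA"][data.age_idx]
        + np.einsum("nk,kn->n", data.X, state["beta"][:, data.age_idx])
        + state["gamma_season"] * data.season
        + state["eps_brood"][data.brood_idx]
        + state["eps_pair"][data.pair_idx]
    )


def log_posterior_rsf4(state: dict, data: _RSF4Data, lik_weight: float = 1.0) -> float:
    for v in state.values():
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite parameter in state")
    eta = linear_predictor_rsf4(state, data)
    lp = lik_weight * bernoulli_loglik(eta, data.y).sum()
    lp += normal_logpdf_prec(state["bA"], 0.0, DIFFUSE_PREC).sum()
    lp += normal_logpdf_prec(
        state["beta"], state["mu"][:, None], state["tau_k"][:, None]
    ).sum()
    lp += normal_logpdf_prec(state["mu"], 0.0, DIFFUSE_PREC).sum()
    lp += normal_logpdf_prec(np.asarray(state["gamma_season"]), 0.0, DIFFUSE_PREC).sum()
    lp += normal_logpdf_prec(state["eps_brood"], 0.0, state["tau_brood"]).sum()
    lp += normal_logpdf_prec(state["eps_pair"], 0.0, state["tau_pair"]).sum()
    for tau in ("tau_k", "tau_brood", "tau_pair"):
        lp += gamma_logpdf(np.asarray(state[tau]), GAMMA_SHAPE, GAMMA_RATE).sum()
    return float(lp)


def _new_adapters_rsf4(data: _RSF4Data, cfg: McmcConfig) -> dict:
    A = len(AGE_LEVELS)
    return {
        "bA": _Adapter(A, cfg.target_accept, cfg.adapt_every),
        "beta": _Adapter((len(RSF4_SLOPE_COLS), A), cfg.target_accept, cfg.adapt_every),
        "gamma": _Adapter(1, cfg.target_accept, cfg.adapt_every),
        "eps_brood": _Adapter(data.n_broods, cfg.target_accept, cfg.adapt_every),
        "eps_pair": _Adapter(data.n_pairs, cfg.target_accept, cfg.adapt_every),
    }


def _sweep_rsf4(state, data, adapters, rng, adapt: bool, lik_weight: float) -> None:
    eta = linear_predictor_rsf4(state, data)
    ones = np.ones(data.n)
    # age-class intercepts (age classes partition rows)
    acc, eta = _grouped_rw_update(
        eta, data.y, ones, data.age_idx, state["bA"], adapters["bA"].scales,
        0.0, DIFFUSE_PREC, rng, lik_weight,
    )
    if adapt:
        adapters["bA"].record(acc)
    # age-specific slopes
    for k in range(len(RSF4_SLOPE_COLS)):
        acc, eta = _grouped_rw_update(
            eta, data.y, data.X[:, k], data.age_idx, state["beta"][k],
            adapters["beta"].scales[k], state["mu"][k], state["tau_k"][k],
            rng, lik_weight,
        )
        if adapt:
            adapters["beta"].acc[k] += acc
    if adapt:
        ad = adapters["beta"]
        ad.count += 1
        if ad.count >= ad.every:
            rate = ad.acc / ad.count
            ad.scales *= np.exp(1.5 * (rate - ad.target))
            np.clip(ad.scales, 1e-4, 50.0, out=ad.scales)
            ad.acc[:] = 0
            ad.count = 0
    # global season coefficient
    gval = np.atleast_1d(np.asarray(state["gamma_season"], dtype=float))
    acc, eta = _grouped_rw_update(
        eta, data.y, data.season, np.zeros(data.n, dtype=int), gval,
        adapters["gamma"].scales, 0.0, DIFFUSE_PREC, rng, lik_weight,
    )
    state["gamma_season"] = float(gval[0])
    if adapt:
        adapters["gamma"].record(acc)
    # brood and pair random intercepts
    acc, eta = _grouped_rw_update(
        eta, data.y, ones, data.brood_idx, state["eps_brood"],
        adapters["eps_brood"].scales, 0.0, state["tau_brood"], rng, lik_weight,
    )
    if adapt:
        adapters["eps_brood"].record(acc)
    acc, eta = _grouped_rw_update(
        eta, data.y, ones, data.pair_idx, state["eps_pair"],
        adapters["eps_pair"].scales, 0.0, state["tau_pair"], rng, lik_weight,
    )
    if adapt:
        adapters["eps_pair"].record(acc)
    # conjugate Gibbs
    A = len(AGE_LEVELS)
    post_prec = DIFFUSE_PREC + A * state["tau_k"]
    post_mean = state["tau_k"] * state["beta"].sum(axis=1) / post_prec
    state["mu"] = rng.normal(post_mean, 1.0 / np.sqrt(post_prec))
    dev = state["beta"] - state["mu"][:, None]
    state["tau_k"] = _draw_gamma(
        rng, GAMMA_SHAPE + A / 2.0, GAMMA_RATE + 0.5 * (dev**2).sum(axis=1)
    )
    sh, rt = update_precision_conjugate(state["eps_brood"])
    state["tau_brood"] = _draw_gamma(rng, sh, rt)
    sh, rt = update_precision_conjugate(state["eps_pair"])
    state["tau_pair"] = _draw_gamma(rng, sh, rt)


_RSF4_DISPLAY = {
    "temp_mean": "Temp",
    "woody": "Woody",
    "grass": "Grass",
    "temp_cv": "TempCV",
    "bareness": "Bareness",
    "obscurity": "Obscurity",
    "woody_season": "Woody*Season",
}


def _monitored_rsf4(state: dict) -> dict:
    out = {age: state["bA"][i] for i, age in enumerate(AGE_LEVELS)}
    for k, col in enumerate(RSF4_SLOPE_COLS):
        for a, age in enumerate(AGE_LEVELS):
            out[f"{_RSF4_DISPLAY[col]}*{age.capitalize()}"] = state["beta"][k, a]
    out["Season"] = state["gamma_season"]
    out["tau.pair"] = state["tau_pair"]
    out["tau.brood"] = state["tau_brood"]
    return out


def fit_rsf4(
    design: pd.DataFrame, config: McmcConfig, lik_weight: float = 1.0
) -> FitResult:
    """Fit the fourth-order paired roost model.

    ``design`` needs columns pair_id, brood_id, age_class, used, season and
    the standardized covariates of :data:`RSF4_SLOPE_COLS`.  Monitored
    parameters are the per-age intercepts and slopes (e.g. "Woody*Neonate"),
    the global Season coefficient, and tau.pair / tau.brood.
    """
    data = _RSF4Data(design)
    return _run_chains(
        data, config, init_state_rsf4, _sweep_rsf4, _monitored_rsf4,
        _new_adapters_rsf4, lik_weight,
    )
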