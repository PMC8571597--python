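"""Parameter-recovery simulation studies.

Each study simulates data under known coefficients (the package's default
generating truth), runs the corresponding model fit, and reports recovered
posterior means.  Estimates are averaged over a small number of independent
replicate simulations, which reduces simulation (data-realization) noise
without touching the per-replicate problem size; per-replicate results are
returned alongside the averages.

Problem sizes follow the package's desk-scale study design: ~500 choice
sets over 25 broods for the third-order model and 600 roost pairs (200 per
age class) for the fourth-order model, with chains extended in reduced
increments until Rhat < 1.1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import bayes_rsf, choice_design, roost_micro, synthetic_data
from .bayes_rsf import McmcConfig


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss]


def third_order_recovery_study(
    seed: int,
    n_replicates: int = 3,
    n_broods: int = 25,
    mcmc_increment: int = 2500,
    mcmc_max_increments: int = 5,
) -> dict:
    """Recover third-order population slopes from simulated choice sets.

    Each replicate simulates ~500 conditional-logit choice sets (1 used +
    5 available) across ``n_broods`` broods under the default generating
    coefficients, using the iid-covariate choice-set generator (see
    ``simulate_gaussian_choice_sets`` for why that is the design whose
    coefficients the fitted model can recover), standardizes the pooled
    design, and fits the hierarchical discrete-choice model.  Returns the
    generating truth, per-replicate posterior means, and their average.
    """
    truth = dict(synthetic_data.DEFAULT_RSF3_TRUTH)
    reps = []
    for rep_seed in _child_seeds(seed, n_replicates):
        s_brood, s_mcmc = _child_seeds(rep_seed, 2)
        bcfg = synthetic_data.BroodSimConfig(
            seed=s_brood, n_broods=n_broods, n_candidates=50
        )
        records, _ = synthetic_data.simulate_gaussian_choice_sets(bcfg)
        design, _ = choice_design.build_design_rsf3(records)
        cfg = McmcConfig.rsf3_default(seed=s_mcmc).reduced(
            increment=mcmc_increment, max_increments=mcmc_max_increments
        )
        fit = bayes_rsf.fit_rsf3(design, cfg)
        reps.append(
            {
                "n_choice_sets": int(records["locid"].nunique()),
                "converged": fit.converged,
                "posterior_mean": {
                    k: float(fit.summary.loc[k, "mean"]) for k in truth
                },
                "ci_half_width": {
                    k: float(
                        (fit.summary.loc[k, "q97.5"] - fit.summary.loc[k, "q2.5"]) / 2
                    )
                    for k in truth
                },
            }
        )
    estimate = {
        k: float(np.mean([r["posterior_mean"][k] for r in reps])) for k in truth
    }
    return {
        "truth": truth,
        "estimate": estimate,
        "replicates": reps,
        "n": sum(r["n_choice_sets"] for r in reps) // len(reps),
    }


def fourth_order_recovery_study(
    seed: int,
    n_replicates: int = 5,
    n_pairs_per_age: int = 200,
    mcmc_increment: int = 4000,
    mcmc_max_increments: int = 3,
) -> dict:
    """Recover fourth-order age-specific slopes from simulated roost pairs.

    Each replicate simulates ``n_pairs_per_age`` pairs per age class with
    the tilted-Gaussian generator (covariates on the standardized scale;
    exact exponential-tilt estimand) and fits the paired hierarchical
    model without re-standardization.
    """
    truth = {}
    for cov, vals in synthetic_data.DEFAULT_RSF4_TRUTH.items():
        disp = bayes_rsf._RSF4_DISPLAY[cov]
        for age, v in zip(bayes_rsf.AGE_LEVELS, vals):
            truth[f"{disp}*{age.capitalize()}"] = float(v)
    reps = []
    for rep_seed in _child_seeds(seed, n_replicates):
        s_data, s_mcmc = _child_seeds(rep_seed, 2)
        rcfg = synthetic_data.RoostSimConfig(
            seed=s_data,
            n_pairs={a: n_pairs_per_age for a in bayes_rsf.AGE_LEVELS},
        )
        records, _ = synthetic_data.simulate_tilted_roost_pairs(rcfg)
        paired = roost_micro.build_pair_table(records)
        design, _ = roost_micro.build_design_rsf4(paired, standardize_covariates=False)
        cfg = dataclasses.replace(
            McmcConfig.rsf4_default(seed=s_mcmc),
            burn_in=2000,
            increment=mcmc_increment,
            max_increments=mcmc_max_increments,
        )
        fit = bayes_rsf.fit_rsf4(design, cfg)
        reps.append(
            {
                "n_pairs": int(len(paired) // 2),
                "converged": fit.converged,
                "posterior_mean": {
                    k: float(fit.summary.loc[k, "mean"]) for k in truth
                },
            }
        )
    estimate = {
        k: float(np.mean([r["posterior_mean"][k] for r in reps])) for k in truth
    }
    return {
        "truth": truth,
        "estimate": estimate,
        "replicates": reps,
        "n": reps[0]["n_pairs"],
    }
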