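"""Fit the fourth-order paired roost-site model.

Simulates roost / paired-available records with known age-specific
coefficients via the tilted-Gaussian recovery generator, then fits the
paired Bernoulli model with hierarchical age-specific slopes.  Positive
slopes mean roosts carry more of a covariate than the paired available
site 15 m away; the age interaction shows how selection changes from
neonate (0-7 d) through juvenile (28-42 d).

Runs a small problem (~1-2 min).
"""

import warnings

from broodsel import (
    McmcConfig,
    RoostSimConfig,
    build_design_rsf4,
    build_pair_table,
    fit_rsf4,
    simulate_tilted_roost_pairs,
)

warnings.filterwarnings("ignore", category=RuntimeWarning)

cfg = RoostSimConfig(seed=21, n_pairs={"neonate": 120, "chick": 120, "juvenile": 120})
records, truth = simulate_tilted_roost_pairs(cfg)
print(f"simulated {records['pair_id'].nunique()} roost/available pairs")

design, _ = build_design_rsf4(build_pair_table(records), standardize_covariates=False)
fit = fit_rsf4(
    design,
    McmcConfig.rsf4_default(seed=22, burn_in=1500, increment=2000, max_increments=3),
)
print(f"chains converged: {fit.converged}\n")

rows = ["Woody*Neonate", "Woody*Juvenile", "TempCV*Neonate", "TempCV*Juvenile",
        "Bareness*Neonate", "Obscurity*Neonate", "Obscurity*Juvenile"]
print(f"{'parameter':<20}{'truth':>8}{'mean':>8}{'2.5%':>8}{'97.5%':>8}")
truth_map = {}
for cov, vals in truth["coefficients"].items():
    for age, v in zip(["Neonate", "Chick", "Juvenile"], vals):
        key = {"temp_mean": "Temp", "temp_cv": "TempCV", "woody_season": "Woody*Season"}.get(
            cov, cov.capitalize()
        )
        truth_map[f"{key}*{age}"] = v
for name in rows:
    row = fit.summary.loc[name]
    print(f"{name:<20}{truth_map[name]:>8.2f}{row['mean']:>8.2f}"
          f"{row['q2.5']:>8.2f}{row['q97.5']:>8.2f}")
print("\nNeonates select thermally stable, concealed roosts (negative "
      "temperature-CV slope, positive obscurity); the pattern reverses for "
      "juveniles as mobility and thermoregulation develop.")
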