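"""Marginal-effect curves from a fitted third-order model.

Builds a small simulated fit, then traces how the relative probability of
use changes with distance to supplemental feed, separately for the early
(on or before July 15) and late nesting season.  Non-focal covariates sit
at their standardized mean, random effects at zero, so the curves describe
a population-median brood.
"""

import warnings

import numpy as np

from broodsel import (
    BroodSimConfig,
    LandscapeConfig,
    McmcConfig,
    build_design_rsf3,
    engineer_surfaces,
    fit_rsf3,
    generate_landscape,
    marginal_effect_curve,
)
from broodsel.synthetic_data import simulate_choice_sets

warnings.filterwarnings("ignore", category=RuntimeWarning)

grid, feedlines, _ = generate_landscape(LandscapeConfig(seed=3))
surfaces = engineer_surfaces(grid, feedlines)
records, _ = simulate_choice_sets(
    grid, surfaces, BroodSimConfig(seed=4, n_broods=10, day_step=2, slots_per_day=1)
)
design, moments = build_design_rsf3(records)
fit = fit_rsf3(design, McmcConfig.rsf3_default(seed=5, increment=1000, max_increments=2))

grid_m = np.array([0.0, 25.0, 50.0, 75.0])
print("relative probability of use vs distance to feed (posterior mean [95% CrI]):")
for season, label in [(0, "early season"), (1, "late season")]:
    curve = marginal_effect_curve(
        fit, "feed", grid_m, moments, conditioning={"season": season}
    )
    cells = "  ".join(
        f"{x:3.0f} m: {m:.2f} [{lo:.2f},{hi:.2f}]"
        for x, m, lo, hi in curve.itertuples(index=False)
    )
    print(f"  {label:<13} {cells}")
print("\nA steeper late-season decline reproduces the stronger pull of "
      "supplemental feed later in the nesting season.")
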