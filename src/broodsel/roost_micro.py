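"""Fourth-order (roost-site) covariate construction.

Each monitored roost is paired with an available site 15 m away at a random
azimuth.  Both sites carry:

* a nocturnal ground-surface temperature trace — 28 readings at 20-min
  intervals from 21:00 to 06:00, sensor-quantized to 0.5 °C — summarized as
  the trace mean (°C) and its coefficient of variation (thermal stability),
* vegetation composition from a 225-point systematic grid over a 1-m²
  quadrat image, with five functional groups (woody, grass, forb, bare
  ground, litter); bare ground and litter are pooled into a "bareness"
  index of traversability,
* visual obscurity, the share of a 1-m² cover board hidden by vegetation.

Highly correlated covariates are screened by pairwise Pearson |r| against a
threshold, keeping the column ranked higher in a caller-supplied priority
order (e.g. woody over forb at |r| = 0.72).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

TEMP_RANGE = (-40.0, 85.0)
TEMP_STEP = 0.5
N_READINGS = 28
N_GRID_POINTS = 225

VEG_GROUPS = ["woody", "grass", "forb", "bare", "litter"]

#: Covariates entering the fourth-order model (forb is screened out by
#: default; woody_season is the woody x late-season interaction).
RSF4_COVS = ["temp_mean", "temp_cv", "woody", "grass", "bareness", "obscurity"]


def reading_schedule(night: str | pd.Timestamp) -> pd.DatetimeIndex:
    """The 28 sensor timestamps for one night: 21:00 ... 06:00 at 20 min."""
    start = pd.Timestamp(night).normalize() + pd.Timedelta(hours=21)
    return pd.date_range(start, periods=N_READINGS, freq="20min")


def validate_trace(readings: np.ndarray) -> np.ndarray:
    """Enforce the sensor protocol: 28 readings, in range, 0.5 °C steps."""
    readings = np.asarray(readings, dtype=float)
    if readings.size != N_READINGS:
        raise ValueError(f"expected {N_READINGS} readings, got {readings.size}")
    lo, hi = TEMP_RANGE
    if readings.min() < lo or readings.max() > hi:
        raise ValueError(f"readings outside sensor range {TEMP_RANGE}")
    steps = readings / TEMP_STEP
    if not np.allclose(steps, np.round(steps), atol=1e-9):
        raise ValueError(f"readings must be quantized to {TEMP_STEP} °C steps")
    return readings


def temp_summary(readings: np.ndarray) -> tuple[float, float]:
    """(mean, CV) of a validated 28-reading trace, on the Celsius scale.

    CV uses the sample (n-1) standard deviation.  A non-positive mean makes
    the CV sign-unstable; it is returned but flagged via a warning value of
    NaN only when the mean is exactly zero.
    """
    readings = validate_trace(readings)
    mean = float(readings.mean())
    sd = float(readings.std(ddof=1))
    if mean == 0.0:
        return mean, float("nan")
    return mean, sd / mean


def composition_from_grid(
    veg_labels: np.ndarray | list[str],
    obscurity_labels: np.ndarray | list[str] | None = None,
) -> dict[str, float]:
    """Percent cover per functional group from 225 point labels.

    ``veg_labels`` are the quadrat-image point classifications; percentages
    are count/225 x 100 and bareness = bare% + litter%.  ``obscurity_labels``
    (values 'vegetated'/'open' from the cover-board image) yield obscurity%.
    """
    veg_labels = np.asarray(veg_labels)
    if veg_labels.size != N_GRID_POINTS:
        raise ValueError(f"expected {N_GRID_POINTS} point labels, got {veg_labels.size}")
    unknown = set(np.unique(veg_labels).tolist()) - set(VEG_GROUPS)
    if unknown:
        raise ValueError(f"unknown functional groups: {sorted(unknown)}")
    out = {
        g: float(np.count_nonzero(veg_labels == g)) / N_GRID_POINTS * 100.0
        for g in VEG_GROUPS
    }
    out["bareness"] = out["bare"] + out["litter"]
    if obscurity_labels is not None:
        obs = np.asarray(obscurity_labels)
        if obs.size != N_GRID_POINTS:
            raise ValueError(
                f"expected {N_GRID_POINTS} cover-board labels, got {obs.size}"
            )
        bad = set(np.unique(obs).tolist()) - {"vegetated", "open"}
        if bad:
            raise ValueError(f"unknown cover-board labels: {sorted(bad)}")
        out["obscurity"] = (
            float(np.count_nonzero(obs == "vegetated")) / N_GRID_POINTS * 100.0
        )
    return out


def composition_from_counts(counts: dict[str, int]) -> dict[str, float]:
    """Same as :func:`composition_from_grid` but from pre-tallied counts."""
    total = sum(counts.get(g, 0) for g in VEG_GROUPS)
    if total != N_GRID_POINTS:
        raise ValueError(f"counts must sum to {N_GRID_POINTS}, got {total}")
    out = {g: counts.get(g, 0) / N_GRID_POINTS * 100.0 for g in VEG_GROUPS}
    out["bareness"] = out["bare"] + out["litter"]
    return out


def correlation_screen(
    table: pd.DataFrame,
    threshold: float,
    priority: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop one member of every covariate pair with |Pearson r| >= threshold.

    ``priority`` ranks columns from most to least preferred; of an offending
    pair the lower-priority column is dropped.  Unlisted columns rank below
    listed ones, ties broken alphabetically so the decision is deterministic
    and independent of input column order.  Returns (retained columns, a
    report of all screened pairs with r and the decision).
    """
    cols = list(table.columns)
    if len(cols) < 2 or len(table) < 3:
        raise ValueError("need >= 2 columns and >= 3 rows")
    sds = table.std(ddof=1)
    const = sds[sds == 0].index.tolist()
    if const:
        raise ValueError(f"constant columns cannot be screened: {const}")
    priority = priority or []

    def rank(c: str) -> tuple[int, str]:
        return (priority.index(c) if c in priority else len(priority), c)

    corr = table.corr(method="pearson")
    dropped: set[str] = set()
    report_rows = []
    for a, b in itertools.combinations(sorted(cols, key=rank), 2):
        r = float(corr.loc[a, b])
        flag = abs(r) >= threshold
        drop = None
        if flag and a not in dropped and b not in dropped:
            drop = max(a, b, key=rank)
            dropped.add(drop)
        report_rows.append(
            {"col_a": a, "col_b": b, "r": r, "flagged": flag, "dropped": drop}
        )
    retained = [c for c in cols if c not in dropped]
    return retained, pd.DataFrame(report_rows)


def pair_records(
    roost: dict | pd.Series, available: dict | pd.Series
) -> pd.DataFrame:
    """Align one roost and one available record into the two design rows of
    a matched pair (shared pair_id/brood_id/age_class/season, used flags 1/0).
    """
    roost, available = dict(roost), dict(available)
    for key in ("pair_id", "brood_id", "age_class", "season"):
        if roost.get(key) != available.get(key):
            raise ValueError(f"pair members disagree on {key!r}")
    roles = {roost.get("role"), available.get("role")}
    if roles != {"roost", "available"}:
        raise ValueError(f"pair must contain one roost and one available, got {roles}")
    rows = []
    for rec in (roost, available):
        rec = dict(rec)
        rec["used"] = int(rec["role"] == "roost")
        rows.append(rec)
    return pd.DataFrame(rows)


def build_pair_table(records: pd.DataFrame) -> pd.DataFrame:
    """Validate and order a full table of paired records (2 rows per pair)."""
    frames = []
    for pid, grp in records.groupby("pair_id", sort=True):
        if len(grp) != 2:
            raise ValueError(f"pair {pid!r} has {len(grp)} records, expected 2")
        roles = grp.set_index("role", drop=False)
        if set(roles.index) != {"roost", "available"}:
            raise ValueError(f"pair {pid!r} roles invalid: {sorted(roles.index)}")
        frames.append(pair_records(roles.loc["roost"], roles.loc["available"]))
    return pd.concat(frames, ignore_index=True)


def build_design_rsf4(
    records: pd.DataFrame, standardize_covariates: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize fourth-order covariates and add the woody x season column.

    Expects the validated pair table (``build_pair_table``).  Forb is
    excluded from the design by the correlation screen; season enters both
    as a global main effect and through woody_season (product of
    standardized parents).  Returns (design, moments).
    """
    from .choice_design import standardize  # shared z-scoring rule

    req = {"pair_id", "brood_id", "age_class", "season", "used", *RSF4_COVS}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"pair records missing columns: {sorted(missing)}")
    tab = records.copy()
    cols = RSF4_COVS + ["season"]
    if standardize_covariates:
        tab, moments = standardize(tab, cols)
    else:
        moments = pd.DataFrame(
            {c: (0.0, 1.0) for c in cols}, index=["mean", "sd"]
        ).T
    tab["woody_season"] = tab["woody"] * tab["season"]
    keep = ["pair_id", "brood_id", "age_class", "used", "season"] + RSF4_COVS + [
        "woody_season"
    ]
    return tab[keep].copy(), moments
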