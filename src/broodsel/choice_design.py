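"""Third-order use-availability choice sets.

Each used telemetry fix is grouped with 5 random "available" points drawn
uniformly inside a per-brood circular buffer centred on the used location.
The buffer radius is 1 sample standard deviation above the brood's mean
step length, so broods that moved little are offered less of the landscape
as available.  Used and available records share a stratum id (``locid``)
and feed a discrete-choice logistic model.

Covariates per record:

====== =======================================================
bu      proportion burned upland within the focal radius
ff      proportion fallow field
dr      proportion hardwood drain
feed    distance to the nearest supplemental feedline (m)
tod     time of day (1 = roost, 0 = diurnal)
season  nesting season half (1 = late, after July 15)
====== =======================================================

plus the brood age class (neonate 0-7 d / chick 8-27 d / juvenile 28+ d).
All model inputs, binary indicators included, are z-scored over the pooled
used+available records; interactions are products of standardized parents.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .landscape import Surface, extract_at_points

#: Brood-level random-slope columns of the third-order design, fixed order.
SLOPE_COLS = [
    "bu",
    "ff",
    "dr",
    "feed",
    "tod",
    "season",
    "bu_tod",
    "dr_tod",
    "ff_tod",
    "feed_bu",
    "feed_chick",
    "feed_juv",
    "feed_season",
    "bu_season",
]
#: Fixed age-offset columns (neonate is the reference, coefficient 0).
AGE_COLS = ["chick", "juv"]
DESIGN_COLS = SLOPE_COLS + AGE_COLS

AGE_CLASS_BREAKS = ((0, 7, "neonate"), (8, 27, "chick"), (28, 10_000, "juvenile"))

ROOST_SLOTS = {"roost", "weekend-roost"}
SEASON_SPLIT = (7, 15)  # late nesting season starts after July 15


def age_class(age_days: int) -> str:
    """Developmental age class from age in days."""
    if age_days < 0:
        raise ValueError("age_days must be >= 0")
    for lo, hi, name in AGE_CLASS_BREAKS:
        if lo <= age_days <= hi:
            return name
    raise AssertionError("unreachable")


def is_late_season(timestamp: pd.Timestamp) -> int:
    ts = pd.Timestamp(timestamp)
    return int((ts.month, ts.day) > SEASON_SPLIT)


def step_lengths(fixes: pd.DataFrame) -> np.ndarray:
    """Euclidean distances between consecutive fixes of one brood.

    ``fixes`` must be chronologically sorted; fewer than 2 fixes give an
    empty array.
    """
    ts = pd.to_datetime(fixes["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("fixes must be sorted by timestamp")
    if len(fixes) < 2:
        return np.empty(0)
    dx = np.diff(fixes["x"].to_numpy(dtype=float))
    dy = np.diff(fixes["y"].to_numpy(dtype=float))
    return np.hypot(dx, dy)


def availability_radius(steps: np.ndarray, floor_m: float = 30.0) -> float:
    """Mean + 1 sample SD of a brood's step lengths, floored at ``floor_m``.

    The floor guards the degenerate buffers short-lived broods produce
    (a brood dying on hatch day has no steps at all); with fewer than two
    steps the floor itself is returned.
    """
    if floor_m <= 0:
        raise ValueError("floor_m must be > 0")
    steps = np.asarray(steps, dtype=float)
    if steps.size < 2:
        return float(floor_m)
    return float(max(steps.mean() + steps.std(ddof=1), floor_m))


def sample_available(
    used_point: tuple[float, float],
    radius_m: float,
    n: int,
    bounds: tuple[float, float, float, float],
    rng: np.random.Generator,
    max_rounds: int = 1000,
) -> np.ndarray:
    """``n`` points uniform on the disc around ``used_point``, inside bounds.

    Points falling outside the study bounds are rejection-resampled, which
    preserves uniformity on the disc-bounds intersection.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    x0, y0 = used_point
    xmin, ymin, xmax, ymax = bounds
    if not (xmin <= x0 < xmax and ymin <= y0 < ymax):
        raise ValueError(f"used point {used_point} outside study bounds {bounds}")
    if (
        x0 + radius_m <= xmin
        or x0 - radius_m >= xmax
        or y0 + radius_m <= ymin
        or y0 - radius_m >= ymax
    ):
        raise ValueError("availability disc lies entirely outside study bounds")
    out = np.empty((0, 2))
    for _ in range(max_rounds):
        need = n - len(out)
        if need == 0:
            return out
        r = radius_m * np.sqrt(rng.random(need))
        theta = rng.random(need) * 2 * np.pi
        pts = np.column_stack([x0 + r * np.cos(theta), y0 + r * np.sin(theta)])
        ok = (
            (pts[:, 0] >= xmin)
            & (pts[:, 0] < xmax)
            & (pts[:, 1] >= ymin)
            & (pts[:, 1] < ymax)
        )
        out = np.vstack([out, pts[ok]])
    raise RuntimeError("could not place available points inside bounds")


def standardize(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """z-score columns; returns (standardized copy, per-column mean/sd).

    Raises on constant columns (their z-score is undefined)."""
    columns = list(columns if columns is not None else table.columns)
    out = table.copy()
    moments = {}
    for col in columns:
        vals = table[col].to_numpy(dtype=float)
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col] = (vals - mu) / sd
        moments[col] = (mu, sd)
    mom = pd.DataFrame(moments, index=["mean", "sd"]).T
    return out, mom


def build_choice_records(
    fixes: pd.DataFrame,
    surfaces: dict[str, Surface],
    n_available: int = 5,
    floor_m: float = 30.0,
    rng: np.random.Generator | None = None,
    bounds: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Assemble raw choice records (1 used + ``n_available`` per fix).

    ``surfaces`` must map 'bu', 'ff', 'dr' to focal-proportion surfaces and
    'feed' to a distance surface, all sharing one geometry.  Availability
    radii are per-brood (mean + SD of that brood's step lengths).  The
    brood's *first* fix has no step history but still anchors a choice set.
    """
    if rng is None:
        rng = np.random.default_rng()
    ref = surfaces["bu"]
    if bounds is None:
        bounds = ref.bounds
    fixes = fixes.sort_values(["brood_id", "timestamp"]).reset_index(drop=True)

    radii = {
        brood: availability_radius(step_lengths(grp), floor_m)
        for brood, grp in fixes.groupby("brood_id", sort=False)
    }

    rows: list[dict] = []
    for locid, fix in enumerate(fixes.itertuples(index=False)):
        pts = sample_available(
            (fix.x, fix.y), radii[fix.brood_id], n_available, bounds, rng
        )
        xs = np.concatenate([[fix.x], pts[:, 0]])
        ys = np.concatenate([[fix.y], pts[:, 1]])
        tod = int(str(fix.slot) in ROOST_SLOTS)
        season = is_late_season(fix.timestamp)
        acl = age_class(int(fix.age_days))
        cov = {name: extract_at_points(surf, xs, ys) for name, surf in surfaces.items()}
        for i in range(n_available + 1):
            rows.append(
                {
                    "locid": locid,
                    "brood_id": fix.brood_id,
                    "timestamp": fix.timestamp,
                    "used": int(i == 0),
                    "x": xs[i],
                    "y": ys[i],
                    "bu": cov["bu"][i],
                    "ff": cov["ff"][i],
                    "dr": cov["dr"][i],
                    "feed": cov["feed"][i],
                    "tod": tod,
                    "season": season,
                    "age_class": acl,
                }
            )
    return pd.DataFrame(rows)


def build_design_rsf3(
    records: pd.DataFrame, standardize_binary: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize covariates and expand the full third-order design.

    Returns ``(design, moments)``: ``design`` carries the id columns
    (locid, brood_id, used) plus the :data:`DESIGN_COLS` in fixed order,
    interactions formed as products of already-standardized parents;
    ``moments`` holds the mean/sd used, for back-transforming to raw scale.
    """
    req = {"locid", "brood_id", "used", "bu", "ff", "dr", "feed", "tod", "season", "age_class"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    counts = records.groupby("locid")["used"].sum()
    if not (counts == 1).all():
        bad = counts[counts != 1].index.tolist()[:5]
        raise ValueError(f"choice sets without exactly one used record: {bad}")

    tab = records.copy()
    tab["chick"] = (tab["age_class"] == "chick").astype(float)
    tab["juv"] = (tab["age_class"] == "juvenile").astype(float)

    continuous = ["bu", "ff", "dr", "feed"]
    binary = ["tod", "season", "chick", "juv"]
    cols = continuous + (binary if standardize_binary else [])
    std, moments = standardize(tab, cols)

    d = std
    d["bu_tod"] = d["bu"] * d["tod"]
    d["dr_tod"] = d["dr"] * d["tod"]
    d["ff_tod"] = d["ff"] * d["tod"]
    d["feed_bu"] = d["feed"] * d["bu"]
    d["feed_chick"] = d["feed"] * d["chick"]
    d["feed_juv"] = d["feed"] * d["juv"]
    d["feed_season"] = d["feed"] * d["season"]
    d["bu_season"] = d["bu"] * d["season"]

    keep = ["locid", "brood_id", "used"] + DESIGN_COLS
    return d[keep].copy(), moments
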