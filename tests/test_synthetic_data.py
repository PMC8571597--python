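"""Generators: landscape targets, telemetry schedule, selection structure,
roost-pair protocol, and seed reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from broodsel import synthetic_data as sd
from broodsel.choice_design import build_design_rsf3
from broodsel.landscape import CLASS_CODES, extract_at_points
from broodsel.roost_micro import build_design_rsf4, build_pair_table, validate_trace
from broodsel.synthetic_data import (
    BroodSimConfig,
    LandscapeConfig,
    RoostSimConfig,
    burn_unit_areas_ha,
    conditional_logit_choice,
    generate_landscape,
    simulate_broods,
    simulate_roost_pairs,
    simulate_tilted_roost_pairs,
)

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


@pytest.fixture(scope="module")
def landscape():
    cfg = LandscapeConfig(seed=11, extent_m=2000.0)
    return cfg, *generate_landscape(cfg)


@pytest.fixture(scope="module")
def surfaces(landscape):
    from broodsel.cli_report import engineer_surfaces

    _, grid, feedlines, _ = landscape
    return engineer_surfaces(grid, feedlines)


class TestLandscape:
    def test_class_proportions_near_targets(self, landscape):
        cfg, grid, _, _ = landscape
        props = grid.class_proportions()
        assert props["burned_upland"] + props["nonburned_upland"] == pytest.approx(
            0.66, abs=0.03
        )
        assert props["field"] == pytest.approx(0.13, abs=0.03)
        assert props["drain"] == pytest.approx(0.21, abs=0.03)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_burn_unit_mean_area(self, landscape):
        cfg, _, _, unit_map = landscape
        areas = burn_unit_areas_ha(unit_map, cfg.cell_size)
        assert areas.mean() == pytest.approx(17.8, rel=0.2)

    def test_feedline_density(self, landscape):
        cfg, grid, feedlines, _ = landscape
        area_ha = grid.n_rows * grid.n_cols * cfg.cell_size**2 / 1e4
        target = cfg.feedline_m_per_ha * area_ha
        assert feedlines.total_length() == pytest.approx(target, rel=0.10)

    def test_seed_reproducibility(self):
        cfg = LandscapeConfig(seed=77, extent_m=1200.0)
        g1, f1, u1 = generate_landscape(cfg)
        g2, f2, u2 = generate_landscape(LandscapeConfig(seed=77, extent_m=1200.0))
        np.testing.assert_array_equal(g1.cells, g2.cells)
        np.testing.assert_array_equal(f1.segments, f2.segments)
        np.testing.assert_array_equal(u1, u2)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(seed=1, prop_upland=0.9, prop_field=0.2, prop_drain=0.2)


class TestSchedule:
    def test_weekday_weekend_fix_counts(self):
        cfg = BroodSimConfig(seed=5, n_broods=3, monitor_days=42)
        sched = sd._schedule(cfg, np.random.default_rng(5))
        sched["date"] = sched["timestamp"].dt.date
        sched["wd"] = sched["timestamp"].dt.weekday
        tagged = sched[sched["age_days"] >= cfg.tag_age_days]
        per_day = tagged.groupby(["brood_id", "date", "wd"]).size().reset_index(name="n")
        assert (per_day[per_day["wd"] < 5]["n"] == 5).all()
        assert (per_day[per_day["wd"] >= 5]["n"] == 3).all()
        pre = sched[sched["age_days"] < cfg.tag_age_days]
        assert (pre.groupby(["brood_id", "date"]).size() == 3).all()


class TestConditionalLogitChoice:
    def test_null_selection_uniform(self, rng):
        # all-zero predictor: chosen index uniform over the candidate set
        counts = np.zeros(8)
        for _ in range(10_000):
            counts[conditional_logit_choice(np.zeros(8), rng)] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_softmax_frequencies(self, rng):
        eta = np.array([0.0, 1.0, 2.0])
        want = np.exp(eta) / np.exp(eta).sum()
        counts = np.zeros(3)
        for _ in range(20_000):
            counts[conditional_logit_choice(eta, rng)] += 1
        np.testing.assert_allclose(counts / 20_000, want, atol=0.015)


class TestBroodSimulation:
    @pytest.fixture(scope="class")
    def sim(self, surfaces, landscape):
        _, grid, _, _ = landscape
        cfg = BroodSimConfig(seed=21, n_broods=6, monitor_days=32, day_step=4, slots_per_day=1)
        fixes, truth = simulate_broods(grid, surfaces, cfg)
        return grid, fixes, truth

    def test_schema_and_determinism(self, sim, surfaces, landscape):
        _, grid, _, _ = landscape
        _, fixes, _ = sim
        cfg = BroodSimConfig(seed=21, n_broods=6, monitor_days=32, day_step=4, slots_per_day=1)
        again, _ = simulate_broods(grid, surfaces, cfg)
        pd.testing.assert_frame_equal(fixes, again)

    def test_positive_selection_shifts_used_covariates(self, surfaces, landscape):
        _, grid, _, _ = landscape
        coeffs = {c: 0.0 for c in sd.DEFAULT_RSF3_TRUTH}
        coeffs["bu"] = 2.0
        cfg = BroodSimConfig(
            seed=31, n_broods=8, monitor_days=20, day_step=2, slots_per_day=1,
            coefficients=coeffs, slope_sd=0.0,
        )
        fixes, _ = simulate_broods(grid, surfaces, cfg)
        used_bu = extract_at_points(surfaces["bu"], fixes["x"].to_numpy(), fixes["y"].to_numpy())
        rng = np.random.default_rng(1)
        rx = rng.uniform(50, 1950, 2000)
        ry = rng.uniform(50, 1950, 2000)
        background_bu = extract_at_points(surfaces["bu"], rx, ry)
        assert used_bu.mean() > background_bu.mean() + 0.05

    def test_selection_strength_monotonicity(self, surfaces, landscape):
        _, grid, _, _ = landscape
        contrasts = []
        for scale in (1.0, 2.0):
            shifts = []
            for seed in range(41, 46):
                coeffs = {c: 0.0 for c in sd.DEFAULT_RSF3_TRUTH}
                coeffs["bu"] = scale
                cfg = BroodSimConfig(
                    seed=seed, n_broods=4, monitor_days=14, day_step=2,
                    slots_per_day=1, coefficients=coeffs, slope_sd=0.0,
                )
                fixes, _ = simulate_broods(grid, surfaces, cfg)
                bu = extract_at_points(
                    surfaces["bu"], fixes["x"].to_numpy(), fixes["y"].to_numpy()
                )
                shifts.append(bu.mean())
            contrasts.append(np.mean(shifts))
        assert contrasts[1] > contrasts[0]

    def test_roundtrip_through_design(self, sim, surfaces):
        from broodsel.choice_design import build_choice_records

        grid, fixes, _ = sim
        recs = build_choice_records(
            fixes, surfaces, rng=np.random.default_rng(3)
        )
        design, _ = build_design_rsf3(recs)
        assert len(design) == 6 * recs["locid"].nunique()

    def test_choice_set_generator(self, surfaces, landscape):
        _, grid, _, _ = landscape
        cfg = BroodSimConfig(seed=51, n_broods=4, monitor_days=12, day_step=2, slots_per_day=1)
        recs, truth = sd.simulate_choice_sets(grid, surfaces, cfg)
        assert (recs.groupby("locid")["used"].sum() == 1).all()
        assert (recs.groupby("locid").size() == 6).all()
        assert set(truth["coefficients"]) == set(sd.DEFAULT_RSF3_TRUTH)


class TestRoostPairs:
    @pytest.fixture(scope="class")
    def sim(self):
        cfg = RoostSimConfig(seed=61, n_pairs={"neonate": 400, "chick": 300, "juvenile": 300})
        return simulate_roost_pairs(cfg)

    def test_pair_separation_is_15m(self, sim):
        pairs, _, _ = sim
        x, y = pairs["x"].to_numpy(), pairs["y"].to_numpy()
        sep = np.hypot(x[::2] - x[1::2], y[::2] - y[1::2])
        np.testing.assert_allclose(sep, 15.0, atol=1e-9)

    def test_traces_follow_sensor_protocol(self, sim):
        _, traces, _ = sim
        counts = traces.groupby("site_id").size()
        assert (counts == 28).all()
        for _, grp in list(traces.groupby("site_id"))[:20]:
            validate_trace(grp["temp_c"].to_numpy())

    def test_woody_forb_correlation_near_target(self, sim):
        pairs, _, _ = sim
        r = np.corrcoef(pairs["woody"], pairs["forb"])[0, 1]
        assert r == pytest.approx(-0.72, abs=0.1)

    def test_composition_partitions(self, sim):
        pairs, _, _ = sim
        total = pairs["woody"] + pairs["grass"] + pairs["forb"] + pairs["bareness"]
        np.testing.assert_allclose(total, 100.0, atol=1e-9)

    def test_trace_means_in_observed_band(self, sim):
        pairs, _, _ = sim
        assert 19.5 <= pairs["temp_mean"].mean() <= 28.5

    def test_determinism(self):
        cfg = RoostSimConfig(seed=8, n_pairs={"neonate": 20, "chick": 20, "juvenile": 20})
        a, ta, _ = simulate_roost_pairs(cfg)
        b, tb, _ = simulate_roost_pairs(
            RoostSimConfig(seed=8, n_pairs={"neonate": 20, "chick": 20, "juvenile": 20})
        )
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_roundtrip_through_design(self, sim):
        pairs, _, _ = sim
        design, _ = build_design_rsf4(build_pair_table(pairs.head(40)))
        assert len(design) == 40

    def test_overflow_guard(self):
        bad = {k: tuple(50.0 for _ in v) for k, v in sd.DEFAULT_RSF4_TRUTH.items()}
        with pytest.raises(ValueError, match="overflow|magnitude"):
            RoostSimConfig(seed=1, coefficients=bad)


class TestGaussianChoiceSets:
    def test_structure_selection_and_determinism(self):
        cfg = BroodSimConfig(seed=13, n_broods=20, n_candidates=50)
        recs, truth = sd.simulate_gaussian_choice_sets(cfg)
        assert (recs.groupby("locid").size() == 6).all()
        assert (recs.groupby("locid")["used"].sum() == 1).all()
        # positive burned-upland truth: used draws sit above available ones
        used = recs[recs.used == 1]["bu"].mean()
        avail = recs[recs.used == 0]["bu"].mean()
        assert used > avail
        again, _ = sd.simulate_gaussian_choice_sets(cfg)
        pd.testing.assert_frame_equal(recs, again)


class TestTiltedRoostPairs:
    def test_contrast_matches_tilt(self):
        cfg = RoostSimConfig(seed=9, n_pairs={"neonate": 2000, "chick": 0, "juvenile": 0})
        recs, truth = simulate_tilted_roost_pairs(cfg)
        # orthogonal design: roost-minus-available mean contrast of each
        # covariate approximates its (season-averaged) generating slope
        woody_contrast = (
            recs[recs.role == "roost"]["woody"].mean()
            - recs[recs.role == "available"]["woody"].mean()
        )
        want = 2.04 - 1.17 * cfg.late_season_frac
        assert woody_contrast == pytest.approx(want, abs=0.15)

    def test_structure_and_determinism(self):
        cfg = RoostSimConfig(seed=10, n_pairs={"neonate": 30, "chick": 30, "juvenile": 30})
        a, _ = simulate_tilted_roost_pairs(cfg)
        b, _ = simulate_tilted_roost_pairs(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert (a.groupby("pair_id").size() == 2).all()
        design, _ = build_design_rsf4(build_pair_table(a), standardize_covariates=False)
        assert len(design) == len(a)
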