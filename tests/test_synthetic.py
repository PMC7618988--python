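"""Synthetic-data generators: tiling, determinism, calibration contracts."""

import numpy as np
import pandas as pd
import pytest
from shapely.ops import unary_union

from aqburden import (
    GridSpec,
    SyntheticScenario,
    assign_countries,
    generate_grid,
    generate_mortality_rates,
    generate_population,
    generate_small_areas,
    simulate_exposure,
)
from aqburden.synthetic import age_band_midpoint, DEFAULT_AGE_BANDS


class TestGrid:
    @pytest.mark.parametrize(
        "n_cols,n_rows", [(2, 2), (1, 1), (10, 7)]
    )
    def test_tiles_extent_exactly(self, n_cols, n_rows):
        spec = GridSpec(n_cols, n_rows, cell_size=1000.0)
        grid = generate_grid(spec)
        assert len(grid) == n_cols * n_rows
        areas = np.array([g.area for g in grid["geometry"]])
        assert np.allclose(areas, 1_000_000.0)
        union = unary_union(grid["geometry"].tolist())
        # no gaps, no overlaps: union area equals the sum of cell areas
        assert union.area == pytest.approx(areas.sum(), rel=1e-12)
        assert union.area == pytest.approx(n_cols * n_rows * 1e6, rel=1e-12)

    def test_single_cell_is_the_extent(self):
        grid = generate_grid(GridSpec(1, 1, cell_size=500.0, origin=(10.0, 20.0)))
        assert grid.loc[0, "geometry"].bounds == (10.0, 20.0, 510.0, 520.0)

    @pytest.mark.parametrize("bad", [dict(n_cols=0, n_rows=3),
                                     dict(n_cols=3, n_rows=-1),
                                     dict(n_cols=2, n_rows=2, cell_size=0.0)])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            GridSpec(**bad)


class TestExposureField:
    def test_same_seed_bitwise_identical(self):
        grid = generate_grid(GridSpec(8, 8))
        sc = SyntheticScenario(years=(2008, 2010), seed=3)
        a = simulate_exposure(grid, sc)
        b = simulate_exposure(grid, sc)
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_degenerate_single_cell_equals_year_mean(self):
        grid = generate_grid(GridSpec(1, 1))
        sc = SyntheticScenario(
            years=(2008, 2018), n_hotspots=0, seed=5,
            country_offsets={"PM25": {}, "NO2": {}},
        )
        out = simulate_exposure(grid, sc)
        for _, row in out.iterrows():
            assert row["value"] == pytest.approx(
                sc.target_mean(row["pollutant"], row["year"]), abs=1e-12
            )

    def test_unknown_pollutant_rejected(self):
        with pytest.raises(ValueError, match="unknown pollutant"):
            SyntheticScenario(trends={"O3": (50.0, 40.0)})

    def test_concentrations_nonnegative(self):
        grid = generate_grid(GridSpec(15, 15))
        sc = SyntheticScenario(years=(2008, 2012), seed=9)
        out = simulate_exposure(grid, sc)
        assert (out["value"] >= 0).all()

    def test_trend_slope_matches_scenario(self):
        """OLS slope of yearly spatial means ~ (end-start)/(n_years-1),
        judged against the between-seed sampling spread at 20 seeds."""
        grid = generate_grid(GridSpec(20, 20))
        years = np.arange(2008, 2019)
        slopes = []
        for seed in range(20):
            sc = SyntheticScenario(seed=seed)
            out = simulate_exposure(grid, sc)
            pm = out[out["pollutant"] == "PM25"]
            means = pm.groupby("year")["value"].mean().loc[years]
            slopes.append(np.polyfit(years, means.to_numpy(), 1)[0])
        slopes = np.asarray(slopes)
        expected = (9.4 - 10.5) / 10.0
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - expected) <= 3.0 * se + 1e-3


class TestSmallAreas:
    def test_partition_every_cell_exactly_once(self):
        grid = generate_grid(GridSpec(10, 10))
        _, assignment = generate_small_areas(grid, 10, seed=2)
        counts = assignment["cell_id"].value_counts()
        assert len(counts) == len(grid)
        assert (counts == 1).all()
        assert assignment["area_id"].nunique() == 10

    def test_identity_partition(self):
        grid = generate_grid(GridSpec(6, 5))
        areas, assignment = generate_small_areas(grid, len(grid), seed=0)
        assert (areas["n_cells"] == 1).all()
        assert assignment["area_id"].nunique() == len(grid)

    def test_single_area_covers_extent(self):
        grid = generate_grid(GridSpec(4, 4))
        areas, _ = generate_small_areas(grid, 1, seed=0)
        assert areas.loc[0, "geometry"].area == pytest.approx(16e6)

    def test_areas_are_contiguous(self):
        grid = generate_grid(GridSpec(12, 12))
        sc = SyntheticScenario(seed=4)
        areas, _ = generate_small_areas(
            grid, 20, seed=4, countries=assign_countries(grid, sc)
        )
        # a contiguous union of cells is a single polygon
        assert all(g.geom_type == "Polygon" for g in areas["geometry"])

    def test_region_implies_country(self):
        grid = generate_grid(GridSpec(20, 30))
        sc = SyntheticScenario(seed=1)
        areas, _ = generate_small_areas(
            grid, 60, seed=1, countries=assign_countries(grid, sc)
        )
        for _, row in areas.iterrows():
            assert row["region"].startswith(row["country"].split("_")[0])
        assert set(areas["country"]) == {"England", "Scotland", "Wales"}

    def test_too_many_areas_rejected(self):
        grid = generate_grid(GridSpec(3, 3))
        with pytest.raises(ValueError):
            generate_small_areas(grid, 10, seed=0)


class TestPopulation:
    def test_zero_dispersion_splits_mean_by_shares(self):
        areas = pd.DataFrame({"area_id": ["A"], "country": ["England"]})
        pop = generate_population(areas, seed=0, dispersion=0.0)
        assert pop["population"].sum() == 1600
        assert set(pop["age_band"]) == set(DEFAULT_AGE_BANDS)

    def test_band_counts_conserve_area_totals(self):
        areas = pd.DataFrame(
            {"area_id": [f"A{i}" for i in range(50)], "country": ["Scotland"] * 50}
        )
        pop = generate_population(areas, seed=3)
        # largest-remainder rounding conserves the drawn total exactly,
        # well within the +/- n_bands slack of simple rounding
        totals = pop.groupby("area_id")["population"].sum()
        assert (totals > 0).all()
        assert (pop["population"] >= 0).all()

    def test_sample_mean_near_country_mean(self):
        areas = pd.DataFrame(
            {"area_id": [f"A{i}" for i in range(1000)],
             "country": ["England"] * 1000}
        )
        pop = generate_population(areas, seed=1, dispersion=0.2)
        totals = pop.groupby("area_id")["population"].sum().to_numpy()
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - 1600.0) <= 3.0 * se

    def test_empty_bands_rejected(self):
        areas = pd.DataFrame({"area_id": ["A"], "country": ["England"]})
        with pytest.raises(ValueError):
            generate_population(areas, age_bands=[])


class TestMortality:
    def test_gompertz_closed_form(self):
        rates = generate_mortality_rates(
            ["R"], ["0-4", "90+"], base_rate=1e-5, slope=0.1, region_sd=0.0
        )
        r = rates.set_index("age_band")["rate"]
        assert r["0-4"] == pytest.approx(1e-5 * np.exp(0.25), rel=1e-12)
        assert r["90+"] == pytest.approx(1e-5 * np.exp(9.25), rel=1e-12)

    def test_flat_and_zero_profiles(self):
        flat = generate_mortality_rates(["R"], slope=0.0, region_sd=0.0,
                                        base_rate=2e-3)
        assert np.allclose(flat["rate"], 2e-3)
        zero = generate_mortality_rates(["R"], base_rate=0.0, region_sd=0.0)
        assert (zero["rate"] == 0).all()

    def test_rates_nondecreasing_in_age(self):
        rates = generate_mortality_rates(["R1", "R2", "R3"], seed=5)
        for _, g in rates.groupby("region"):
            mids = g["age_band"].map(age_band_midpoint)
            ordered = g.assign(mid=mids).sort_values("mid")["rate"].to_numpy()
            assert (np.diff(ordered) >= 0).all()

    def test_rates_bounded_and_capped(self):
        rates = generate_mortality_rates(["R"], base_rate=0.5, slope=0.2, seed=0)
        assert ((rates["rate"] >= 0) & (rates["rate"] <= 1)).all()
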