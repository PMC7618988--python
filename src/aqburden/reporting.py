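"""Aggregation, report tables and the end-to-end pipeline.

Builds the two report shapes of a limit-value health-impact assessment:
a descriptive exposure table (population-weighted means, concentration-
band shares, compliance percentages) and a burden table (attributable
deaths with 95% eCIs and standardised excess rates per group, year,
pollutant and cut-off), plus scenario-comparison percentages.

Display rounding is applied only in dedicated display columns: deaths to
the nearest integer, percentages to one decimal, means to one decimal.
Unrounded group centrals are exactly additive across any partition of
areas; rounded ones can differ from the sum of rounded parts by at most
(number of parts - 1).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .burden import RiskEstimate, rr_to_beta, scenario_burden, DEFAULT_RISKS
from .exposure import assign_exposure, compute_overlap_weights, write_areas_geojson
from .summary import DEFAULT_BAND_CUTS, summary_table
from .uncertainty import (
    UncertaintyConfig,
    european_standard_weights,
    propagate,
    standardized_excess_rate,
    validate_standard_weights,
)

__version__ = "0.1.0"


def aggregate(
    burden: pd.DataFrame, areas: pd.DataFrame | None = None, level: str = "gb"
) -> pd.DataFrame:
    """Exact sums of unrounded per-cell deaths within groups.

    ``level`` is ``"gb"`` (single national group) or a column of the area
    table (``country``, ``region``, ``urban_rural``).
    """
    df = burden
    if level == "gb":
        df = df.assign(group="GB")
    else:
        if areas is None or level not in areas.columns:
            raise ValueError(f"unknown aggregation level {level!r}")
        df = df.merge(
            areas[["area_id", level]].rename(columns={level: "group"}),
            on="area_id",
            how="left",
        )
        if df["group"].isna().any():
            bad = df.loc[df["group"].isna(), "area_id"].unique()
            raise ValueError(f"areas without {level!r} label: {sorted(bad)[:10]}")
    out = df.groupby(
        ["group", "year", "pollutant", "cutoff"], as_index=False, sort=True
    )["deaths"].sum()
    out.insert(0, "level", level)
    return out


def reduction_percent(total_at_c: float, overall_total: float) -> float:
    """Share (%) of the overall burden avoidable by meeting cut-off c."""
    if overall_total <= 0:
        raise ValueError("overall burden must be positive")
    return 100.0 * total_at_c / overall_total


def round_deaths(v) -> int:
    return int(np.round(v))


def standardized_rates(
    burden: pd.DataFrame,
    pop: pd.DataFrame,
    areas: pd.DataFrame | None = None,
    level: str = "gb",
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Directly standardised excess rate per 100,000 by group/year/cut-off."""
    if weights is None:
        weights = european_standard_weights(sorted(pop["age_band"].unique(),
                                                   key=synthetic.age_band_midpoint))
    if level == "gb":
        bdf = burden.assign(group="GB")
        pdf = pop.assign(group="GB")
    else:
        if areas is None or level not in areas.columns:
            raise ValueError(f"unknown aggregation level {level!r}")
        lab = areas[["area_id", level]].rename(columns={level: "group"})
        bdf = burden.merge(lab, on="area_id", how="left")
        pdf = pop.merge(lab, on="area_id", how="left")
    d = bdf.groupby(
        ["group", "year", "pollutant", "cutoff", "age_band"], sort=True
    )["deaths"].sum()
    p = pdf.groupby(["group", "age_band"], sort=True)["population"].sum()
    rows = []
    for (g, y, pol, c), d_age in d.groupby(level=[0, 1, 2, 3]):
        d_age = d_age.droplevel([0, 1, 2, 3])
        rate = standardized_excess_rate(d_age, p.loc[g], weights)
        rows.append((level, g, y, pol, c, rate))
    return pd.DataFrame(
        rows, columns=["level", "group", "year", "pollutant", "cutoff",
                       "std_rate_per_100k"]
    )


def render_report(
    summary: pd.DataFrame | None,
    report: pd.DataFrame | None,
    out_dir,
) -> list[Path]:
    """Write deterministic CSV reports with display-rounded columns."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if summary is not None:
        s = summary.copy()
        for col in s.columns:
            if col.startswith("pct_") :
                s[col] = s[col].round(1)
            elif col == "mean":
                s[col] = s[col].round(1)
        path = out_dir / "exposure_summary.csv"
        s.to_csv(path, index=False)
        written.append(path)
    if report is not None:
        r = report.copy()
        for col in ("central", "low", "high"):
            if col in r:
                r[f"{col}_disp"] = r[col].map(round_deaths)
        if "std_rate_per_100k" in r:
            r["std_rate_disp"] = r["std_rate_per_100k"].round(1)
        r = r.sort_values(
            ["pollutant", "cutoff", "level", "group", "year"], ignore_index=True
        )
        path = out_dir / "burden_report.csv"
        r.to_csv(path, index=False)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Default GB-like scaled-down study configuration.

    A 40 x 72 km grid of 1 km cells partitioned into 300 small areas
    stands in for the national geography at roughly 1/140 of its
    population; all rates, trends and risk estimates keep their
    full-scale values, so burdens scale with population only.
    """
    return {
        "grid": {"n_cols": 40, "n_rows": 72, "cell_size": 1000.0},
        "scenario": {},  # SyntheticScenario defaults
        "areas": {
            "n_areas": 300,
            # area counts follow the census-unit split, not land shares
            "country_shares": {"England": 0.787, "Scotland": 0.167, "Wales": 0.046},
            "urban_radius": 5000.0,
        },
        "population": {"dispersion": 0.2},
        "mortality": {"base_rate": 2.6e-5, "slope": 0.095, "region_sd": 0.05},
        "risks": DEFAULT_RISKS,
        "cutoffs": {"PM25": [0, 5, 10, 15, 20], "NO2": [0, 10, 20, 30, 40]},
        "bands": {k: list(v) for k, v in DEFAULT_BAND_CUTS.items()},
        "uncertainty": {"n_draws": 1000, "level": 0.95, "method": "linear"},
        "levels": ["gb", "country"],
        "seed": 0,
    }


def _merge_config(base: dict, override: Mapping | None) -> dict:
    if not override:
        return base
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge_config(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(
    config: Mapping | None = None,
    out_dir=None,
    seed: int | None = None,
) -> dict:
    """simulate -> map -> summarize -> burden (+eCI) -> report.

    Returns all intermediate tables; when ``out_dir`` is given, also
    writes CSV/GeoJSON outputs and a manifest (config hash, seed,
    versions). Fully deterministic given config and seed.
    """
    cfg = _merge_config(default_config(), config)
    if seed is not None:
        cfg["seed"] = int(seed)
    root = int(cfg["seed"])

    spec = synthetic.GridSpec(**cfg["grid"])
    grid = synthetic.generate_grid(spec)
    scenario = synthetic.SyntheticScenario(**cfg["scenario"], seed=root)
    exposure = synthetic.simulate_exposure(grid, scenario)
    countries = synthetic.assign_countries(grid, scenario)
    hotspots = synthetic.hotspot_centres(grid, scenario)
    areas, assignment = synthetic.generate_small_areas(
        grid,
        cfg["areas"]["n_areas"],
        cfg["areas"].get("country_shares"),
        seed=root,
        countries=countries,
        hotspot_xy=hotspots,
        urban_radius=cfg["areas"].get("urban_radius", 5000.0),
    )
    weights = compute_overlap_weights(areas, grid)
    x = assign_exposure(weights, exposure)

    age_bands = cfg["population"].get("age_bands") or list(synthetic.DEFAULT_AGE_BANDS)
    pop = synthetic.generate_population(
        areas,
        age_bands,
        cfg["population"].get("mean_size_by_country"),
        seed=root,
        dispersion=cfg["population"].get("dispersion", 0.2),
    )
    rates = synthetic.generate_mortality_rates(
        sorted(areas["region"].unique()), age_bands, seed=root, **cfg["mortality"]
    )

    summaries = []
    for by in ([], ["country"]):
        s = summary_table(
            x, pop, areas, by=by,
            band_cuts={k: tuple(v) for k, v in cfg["bands"].items()},
            limits={k: [c for c in v if c > 0] for k, v in cfg["cutoffs"].items()},
        )
        if not by:
            s.insert(0, "group", "GB")
        else:
            s = s.rename(columns={"country": "group"})
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)

    ucfg = UncertaintyConfig(seed=root, **cfg["uncertainty"])
    std_weights = european_standard_weights(age_bands)
    validate_standard_weights(std_weights)
    burden_frames, report_frames = [], []
    for pol, risk in cfg["risks"].items():
        coef = rr_to_beta(RiskEstimate(pol, **risk))
        cutoffs = cfg["cutoffs"][pol]
        b = scenario_burden(x, pop, rates, areas, coef, cutoffs)
        burden_frames.append(b)
        rep = propagate(
            x, pop, rates, areas, coef, cutoffs, ucfg, levels=cfg["levels"]
        )
        srates = pd.concat(
            [
                standardized_rates(b, pop, areas, level, std_weights)
                for level in cfg["levels"]
            ],
            ignore_index=True,
        )
        rep = rep.merge(
            srates, on=["level", "group", "year", "pollutant", "cutoff"], how="left"
        )
        report_frames.append(rep)
    burden = pd.concat(burden_frames, ignore_index=True)
    report = pd.concat(report_frames, ignore_index=True)

    # avoidable share of the overall burden at each cut-off
    overall = report[report["cutoff"] == 0].set_index(
        ["level", "group", "year", "pollutant"]
    )["central"]
    key = report.set_index(["level", "group", "year", "pollutant"]).index
    report = report.assign(
        reduction_pct=100.0 * report["central"].to_numpy()
        / overall.reindex(key).to_numpy()
    )

    result = {
        "config": cfg,
        "grid": grid,
        "exposure": exposure,
        "areas": areas,
        "assignment": assignment,
        "weights": weights,
        "area_exposure": x,
        "population": pop,
        "rates": rates,
        "summary": summary,
        "burden": burden,
        "report": report,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        exposure.to_csv(out_dir / "exposure_grid.csv", index=False)
        write_areas_geojson(areas, out_dir / "areas.geojson")
        weights.to_csv(out_dir / "overlap_weights.csv", index=False)
        x.to_csv(out_dir / "area_exposure.csv", index=False)
        pop.to_csv(out_dir / "population.csv", index=False)
        rates.to_csv(out_dir / "mortality_rates.csv", index=False)
        burden.to_csv(out_dir / "burden_cells.csv", index=False)
        render_report(summary, report, out_dir)
        cfg_json = json.dumps(cfg, sort_keys=True, default=float)
        manifest = {
            "config": cfg,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": root,
            "versions": {
                "aqburden": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "outputs": sorted(p.name for p in out_dir.iterdir()),
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        result["out_dir"] = out_dir
    return result
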