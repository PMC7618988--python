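"""Grid-to-small-area exposure assignment.

Concentrations on the regular grid are merged onto small-area polygons by
area-weighted interpolation: each area receives the overlap-area-weighted
average of the cells it intersects. Weights are renormalised over the
covered fraction, so areas only partially covered by the grid (coastline-
like cases) are not biased low. Sub-annual series can be aggregated to
annual means with a minimum-coverage rule before assignment.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree


def compute_overlap_weights(areas: pd.DataFrame, grid: pd.DataFrame) -> pd.DataFrame:
    """Area-weighted interpolation weights from polygon overlap.

    For each area, weight(area, cell) = intersection area / total
    intersected area of that area. Weights therefore sum to one per area
    even when the grid covers the area only partially. Areas with zero
    grid coverage raise, listing the offending ids.

    Parameters
    ----------
    areas : DataFrame with ``area_id`` and shapely ``geometry`` columns.
    grid : cell table from :func:`~aqburden.synthetic.generate_grid`.
    """
    cell_geoms = grid["geometry"].tolist()
    cell_ids = grid["cell_id"].to_numpy()
    tree = STRtree(cell_geoms)
    rows: list[tuple[str, int, float]] = []
    uncovered: list[str] = []
    for area_id, geom in zip(areas["area_id"], areas["geometry"]):
        if geom is None or geom.is_empty or geom.area <= 0:
            uncovered.append(str(area_id))
            continue
        idx = tree.query(geom)
        inter = np.array(
            [geom.intersection(cell_geoms[i]).area for i in idx], dtype=float
        )
        keep = inter > 0
        total = inter[keep].sum()
        if total <= 0:
            uncovered.append(str(area_id))
            continue
        for i, a in zip(np.asarray(idx)[keep], inter[keep]):
            rows.append((area_id, int(cell_ids[i]), a / total))
    if uncovered:
        raise ValueError(
            "areas with no grid coverage: " + ", ".join(sorted(uncovered))
        )
    out = pd.DataFrame(rows, columns=["area_id", "cell_id", "weight"])
    return out.sort_values(["area_id", "cell_id"], ignore_index=True)


def weights_from_cell_assignment(assignment: pd.DataFrame) -> pd.DataFrame:
    """Exact weights when areas are unions of whole (equal-size) cells."""
    counts = assignment.groupby("area_id")["cell_id"].transform("size")
    out = assignment.copy()
    out["weight"] = 1.0 / counts
    return out[["area_id", "cell_id", "weight"]].sort_values(
        ["area_id", "cell_id"], ignore_index=True
    )


def assign_exposure(weights: pd.DataFrame, exposure: pd.DataFrame) -> pd.DataFrame:
    """Area annual concentrations x_iy = sum of weight * cell value.

    Every cell referenced by the weights must carry a (non-missing) value
    for every year/pollutant present; a missing cell is a hard error, not
    silently imputed. The result is bounded by the min/max of each area's
    contributing cells.
    """
    if (weights["weight"] < 0).any():
        raise ValueError("weights must be nonnegative")
    exp = exposure.copy()
    if exp["value"].isna().any():
        bad = exp.loc[exp["value"].isna(), "cell_id"].unique()
        raise ValueError(f"missing exposure values for cells: {sorted(bad)[:10]}")
    merged = weights.merge(exp, on="cell_id", how="left")
    if merged["value"].isna().any():
        bad = merged.loc[merged["value"].isna(), "cell_id"].unique()
        raise ValueError(
            f"cells referenced by weights absent from exposure: {sorted(bad)[:10]}"
        )
    merged["wv"] = merged["weight"] * merged["value"]
    out = (
        merged.groupby(["area_id", "year", "pollutant"], as_index=False, sort=True)
        .agg(value=("wv", "sum"), wsum=("weight", "sum"))
    )
    out["value"] = out["value"] / out["wsum"]
    return out.drop(columns="wsum")


def annualize(
    daily: pd.DataFrame, coverage_threshold: float = 0.75
) -> pd.DataFrame:
    """Annual cell means from a dated sub-annual series.

    Returns one row per (cell_id, year, pollutant) with the arithmetic
    mean of available values and the coverage fraction (days present /
    days in the year). Years below ``coverage_threshold`` are flagged
    missing (NaN value) so that downstream use fails loudly.
    """
    df = daily.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year
    days_in_year = np.where(dates.dt.is_leap_year, 366, 365)
    df["_diy"] = days_in_year
    out = (
        df.groupby(["cell_id", "year", "pollutant"], as_index=False, sort=True)
        .agg(value=("value", "mean"), n=("value", "size"), diy=("_diy", "first"))
    )
    out["coverage"] = out["n"] / out["diy"]
    out.loc[out["coverage"] < coverage_threshold, "value"] = np.nan
    return out[["cell_id", "year", "pollutant", "value", "coverage"]]


def write_grid_csv(grid: pd.DataFrame, path) -> None:
    """Persist the cell table (ids, indices, centroids, cell size)."""
    out = grid[["cell_id", "col", "row", "cx", "cy"]].copy()
    out["cell_size"] = grid.attrs.get("cell_size", 1000.0)
    out.to_csv(path, index=False)


def read_grid_csv(path) -> pd.DataFrame:
    """Rebuild a cell table (with square polygons) written by write_grid_csv."""
    from shapely.geometry import box

    df = pd.read_csv(path)
    s = float(df["cell_size"].iloc[0])
    df["geometry"] = [
        box(cx - s / 2, cy - s / 2, cx + s / 2, cy + s / 2)
        for cx, cy in zip(df["cx"], df["cy"])
    ]
    df.attrs["cell_size"] = s
    return df.drop(columns="cell_size")


# ---------------------------------------------------------------------------
# GeoJSON I/O (plain-JSON FeatureCollections; planar coordinates)
# ---------------------------------------------------------------------------

def write_areas_geojson(areas: pd.DataFrame, path) -> None:
    props: Iterable[str] = [
        c for c in ("area_id", "country", "region", "urban_rural") if c in areas
    ]
    features = []
    for _, row in areas.iterrows():
        features.append(
            {
                "type": "Feature",
                "properties": {k: row[k] for k in props},
                "geometry": mapping(row["geometry"]),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_areas_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        fc = json.load(fh)
    rows = []
    for feat in fc["features"]:
        rec = dict(feat.get("properties", {}))
        rec["geometry"] = shape(feat["geometry"])
        rows.append(rec)
    return pd.DataFrame(rows)
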