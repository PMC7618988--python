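"""Descriptive exposure statistics by population.

Population-weighted mean concentrations, the percentage of the population
in concentration bands, and compliance shares against annual-mean limit
values, for any grouping of small areas (whole domain, country, region,
urban/rural class).

Band convention: with cut points c1 < c2 < ... the bands are [0, c1],
(c1, c2], ..., (ck, inf); a value exactly at a cut point belongs to the
lower band. "Below the limit" means x <= limit (non-exceedance of an
annual-mean limit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Default band cut points (ug/m3) per pollutant.
DEFAULT_BAND_CUTS = {"PM25": (5.0, 10.0, 15.0, 20.0), "NO2": (10.0, 20.0, 30.0, 40.0)}


@dataclass(frozen=True)
class BandScheme:
    """Ordered concentration cut points partitioning [0, inf)."""

    cuts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cuts) == 0:
            raise ValueError("at least one cut point required")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut points must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        lab = [f"<={self.cuts[0]:g}"]
        lab += [f"{a:g}-{b:g}" for a, b in zip(self.cuts, self.cuts[1:])]
        lab.append(f">{self.cuts[-1]:g}")
        return lab

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Band index per value; ties at cut points go to the lower band."""
        return np.searchsorted(np.asarray(self.cuts), np.asarray(x), side="left")


def area_totals(pop: pd.DataFrame) -> pd.Series:
    """All-ages population per area."""
    return pop.groupby("area_id")["population"].sum()


def _with_groups(
    x: pd.DataFrame, areas: pd.DataFrame | None, by: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    df = x.copy()
    by = list(by)
    if by:
        if areas is None:
            raise ValueError("grouping requires the area table")
        df = df.merge(areas[["area_id", *by]], on="area_id", how="left")
        missing = df[by].isna().any(axis=1)
        if missing.any():
            bad = df.loc[missing, "area_id"].unique()
            raise ValueError(f"areas without grouping labels: {sorted(bad)[:10]}")
    return df, by


def population_weighted_mean(
    x: pd.DataFrame,
    pop: pd.DataFrame,
    areas: pd.DataFrame | None = None,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """sum_i P_i x_iy / sum_i P_i per group, year and pollutant."""
    df, by = _with_groups(x, areas, by)
    totals = area_totals(pop)
    df["P"] = df["area_id"].map(totals)
    if df["P"].isna().any():
        bad = df.loc[df["P"].isna(), "area_id"].unique()
        raise ValueError(f"areas without population: {sorted(bad)[:10]}")
    df["Px"] = df["P"] * df["value"]
    g = df.groupby([*by, "year", "pollutant"], as_index=False, sort=True).agg(
        Px=("Px", "sum"), P=("P", "sum")
    )
    if (g["P"] <= 0).any():
        raise ValueError("zero total population in a group; mean undefined")
    g["mean"] = g["Px"] / g["P"]
    return g.drop(columns=["Px", "P"])


def band_shares(
    x: pd.DataFrame,
    pop: pd.DataFrame,
    scheme: BandScheme,
    areas: pd.DataFrame | None = None,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """% of group population living at concentrations in each band."""
    df, by = _with_groups(x, areas, by)
    totals = area_totals(pop)
    df["P"] = df["area_id"].map(totals)
    df["band"] = df["value"].pipe(lambda v: scheme.assign(v.to_numpy()))
    labels = scheme.labels
    g = (
        df.groupby([*by, "year", "pollutant", "band"], sort=True)["P"]
        .sum()
        .reset_index()
    )
    tot = g.groupby([*by, "year", "pollutant"], sort=True)["P"].transform("sum")
    g["share_pct"] = 100.0 * g["P"] / tot
    g["band"] = g["band"].map(lambda i: labels[i])
    # complete the band set with explicit zeros
    keys = g[[*by, "year", "pollutant"]].drop_duplicates()
    full = keys.merge(pd.DataFrame({"band": labels}), how="cross")
    out = full.merge(g.drop(columns="P"), on=[*by, "year", "pollutant", "band"], how="left")
    out["share_pct"] = out["share_pct"].fillna(0.0)
    return out


def compliance_share(
    x: pd.DataFrame,
    pop: pd.DataFrame,
    limit: float,
    areas: pd.DataFrame | None = None,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Population % and area count/% at or below an annual-mean limit."""
    if limit < 0:
        raise ValueError("limit must be nonnegative")
    df, by = _with_groups(x, areas, by)
    totals = area_totals(pop)
    df["P"] = df["area_id"].map(totals)
    df["below"] = df["value"] <= limit
    df["Pb"] = df["P"] * df["below"]
    g = df.groupby([*by, "year", "pollutant"], as_index=False, sort=True).agg(
        P=("P", "sum"),
        Pb=("Pb", "sum"),
        n_areas=("area_id", "size"),
        n_areas_below=("below", "sum"),
    )
    g["pop_below_pct"] = 100.0 * g["Pb"] / g["P"]
    g["areas_below_pct"] = 100.0 * g["n_areas_below"] / g["n_areas"]
    return g[
        [*by, "year", "pollutant", "pop_below_pct", "areas_below_pct",
         "n_areas_below", "n_areas"]
    ]


def summary_table(
    x: pd.DataFrame,
    pop: pd.DataFrame,
    areas: pd.DataFrame | None = None,
    by: Sequence[str] = (),
    band_cuts: Mapping[str, Sequence[float]] = DEFAULT_BAND_CUTS,
    limits: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """One row per group x year x pollutant: population-weighted mean,
    band shares and compliance percentages (wide, report-ready)."""
    means = population_weighted_mean(x, pop, areas, by)
    pieces = [means.set_index([*by, "year", "pollutant"])]
    for pol, cuts in band_cuts.items():
        scheme = BandScheme(tuple(float(c) for c in cuts))
        bs = band_shares(
            x[x["pollutant"] == pol], pop, scheme, areas, by
        )
        wide = bs.pivot_table(
            index=[*by, "year", "pollutant"],
            columns="band",
            values="share_pct",
            sort=False,
        )
        wide.columns = [f"pct_pop_{c}" for c in wide.columns]
        pieces.append(wide)
    if limits:
        for pol, lims in limits.items():
            for lim in lims:
                cs = compliance_share(
                    x[x["pollutant"] == pol], pop, float(lim), areas, by
                ).set_index([*by, "year", "pollutant"])
                pieces.append(
                    cs[["pop_below_pct", "areas_below_pct"]].rename(
                        columns={
                            "pop_below_pct": f"pct_pop_below_{lim:g}",
                            "areas_below_pct": f"pct_areas_below_{lim:g}",
                        }
                    )
                )
    out = pd.concat(pieces, axis=1).reset_index()
    return out.sort_values([*by, "pollutant", "year"], ignore_index=True)
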