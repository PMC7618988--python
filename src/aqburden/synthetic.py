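"""Seeded synthetic inputs emulating a Great-Britain-like study region.

Everything downstream of the exposure model is testable without any real
data: this module builds a regular metric grid, spatially autocorrelated
annual concentration fields with a declining trend and urban hotspots,
contiguous small areas (census-unit-like groupings of grid cells),
age-stratified populations, and region-by-age mortality rates.

All generators are pure functions of their parameters and a seed; every
random draw flows from a single root seed through named substreams, so any
single component can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import zlib
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box
from shapely.ops import unary_union

POLLUTANTS = ("PM25", "NO2")

COUNTRIES = ("England", "Scotland", "Wales")

#: Nineteen five-year bands, 0-4 ... 90+ (open-ended last band).
DEFAULT_AGE_BANDS: tuple[str, ...] = tuple(
    [f"{a}-{a + 4}" for a in range(0, 90, 5)] + ["90+"]
)

#: Approximate GB age composition (2011-census-like shares, normalised at use).
AGE_SHARES: dict[str, float] = {
    "0-4": 6.2, "5-9": 5.6, "10-14": 5.8, "15-19": 6.3, "20-24": 6.8,
    "25-29": 6.9, "30-34": 6.6, "35-39": 6.7, "40-44": 7.3, "45-49": 7.3,
    "50-54": 6.4, "55-59": 5.7, "60-64": 6.0, "65-69": 4.8, "70-74": 3.9,
    "75-79": 3.1, "80-84": 2.4, "85-89": 1.5, "90+": 0.7,
}


def age_band_lower(band: str) -> float:
    """Lower age bound of a band label like ``"35-39"`` or ``"90+"``."""
    return float(band[:-1]) if band.endswith("+") else float(band.split("-")[0])


def age_band_midpoint(band: str) -> float:
    """Midpoint in years of a band label like ``"35-39"`` or ``"90+"``."""
    if band.endswith("+"):
        return float(band[:-1]) + 2.5
    lo, hi = band.split("-")
    return (float(lo) + float(hi) + 1.0) / 2.0


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A regular planar grid of square cells (projected metres).

    Cells tile the rectangle ``[x0, x0 + n_cols*cell_size] x
    [y0, y0 + n_rows*cell_size]`` without gaps or overlaps; cell ids run
    row-major from the origin corner.
    """

    n_cols: int
    n_rows: int
    cell_size: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows


def generate_grid(spec: GridSpec) -> pd.DataFrame:
    """Cell table with ids, centroids and square polygons tiling the extent."""
    x0, y0 = spec.origin
    s = spec.cell_size
    cols, rows = np.meshgrid(np.arange(spec.n_cols), np.arange(spec.n_rows))
    cols, rows = cols.ravel(), rows.ravel()
    cx = x0 + (cols + 0.5) * s
    cy = y0 + (rows + 0.5) * s
    geoms = [
        box(x0 + c * s, y0 + r * s, x0 + (c + 1) * s, y0 + (r + 1) * s)
        for c, r in zip(cols, rows)
    ]
    grid = pd.DataFrame(
        {
            "cell_id": rows * spec.n_cols + cols,
            "col": cols,
            "row": rows,
            "cx": cx,
            "cy": cy,
            "geometry": geoms,
        }
    )
    grid.attrs.update(
        n_cols=spec.n_cols, n_rows=spec.n_rows, cell_size=s, origin=spec.origin
    )
    return grid


def _grid_shape(grid: pd.DataFrame) -> tuple[int, int]:
    return int(grid["row"].max()) + 1, int(grid["col"].max()) + 1


# ---------------------------------------------------------------------------
# Scenario and concentration fields
# ---------------------------------------------------------------------------

@dataclass
class SyntheticScenario:
    """Parameters of the GB-like exposure scenario.

    The defaults emulate the study conditions: annual means over 2008-2018
    declining from 10.5 to 9.4 ug/m3 (PM2.5) and 23.1 to 18.7 ug/m3 (NO2),
    population-weighted; an England/Scotland/Wales contrast; and urban
    hotspots that load NO2 roughly twice as strongly as PM2.5.

    Fields are calibrated so that the country-population-share-weighted
    spatial mean follows the target trajectory (the anchors being
    population-weighted statistics), then clamped at zero.
    """

    years: tuple[int, int] = (2008, 2018)
    trends: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"PM25": (10.5, 9.4), "NO2": (23.1, 18.7)}
    )
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"PM25": 1.3, "NO2": 3.5}
    )
    #: Between-country mean offsets (ug/m3), chosen to reproduce the
    #: England-high / Scotland-low / Wales-intermediate contrast while
    #: keeping the population-share-weighted offset at zero.
    country_offsets: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "PM25": {"England": 0.42, "Scotland": -3.18, "Wales": -1.68},
            "NO2": {"England": 1.02, "Scotland": -5.38, "Wales": -8.28},
        }
    )
    correlation_length: float = 10_000.0  # metres
    year_noise_frac: float = 0.3  # sd of the year-specific field, as a
    # fraction of noise_sd; the persistent field carries the rest
    n_hotspots: int = 6
    hotspot_amplitude: float = 18.0  # ug/m3 peak for NO2; PM2.5 gets half
    hotspot_sigma: float = 2500.0  # metres
    # Country partition of the grid (fractions of rows/cols): Scotland is
    # the northern block, Wales a western mid-latitude block.
    scotland_row_frac: float = 0.66
    wales_col_frac: float = 0.25
    wales_row_range: tuple[float, float] = (0.25, 0.55)
    country_pop_shares: Mapping[str, float] = field(
        default_factory=lambda: {"England": 0.864, "Scotland": 0.086, "Wales": 0.050}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError("years must be an inclusive (first, last) range")
        for pol, (a, b) in self.trends.items():
            if pol not in POLLUTANTS:
                raise ValueError(f"unknown pollutant {pol!r}; expected {POLLUTANTS}")
            if a < 0 or b < 0:
                raise ValueError("trend means must be nonnegative")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def target_mean(self, pollutant: str, year: int) -> float:
        start, end = self.trends[pollutant]
        y0, y1 = self.years
        if y1 == y0:
            return start
        return start + (end - start) * (year - y0) / (y1 - y0)


def assign_countries(grid: pd.DataFrame, scenario: SyntheticScenario) -> pd.Series:
    """Country label per grid cell from the scenario's block partition."""
    n_rows, n_cols = _grid_shape(grid)
    rf = (grid["row"] + 0.5) / n_rows
    cf = (grid["col"] + 0.5) / n_cols
    country = np.full(len(grid), "England", dtype=object)
    country[rf >= scenario.scotland_row_frac] = "Scotland"
    wlo, whi = scenario.wales_row_range
    wales = (
        (cf < scenario.wales_col_frac)
        & (rf >= wlo)
        & (rf < whi)
        & (rf < scenario.scotland_row_frac)
    )
    country[wales] = "Wales"
    return pd.Series(country, index=grid.index, name="country")


def hotspot_centres(grid: pd.DataFrame, scenario: SyntheticScenario) -> np.ndarray:
    """Fixed urban-hotspot centres (metres), sampled among England cells."""
    if scenario.n_hotspots == 0:
        return np.empty((0, 2))
    rng = substream(scenario.seed, "hotspots")
    countries = assign_countries(grid, scenario)
    pool = grid.index[countries == "England"]
    if len(pool) == 0:
        pool = grid.index
    pick = rng.choice(pool, size=min(scenario.n_hotspots, len(pool)), replace=False)
    return grid.loc[pick, ["cx", "cy"]].to_numpy(dtype=float)


def _smooth_unit_field(
    shape: tuple[int, int], sigma_cells: float, rng: np.random.Generator
) -> np.ndarray:
    """Kernel-smoothed white noise, rescaled to unit standard deviation."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_exposure(
    grid: pd.DataFrame, scenario: SyntheticScenario
) -> pd.DataFrame:
    """Annual concentration per cell, year and pollutant (long format).

    The field is the sum of a persistent smoothed-noise surface, a smaller
    year-specific smoothed surface, country offsets and Gaussian urban
    bumps; each year it is shifted so the population-share-weighted mean
    hits the trend target, then clamped at zero.
    """
    n_rows, n_cols = _grid_shape(grid)
    shape = (n_rows, n_cols)
    sigma_cells = scenario.correlation_length / float(
        grid.attrs.get("cell_size", 1000.0)
    )
    countries = assign_countries(grid, scenario)
    # population-share weights per cell: country share spread over its cells
    w = np.zeros(len(grid))
    for c in COUNTRIES:
        mask = (countries == c).to_numpy()
        if mask.any():
            w[mask] = scenario.country_pop_shares.get(c, 0.0) / mask.sum()
    if w.sum() <= 0:
        w[:] = 1.0
    w = w / w.sum()

    centres = hotspot_centres(grid, scenario)
    cx = grid["cx"].to_numpy()
    cy = grid["cy"].to_numpy()
    bump = np.zeros(len(grid))
    for hx, hy in centres:
        d2 = (cx - hx) ** 2 + (cy - hy) ** 2
        bump += np.exp(-d2 / (2.0 * scenario.hotspot_sigma**2))

    frames = []
    order = grid["row"].to_numpy() * n_cols + grid["col"].to_numpy()
    for pol in scenario.trends:
        rng = substream(scenario.seed, f"exposure:{pol}")
        base = _smooth_unit_field(shape, sigma_cells, rng).ravel()[order]
        sd = scenario.noise_sd.get(pol, 0.0)
        persist_sd = sd * np.sqrt(max(1.0 - scenario.year_noise_frac**2, 0.0))
        offs = countries.map(scenario.country_offsets.get(pol, {})).fillna(0.0)
        amp = scenario.hotspot_amplitude * (0.5 if pol == "PM25" else 1.0)
        for year in scenario.year_list:
            ynoise = _smooth_unit_field(shape, sigma_cells, rng).ravel()[order]
            val = (
                base * persist_sd
                + ynoise * sd * scenario.year_noise_frac
                + offs.to_numpy()
                + amp * bump
            )
            val = val + (scenario.target_mean(pol, year) - float(w @ val))
            np.maximum(val, 0.0, out=val)
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": grid["cell_id"].to_numpy(),
                        "year": year,
                        "pollutant": pol,
                        "value": val,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pollutant", "year", "cell_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# Small areas
# ---------------------------------------------------------------------------

def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer allocation of `total` proportional to `shares` (sums exactly)."""
    shares = np.asarray(shares, dtype=float)
    shares = shares / shares.sum()
    raw = total * shares
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:rem]] += 1
    return base


def generate_small_areas(
    grid: pd.DataFrame,
    n_areas: int,
    country_shares: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    countries: pd.Series | None = None,
    hotspot_xy: np.ndarray | None = None,
    urban_radius: float = 5000.0,
    urban_share: float = 0.25,
    build_geometry: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the grid into contiguous small areas with labels.

    Areas are grown by seeded multi-source breadth-first search over the
    4-neighbour cell adjacency graph, restricted within countries, so each
    area is contiguous, lies in one country, and every cell belongs to
    exactly one area. England areas get one of nine block regions;
    Scotland and Wales are single regions. Areas within ``urban_radius``
    of a hotspot centre are labelled urban (random labels with probability
    ``urban_share`` when no centres are given).

    Returns ``(areas, assignment)``: the area table (id, country, region,
    urban_rural, n_cells and optionally geometry) and the cell-to-area map.
    """
    n_cells = len(grid)
    if not 1 <= n_areas <= n_cells:
        raise ValueError(f"n_areas must be in [1, {n_cells}], got {n_areas}")
    if countries is None:
        countries = pd.Series(["England"] * n_cells, index=grid.index)
    countries = countries.astype(object)
    present = [c for c in COUNTRIES if (countries == c).any()]
    if country_shares is None:
        country_shares = {c: (countries == c).mean() for c in present}
    shares = np.array([max(country_shares.get(c, 0.0), 0.0) for c in present])
    if shares.sum() <= 0:
        shares = np.array([(countries == c).sum() for c in present], dtype=float)
    counts = _largest_remainder(n_areas, shares)
    # every country with cells needs >= 1 area and <= its cell count
    cells_per = np.array([(countries == c).sum() for c in present])
    counts = np.minimum(np.maximum(counts, 1), cells_per)
    while counts.sum() != n_areas:
        diff = n_areas - counts.sum()
        room = (
            (cells_per - counts) if diff > 0 else (counts - 1)
        )
        i = int(np.argmax(room))
        if room[i] <= 0:
            raise ValueError("cannot allocate areas to countries")
        counts[i] += 1 if diff > 0 else -1

    rng = substream(seed, "areas")
    n_rows, n_cols = _grid_shape(grid)
    pos_of = np.full(n_rows * n_cols, -1, dtype=int)
    pos_of[grid["row"].to_numpy() * n_cols + grid["col"].to_numpy()] = np.arange(
        n_cells
    )
    col = grid["col"].to_numpy()
    row = grid["row"].to_numpy()
    country_arr = countries.to_numpy()
    assign = np.full(n_cells, -1, dtype=int)
    next_area = 0
    area_country: list[str] = []
    for c, k in zip(present, counts):
        members = np.flatnonzero(country_arr == c)
        seeds = rng.choice(members, size=k, replace=False)
        q: deque[int] = deque()
        for s in seeds:
            assign[s] = next_area
            area_country.append(c)
            next_area += 1
            q.append(int(s))
        while q:
            i = q.popleft()
            r, cc = row[i], col[i]
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                nr, nc = r + dr, cc + dc
                if 0 <= nr < n_rows and 0 <= nc < n_cols:
                    j = pos_of[nr * n_cols + nc]
                    if j >= 0 and assign[j] < 0 and country_arr[j] == c:
                        assign[j] = assign[i]
                        q.append(int(j))

    area_ids = np.array([f"A{i:05d}" for i in range(n_areas)])
    assignment = pd.DataFrame(
        {"cell_id": grid["cell_id"].to_numpy(), "area_id": area_ids[assign]}
    )

    cx = grid["cx"].to_numpy()
    cy = grid["cy"].to_numpy()
    acx = np.zeros(n_areas)
    acy = np.zeros(n_areas)
    sizes = np.zeros(n_areas, dtype=int)
    np.add.at(acx, assign, cx)
    np.add.at(acy, assign, cy)
    np.add.at(sizes, assign, 1)
    acx /= sizes
    acy /= sizes

    # region labels: England split into a 3x3 block grid of its extent
    eng = np.array([c == "England" for c in area_country])
    regions = np.array(area_country, dtype=object)
    if eng.any():
        exmin, exmax = acx[eng].min(), acx[eng].max()
        eymin, eymax = acy[eng].min(), acy[eng].max()
        bx = np.clip(
            (3 * (acx - exmin) / max(exmax - exmin, 1e-9)).astype(int), 0, 2
        )
        by = np.clip(
            (3 * (acy - eymin) / max(eymax - eymin, 1e-9)).astype(int), 0, 2
        )
        regions[eng] = np.array(
            [f"England_R{3 * y + x + 1}" for x, y in zip(bx[eng], by[eng])],
            dtype=object,
        )

    if hotspot_xy is not None and len(hotspot_xy) > 0:
        d2 = (
            (acx[:, None] - hotspot_xy[None, :, 0]) ** 2
            + (acy[:, None] - hotspot_xy[None, :, 1]) ** 2
        )
        urban = d2.min(axis=1) <= urban_radius**2
    else:
        urban = rng.random(n_areas) < urban_share

    areas = pd.DataFrame(
        {
            "area_id": area_ids,
            "country": area_country,
            "region": regions,
            "urban_rural": np.where(urban, "urban", "rural"),
            "n_cells": sizes,
            "cx": acx,
            "cy": acy,
        }
    )
    if build_geometry:
        geom_map = {}
        cell_geoms = grid["geometry"].to_numpy()
        for a in range(n_areas):
            geom_map[area_ids[a]] = unary_union(
                [cell_geoms[i] for i in np.flatnonzero(assign == a)]
            )
        areas["geometry"] = areas["area_id"].map(geom_map)
    return areas, assignment


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

DEFAULT_MEAN_SIZE = {"England": 1600.0, "Wales": 1600.0, "Scotland": 760.0}


def generate_population(
    areas: pd.DataFrame,
    age_bands: Sequence[str] = DEFAULT_AGE_BANDS,
    mean_size_by_country: Mapping[str, float] | None = None,
    seed: int = 0,
    dispersion: float = 0.2,
) -> pd.DataFrame:
    """Age-stratified area populations (long: area_id, age_band, population).

    Area totals are gamma-distributed around the country mean (coefficient
    of variation ``dispersion``; zero dispersion gives the mean exactly)
    and split across bands by a fixed GB-like age-share simplex using
    largest-remainder rounding, so band counts sum exactly to the total.
    """
    if len(age_bands) == 0:
        raise ValueError("age_bands must be nonempty")
    means = dict(DEFAULT_MEAN_SIZE)
    if mean_size_by_country:
        means.update(mean_size_by_country)
    for c, m in means.items():
        if m <= 0:
            raise ValueError(f"mean size for {c} must be positive")
    shares = np.array([AGE_SHARES.get(b, 1.0) for b in age_bands], dtype=float)
    shares = shares / shares.sum()
    rng = substream(seed, "population")
    rows = []
    for _, area in areas.iterrows():
        mean = means.get(area["country"], 1600.0)
        if dispersion > 0:
            shape = 1.0 / dispersion**2
            total = int(round(rng.gamma(shape, mean / shape)))
        else:
            total = int(round(mean))
        total = max(total, len(age_bands))  # every band representable
        counts = _largest_remainder(total, shares)
        for b, n in zip(age_bands, counts):
            rows.append((area["area_id"], b, int(n)))
    return pd.DataFrame(rows, columns=["area_id", "age_band", "population"])


def generate_mortality_rates(
    regions: Sequence[str],
    age_bands: Sequence[str] = DEFAULT_AGE_BANDS,
    seed: int = 0,
    base_rate: float = 2.6e-5,
    slope: float = 0.095,
    region_sd: float = 0.05,
) -> pd.DataFrame:
    """Region-by-age mortality rates with a Gompertz age profile.

    rate(region, band) = min(base_rate * exp(slope * midpoint) * u_region, 1)
    where u_region is a small lognormal region multiplier. The multiplier
    is constant within region, so rates stay nondecreasing in age. The
    defaults give a crude all-ages rate near 9 per 1000 person-years under
    the generator's age composition, in line with GB nonexternal mortality.
    """
    if len(regions) == 0 or len(age_bands) == 0:
        raise ValueError("regions and age_bands must be nonempty")
    rng = substream(seed, "mortality")
    rows = []
    for region in regions:
        mult = float(np.exp(rng.normal(0.0, region_sd))) if region_sd > 0 else 1.0
        for b in age_bands:
            rate = min(base_rate * np.exp(slope * age_band_midpoint(b)) * mult, 1.0)
            rows.append((region, b, rate))
    return pd.DataFrame(rows, columns=["region", "age_band", "rate"])
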