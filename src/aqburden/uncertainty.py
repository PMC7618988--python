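"""Monte-Carlo propagation of relative-risk uncertainty.

The only uncertainty propagated is the sampling error of the published
log-RR coefficient: draws are taken from a Gaussian centred on beta-hat
with the standard deviation implied by the published 95% CI, the burden
is recomputed in full for every draw, and 95% empirical confidence
intervals (eCIs) are the percentile interval of the per-draw totals.

One draw set per pollutant is generated and reused across every
aggregation level, year and cut-off, so that intervals are coherent:
per-draw country totals sum exactly to the per-draw national total (the
national total is defined as that sum), and since the burden is strictly
increasing in beta for positive exceedance, the eCI equals the burden
evaluated at the empirical beta percentiles.

Age-specific excess deaths are also combined into directly standardised
excess rates per 100,000 using a fixed standard population (European
Standard Population 2013 weights shipped as defaults).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .burden import RiskCoefficient
from .synthetic import DEFAULT_AGE_BANDS, substream

#: European Standard Population 2013 weights for the nineteen 5-year
#: bands (sum 100,000). Shipped as reference defaults; supply your own
#: weights for any other band scheme.
EUROPEAN_STANDARD_POPULATION_2013: dict[str, float] = {
    "0-4": 5000, "5-9": 5500, "10-14": 5500, "15-19": 5500, "20-24": 6000,
    "25-29": 6000, "30-34": 6500, "35-39": 7000, "40-44": 7000, "45-49": 7000,
    "50-54": 7000, "55-59": 6500, "60-64": 6000, "65-69": 5500, "70-74": 5000,
    "75-79": 4000, "80-84": 2500, "85-89": 1500, "90+": 1000,
}


@dataclass(frozen=True)
class UncertaintyConfig:
    """Monte-Carlo settings for empirical confidence intervals."""

    n_draws: int = 1000
    level: float = 0.95
    seed: int = 0
    method: str = "linear"  # percentile estimator, passed to np.quantile

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be at least 2")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")


def draw_betas(coef: RiskCoefficient, cfg: UncertaintyConfig) -> np.ndarray:
    """Gaussian coefficient draws; seeded per pollutant, reproducible."""
    rng = substream(cfg.seed, f"betas:{coef.pollutant}")
    return rng.normal(coef.beta, coef.sd, size=cfg.n_draws)


def eci(per_draw_totals, cfg: UncertaintyConfig) -> tuple[float, float]:
    """Percentile empirical confidence interval of per-draw totals."""
    vals = np.asarray(per_draw_totals, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 draws for an interval")
    alpha = (1.0 - cfg.level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha], method=cfg.method)
    return float(lo), float(hi)


def _area_arrays(
    x: pd.DataFrame,
    pop: pd.DataFrame,
    rates: pd.DataFrame,
    areas: pd.DataFrame,
    pollutant: str,
):
    """Per-area expected-death weight W_i = sum_a p_ia m_ia and the
    area-by-year exposure matrix, aligned on a common area order."""
    pm = pop.merge(areas[["area_id", "region"]], on="area_id", how="left")
    if pm["region"].isna().any():
        bad = pm.loc[pm["region"].isna(), "area_id"].unique()
        raise ValueError(f"areas without a region: {sorted(bad)[:10]}")
    pm = pm.merge(rates, on=["region", "age_band"], how="left")
    if pm["rate"].isna().any():
        raise ValueError("region/age combinations missing from rates")
    pm["w"] = pm["population"] * pm["rate"]
    W = pm.groupby("area_id")["w"].sum()
    xp = x[x["pollutant"] == pollutant]
    if xp.empty:
        raise ValueError(f"no exposure rows for pollutant {pollutant!r}")
    xv = xp.pivot_table(index="area_id", columns="year", values="value", sort=True)
    if xv.isna().any().any():
        raise ValueError("exposure missing for some area/year combinations")
    W = W.reindex(xv.index)
    if W.isna().any():
        bad = xv.index[W.isna()]
        raise ValueError(f"areas without population/rates: {list(bad)[:10]}")
    return W, xv


def propagate(
    x: pd.DataFrame,
    pop: pd.DataFrame,
    rates: pd.DataFrame,
    areas: pd.DataFrame,
    coef: RiskCoefficient,
    cutoffs: Sequence[float],
    cfg: UncertaintyConfig,
    levels: Sequence[str] = ("gb", "country"),
    return_draws: bool = False,
):
    """Central burden and eCI per (level, group, year, cut-off).

    ``levels`` may contain ``"gb"`` (whole domain) and/or columns of the
    area table (``country``, ``region``, ``urban_rural``). The national
    total is computed as the sum of per-draw country totals, so shared
    draws make the intervals additive-coherent across those two levels.
    """
    W, xv = _area_arrays(x, pop, rates, areas, coef.pollutant)
    Wv = W.to_numpy(dtype=float)
    label_of = areas.set_index("area_id")
    betas = draw_betas(coef, cfg)
    cols = ["level", "group", "year", "pollutant", "cutoff", "central", "low", "high"]

    # group masks per non-gb level; country masks always (gb is their sum)
    def masks_for(column: str) -> dict[str, np.ndarray]:
        lab = label_of.loc[xv.index, column]
        return {g: (lab == g).to_numpy() for g in sorted(lab.unique())}

    country_masks = masks_for("country")
    rows = []
    draws_out: dict[tuple, np.ndarray] = {}
    for year in xv.columns:
        xcol = xv[year].to_numpy(dtype=float)
        for c in cutoffs:
            E = np.maximum(xcol - float(c), 0.0)
            K = 1.0 - np.exp(-np.outer(betas, E))  # draws x areas
            Kc = 1.0 - np.exp(-coef.beta * E)
            ctotals = {}
            ccentral = {}
            for g, mask in country_masks.items():
                ctotals[g] = (K[:, mask] * Wv[mask]).sum(axis=1)
                ccentral[g] = float(np.sum(Wv[mask] * Kc[mask]))
            for level in levels:
                if level == "gb":
                    T = np.sum(list(ctotals.values()), axis=0)
                    lo, hi = eci(T, cfg)
                    central = float(np.sum(list(ccentral.values())))
                    rows.append(
                        ("gb", "GB", year, coef.pollutant, float(c), central, lo, hi)
                    )
                    if return_draws:
                        draws_out[("gb", "GB", year, float(c))] = T
                elif level == "country":
                    for g, T in ctotals.items():
                        lo, hi = eci(T, cfg)
                        rows.append(
                            ("country", g, year, coef.pollutant, float(c),
                             ccentral[g], lo, hi)
                        )
                        if return_draws:
                            draws_out[("country", g, year, float(c))] = T
                else:
                    for g, mask in masks_for(level).items():
                        T = (K[:, mask] * Wv[mask]).sum(axis=1)
                        lo, hi = eci(T, cfg)
                        central = float(np.sum(Wv[mask] * Kc[mask]))
                        rows.append(
                            (level, g, year, coef.pollutant, float(c),
                             central, lo, hi)
                        )
                        if return_draws:
                            draws_out[(level, g, year, float(c))] = T
    out = pd.DataFrame(rows, columns=cols)
    return (out, betas, draws_out) if return_draws else out


def standardized_excess_rate(
    d_by_age: Mapping[str, float] | pd.Series,
    p_by_age: Mapping[str, float] | pd.Series,
    weights: Mapping[str, float] | pd.Series,
) -> float:
    """Directly standardised excess-death rate per 100,000.

    rate = 100000 * sum_a w_a (d_a / p_a) / sum_a w_a over the age bands
    of ``d_by_age``. A band with zero population and zero deaths is
    skipped with a warning; zero population with nonzero deaths is an
    error. Weights must be positive and cover every band.
    """
    d = pd.Series(d_by_age, dtype=float)
    p = pd.Series(p_by_age, dtype=float).reindex(d.index)
    w = pd.Series(weights, dtype=float).reindex(d.index)
    if w.isna().any():
        missing = list(d.index[w.isna()])
        raise ValueError(f"standard weights missing for bands: {missing}")
    if (w <= 0).any():
        raise ValueError("standard weights must be positive")
    if p.isna().any():
        missing = list(d.index[p.isna()])
        raise ValueError(f"population missing for bands: {missing}")
    zero = p == 0
    if (zero & (d > 0)).any():
        bad = list(d.index[zero & (d > 0)])
        raise ValueError(f"zero population with nonzero deaths in bands: {bad}")
    if zero.any():
        warnings.warn(
            f"skipping zero-population bands: {list(d.index[zero])}",
            stacklevel=2,
        )
        d, p, w = d[~zero], p[~zero], w[~zero]
    return float(100000.0 * np.sum(w * (d / p)) / np.sum(w))


def validate_standard_weights(weights: Mapping[str, float]) -> None:
    """Standard-population weights are conventionally scaled to 100,000."""
    total = float(sum(weights.values()))
    if not np.isclose(total, 100000.0, rtol=1e-6):
        raise ValueError(f"standard weights sum to {total}, expected 100000")


def european_standard_weights(
    age_bands: Sequence[str] = DEFAULT_AGE_BANDS,
) -> dict[str, float]:
    """ESP2013 weights restricted to (and validated against) a band list."""
    try:
        w = {b: EUROPEAN_STANDARD_POPULATION_2013[b] for b in age_bands}
    except KeyError as exc:
        raise ValueError(
            f"no shipped ESP2013 weight for band {exc.args[0]!r}; "
            "supply weights for custom band schemes"
        ) from None
    return w
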