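"""Attributable-mortality model under counterfactual concentration limits.

For pollutant j with log-linear concentration-response coefficient beta_j
(log relative risk per ug/m3), the expected premature deaths in small area
i, age band a and year y attributable to annual-mean exposure x_iy above a
counterfactual cut-off c are

    d_iay(c) = p_ia * m_ia * (1 - exp(-beta_j * (x_iy - c)+))

with p_ia the area population in the band, m_ia the baseline (nonexternal)
mortality rate assigned from the area's region, and (x - c)+ = max(x-c, 0)
the exceedance hinge. c = 0 gives the overall burden of the pollutant;
c = limit gives the burden of exceedances above that limit. Populations
and rates are held fixed across years so that years are comparable.

beta is derived from a published relative risk RR per increment Delta
(here 10 ug/m3) as beta = ln(RR)/Delta, with sampling standard deviation
sigma_beta = (ln RR_high - ln RR_low) / (2 * z_0.975 * Delta) from the
95% confidence interval, assuming symmetric Gaussian sampling error on
the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import age_band_lower

Z975 = 1.959964  # standard-normal 97.5th percentile

#: Published all-cause-mortality relative risks per 10 ug/m3 used by default.
DEFAULT_RISKS = {
    "PM25": {"rr": 1.08, "rr_low": 1.06, "rr_high": 1.09, "increment": 10.0},
    "NO2": {"rr": 1.023, "rr_low": 1.008, "rr_high": 1.037, "increment": 10.0},
}


@dataclass(frozen=True)
class RiskEstimate:
    """Relative risk with 95% CI per concentration increment."""

    pollutant: str
    rr: float
    rr_low: float
    rr_high: float
    increment: float = 10.0

    def __post_init__(self) -> None:
        if self.rr <= 0 or self.rr_low <= 0 or self.rr_high <= 0:
            raise ValueError("relative risks must be positive")
        if not self.rr_low <= self.rr <= self.rr_high:
            raise ValueError("require rr_low <= rr <= rr_high")
        if self.increment <= 0:
            raise ValueError("increment must be positive")


@dataclass(frozen=True)
class RiskCoefficient:
    """Log-RR per unit concentration with its sampling standard deviation."""

    pollutant: str
    beta: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def rr_to_beta(est: RiskEstimate) -> RiskCoefficient:
    """beta = ln(RR)/Delta; sigma from the CI width on the log scale."""
    beta = np.log(est.rr) / est.increment
    sd = (np.log(est.rr_high) - np.log(est.rr_low)) / (2.0 * Z975 * est.increment)
    return RiskCoefficient(est.pollutant, float(beta), float(sd))


def default_coefficient(pollutant: str) -> RiskCoefficient:
    if pollutant not in DEFAULT_RISKS:
        raise ValueError(f"no default risk estimate for {pollutant!r}")
    return rr_to_beta(RiskEstimate(pollutant, **DEFAULT_RISKS[pollutant]))


def exceedance(x, c):
    """(x - c)+ : the portion of exposure above the cut-off."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(np.asarray(c) < 0):
        raise ValueError("concentrations and cut-offs must be nonnegative")
    out = np.maximum(x - c, 0.0)
    return float(out) if out.ndim == 0 else out


def attributable_deaths(p, m, beta, x, c=0.0):
    """Evaluate the hinge model elementwise; fractional deaths retained."""
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(p < 0):
        raise ValueError("population must be nonnegative")
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("mortality rates must lie in [0, 1]")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    d = p * m * (1.0 - np.exp(-np.asarray(beta) * exceedance(x, c)))
    return float(d) if np.ndim(d) == 0 else d


def scenario_burden(
    x: pd.DataFrame,
    pop: pd.DataFrame,
    rates: pd.DataFrame,
    areas: pd.DataFrame,
    coef: RiskCoefficient,
    cutoffs: Sequence[float],
    min_age: float | None = None,
) -> pd.DataFrame:
    """Burden table: one row per (area, age band, year, cut-off).

    ``x`` is filtered to the coefficient's pollutant; every area must map
    to a region present in the rate table. Values agree elementwise with
    :func:`attributable_deaths`. By default the relative risk applies to
    every age band; ``min_age`` restricts the calculation to bands whose
    lower bound is at least that age (a common sensitivity choice, e.g.
    adults 30+), dropping the younger bands from the table.
    """
    cutoffs = [float(c) for c in cutoffs]
    if any(c < 0 for c in cutoffs):
        raise ValueError("cut-offs must be nonnegative")
    if min_age is not None:
        keep = pop["age_band"].map(age_band_lower) >= float(min_age)
        pop = pop[keep]
        if pop.empty:
            raise ValueError(f"no age bands at or above min_age={min_age}")
    xp = x[x["pollutant"] == coef.pollutant]
    if xp.empty:
        raise ValueError(f"no exposure rows for pollutant {coef.pollutant!r}")
    pm = pop.merge(areas[["area_id", "region"]], on="area_id", how="left")
    if pm["region"].isna().any():
        bad = pm.loc[pm["region"].isna(), "area_id"].unique()
        raise ValueError(f"areas without a region: {sorted(bad)[:10]}")
    pm = pm.merge(rates, on=["region", "age_band"], how="left")
    if pm["rate"].isna().any():
        bad = pm.loc[pm["rate"].isna(), ["region", "age_band"]].drop_duplicates()
        raise ValueError(
            "region/age combinations missing from rates: "
            + bad.to_string(index=False)
        )
    merged = pm.merge(xp[["area_id", "year", "value"]], on="area_id", how="inner")
    frames = []
    p = merged["population"].to_numpy(dtype=float)
    m = merged["rate"].to_numpy(dtype=float)
    xv = merged["value"].to_numpy(dtype=float)
    for c in cutoffs:
        d = attributable_deaths(p, m, coef.beta, xv, c)
        frames.append(
            pd.DataFrame(
                {
                    "area_id": merged["area_id"],
                    "age_band": merged["age_band"],
                    "year": merged["year"],
                    "pollutant": coef.pollutant,
                    "cutoff": c,
                    "deaths": d,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["cutoff", "year", "area_id", "age_band"], ignore_index=True
    )
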