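"""Climate-side computations for common-garden interpretation.

Seasonal aggregation of monthly climate records, calibrated (Gower)
climatic distance between a source population and a common-garden site, and
population-mean trait-climate Pearson correlations.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SEASONS",
    "seasonal_aggregate",
    "gower_calibrated_distance",
    "trait_climate_correlation",
]

# calendar-year convention: winter pools December with the January/February
# of the same record year
SEASONS: dict[str, tuple[int, int, int]] = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "fall": (9, 10, 11),
}


def seasonal_aggregate(monthly: pd.DataFrame) -> pd.DataFrame:
    """Seasonal means from monthly records.

    ``monthly`` has one row per population and a (variable, month) column
    MultiIndex with months 1..12. Every month must be present for every
    variable; a missing month raises an error naming it. Returns a
    population x (variable, season) table of 3-month arithmetic means.
    """
    if not isinstance(monthly.columns, pd.MultiIndex):
        raise ValueError("monthly table needs a (variable, month) column MultiIndex")
    variables = monthly.columns.get_level_values(0).unique()
    for var in variables:
        have = set(monthly[var].columns)
        lacking = sorted(set(range(1, 13)) - have)
        if lacking:
            raise ValueError(f"variable {var!r} is missing month(s) {lacking}")
    cols = {}
    for var in variables:
        for season, months in SEASONS.items():
            cols[(var, season)] = monthly[var][list(months)].mean(axis=1)
    out = pd.DataFrame(cols, index=monthly.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["variable", "season"])
    out.attrs["winter_convention"] = "calendar-year (December of the same record year)"
    return out


def gower_calibrated_distance(source: Mapping[str, float] | pd.Series,
                              garden: Mapping[str, float] | pd.Series,
                              ranges: Mapping[str, float] | pd.Series) -> float:
    """Calibrated climatic distance: mean over variables of
    |source - garden| / observed range.

    Symmetric in its two endpoints and bounded by 1 whenever deviations do
    not exceed the calibration ranges. Variables with zero range are dropped
    with a warning.
    """
    source, garden, ranges = (pd.Series(x, dtype=float)
                              for x in (source, garden, ranges))
    shared = source.index.intersection(garden.index).intersection(ranges.index)
    if shared.empty:
        raise ValueError("no shared variables between source, garden and ranges")
    r = ranges.loc[shared]
    zero = r <= 0
    if zero.any():
        warnings.warn(f"dropping zero-range variable(s): {sorted(shared[zero])}")
        shared = shared[~zero]
        if shared.empty:
            return np.nan
    dev = (source.loc[shared] - garden.loc[shared]).abs() / ranges.loc[shared]
    return float(dev.mean())


def trait_climate_correlation(traits: pd.Series, climate: pd.DataFrame,
                              exclude: Iterable[str] = ()) -> pd.DataFrame:
    """Pearson correlations between population trait means and each climate
    column, with two-sided t-test p-values.

    ``exclude`` drops populations (e.g. poorly replicated ones) before
    computing; pairs with fewer than 4 populations or zero variance yield
    NaN.
    """
    traits = traits.drop(index=[p for p in exclude if p in traits.index])
    rows = []
    for col in climate.columns:
        merged = pd.concat([traits, climate[col]], axis=1, join="inner").dropna()
        n = len(merged)
        r = p = np.nan
        if n >= 4:
            x, y = merged.iloc[:, 0], merged.iloc[:, 1]
            if x.std() > 0 and y.std() > 0:
                r, p = stats.pearsonr(x, y)
        rows.append({"variable": col, "r": r, "p_value": p, "n": n})
    return pd.DataFrame(rows)
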