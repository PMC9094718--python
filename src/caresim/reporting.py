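"""Presentation tables, derived ratios, and validation utilities.

Produces the headline-style outputs: prevalence tables on the 9-year
presentation grid (counts and proportions with 5th-95th percentile interval
strings), derived growth ratios and percent changes, and backward-validation
comparisons between projected and observed tables.  Also ships a small
reference table of published national projections of dementia/MCI/frailty
prevalence in Japan (2016-2043) used for arithmetic-consistency checks.
"""

from __future__ import annotations

import importlib.resources as resources
import json

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "proportion",
    "change_ratio",
    "build_prevalence_table",
    "backward_validate",
    "load_reference_projections",
    "load_reference_headline",
]


def proportion(count: int, population: int, decimals: int = 2) -> float:
    """Prevalence proportion in percent, ``100 * count / population``.

    Reported to ``decimals`` places (two, matching the prevalence tables).
    """
    if population <= 0:
        raise DataError("population must be positive")
    if count < 0 or count > population:
        raise DataError("count must lie in [0, population]")
    return round(100.0 * count / population, decimals)


def change_ratio(value_t1: float, value_t0: float) -> tuple[float, float]:
    """Growth of a quantity between two periods.

    Returns ``(ratio, percent_change)`` with ``ratio = v1/v0`` and
    ``percent_change = 100 * (v1/v0 - 1)``.  Presentation rounding (one
    decimal for the ratio, nearest integer for the percent change) is left
    to the caller: ``round(ratio, 1)``, ``round(pct)``.
    """
    if value_t0 <= 0:
        raise DataError("baseline value must be positive")
    ratio = value_t1 / value_t0
    return ratio, 100.0 * (ratio - 1.0)


def _interval(lo: float, hi: float, decimals: int = 0) -> str:
    if decimals == 0:
        return f"({lo:.0f}-{hi:.0f})"
    return f"({lo:.{decimals}f}-{hi:.{decimals}f})"


def build_prevalence_table(
    summary: pd.DataFrame, years=None, lower: float = 5.0, upper: float = 95.0
) -> pd.DataFrame:
    """Headline-style prevalence table from an ensemble summary.

    ``summary`` is the ``prevalence`` table of
    :meth:`caresim.bootstrap.ResultEnsemble.summary`.  Output rows are
    year x sex x age group x condition with mean counts/proportions and
    "(p5-p95)" interval strings.  Verifies two invariants on the means:
    the dementia-and-frailty intersection never exceeds either marginal,
    and the 60-74 and >=75 age groups sum to the >=60 group.
    """
    lo = f"p{lower:g}"
    hi = f"p{upper:g}"
    df = summary.copy()
    if years is not None:
        missing = set(years) - set(df["year"].unique())
        if missing:
            raise DataError(f"summary has no rows for years {sorted(missing)}")
        df = df[df["year"].isin(years)]

    piv = df.set_index(["year", "sex", "age_group", "condition"])
    for (year, sex, group), part in df.groupby(["year", "sex", "age_group"]):
        by_cond = part.set_index("condition")["count_mean"]
        inter = by_cond.get("dementia_and_frailty", 0.0)
        if inter > min(by_cond.get("dementia", np.inf), by_cond.get("frailty", np.inf)) + 1e-6:
            raise DataError(
                f"intersection exceeds a marginal in {year}/{sex}/{group}"
            )
    for (year, sex, cond), part in df.groupby(["year", "sex", "condition"]):
        by_group = part.set_index("age_group")["count_mean"]
        if {"60plus", "60_74", "75plus"} <= set(by_group.index):
            if abs(by_group["60_74"] + by_group["75plus"] - by_group["60plus"]) > 1e-6:
                raise DataError(
                    f"age groups do not partition the >=60 total in {year}/{sex}/{cond}"
                )

    out = df[["year", "sex", "age_group", "condition"]].copy()
    out["count"] = df["count_mean"].round(0).astype(int)
    out["count_interval"] = [
        _interval(a, b) for a, b in zip(df[f"count_{lo}"], df[f"count_{hi}"])
    ]
    out["population"] = df["population_mean"].round(0).astype(int)
    out["proportion_pct"] = df["proportion_pct_mean"].round(2)
    out["proportion_interval"] = [
        _interval(a, b, 2)
        for a, b in zip(df[f"proportion_pct_{lo}"], df[f"proportion_pct_{hi}"])
    ]
    return out.reset_index(drop=True)


def backward_validate(
    projected: pd.DataFrame,
    observed: pd.DataFrame,
    keys,
    value_col: str = "proportion_pct",
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Compare a projected table against an observed one, cell by cell.

    Both tables must carry the ``keys`` columns and ``value_col``.  Returns
    per-cell absolute and relative differences plus a ``flagged`` column
    marking cells whose relative difference exceeds ``tolerance``.  A key
    mismatch raises an error listing the unmatched strata.
    """
    keys = list(keys)
    p = projected[keys + [value_col]].rename(columns={value_col: "projected"})
    o = observed[keys + [value_col]].rename(columns={value_col: "observed"})
    merged = p.merge(o, on=keys, how="outer", indicator=True)
    unmatched = merged[merged["_merge"] != "both"]
    if len(unmatched):
        strata = unmatched[keys].to_dict(orient="records")
        raise DataError(f"strata not present in both tables: {strata}")
    merged = merged.drop(columns="_merge")
    merged["abs_diff"] = merged["projected"] - merged["observed"]
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["rel_diff"] = np.where(
            merged["observed"] != 0,
            merged["abs_diff"] / merged["observed"],
            np.where(merged["projected"] == 0, 0.0, np.inf),
        )
    merged["flagged"] = np.abs(merged["rel_diff"]) > tolerance
    return merged


# ---------------------------------------------------------------------------
# published reference numbers (arithmetic-consistency checks)
# ---------------------------------------------------------------------------

def load_reference_projections() -> pd.DataFrame:
    """Published national projection table: counts, populations, proportions.

    Columns: year, sex, age_group, condition, count, population,
    printed_proportion_pct.  The printed proportions equal
    ``100 * count / population`` to their printed precision.
    """
    with resources.files("caresim.data").joinpath(
        "reference_projections_japan.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def load_reference_headline() -> dict:
    """Published headline cost totals (billions, constant 2016 US$)."""
    with resources.files("caresim.data").joinpath("reference_headline.json").open() as fh:
        return json.load(fh)
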