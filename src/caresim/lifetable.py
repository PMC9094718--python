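"""Period life tables and the Sullivan partition of life expectancy.

Life tables are built from the simulation's occurrence/exposure mortality
experience: central death rates ``m_x = deaths / person-years`` are
converted to interval death probabilities with the mid-interval assumption
``q_x = w m_x / (1 + (w/2) m_x)`` for closed intervals of width ``w`` and an
open terminal interval with the ``L = l / m`` convention.  The Sullivan
method then splits remaining life expectancy at the table's start age into
years lived with and without a condition by weighting the person-years
column with age-specific prevalence:

    years_with = sum_x prevalence_x * L_x / l_start
    years_without = e_start - years_with
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "LifeTable",
    "StateLifeExpectancy",
    "life_table_from_rates",
    "life_table_from_qx",
    "build_period_life_table",
    "sullivan_partition",
]


@dataclass
class LifeTable:
    """Columns: age (interval start), width, qx, lx, Lx, Tx, ex.

    The last row is the open terminal interval (``width`` NaN).  ``lx`` is
    non-increasing with radix 1 at the start age; ``ex = Tx / lx``.
    """

    frame: pd.DataFrame
    stratum: dict = field(default_factory=dict)

    @property
    def start_age(self) -> float:
        return float(self.frame["age"].iloc[0])

    @property
    def ex_start(self) -> float:
        """Remaining life expectancy at the table's start age."""
        return float(self.frame["ex"].iloc[0])

    def abridged(self, width: int = 5) -> "LifeTable":
        """Re-express a single-year table on ``width``-year intervals."""
        f = self.frame
        closed = f.iloc[:-1]
        groups = ((closed["age"] - self.start_age) // width).astype(int)
        rows = []
        for g, part in closed.groupby(groups):
            age0 = float(part["age"].iloc[0])
            lx = float(part["lx"].iloc[0])
            Lx = float(part["Lx"].sum())
            l_next = lx - float((part["lx"] * part["qx"]).sum())
            qx = (lx - l_next) / lx if lx > 0 else 0.0
            rows.append((age0, float(width), qx, lx, Lx))
        term = f.iloc[-1]
        rows.append((float(term["age"]), np.nan, 1.0, float(term["lx"]), float(term["Lx"])))
        out = pd.DataFrame(rows, columns=["age", "width", "qx", "lx", "Lx"])
        out["Tx"] = out["Lx"][::-1].cumsum()[::-1]
        out["ex"] = np.where(out["lx"] > 0, out["Tx"] / out["lx"].replace(0, np.nan), 0.0)
        out["ex"] = out["ex"].fillna(0.0)
        return LifeTable(out, dict(self.stratum))


def life_table_from_qx(
    qx, start_age: float = 65.0, width: float = 1.0, terminal_m: float | None = None,
    stratum: dict | None = None,
) -> LifeTable:
    """Build a life table from interval death probabilities.

    ``qx`` covers the closed intervals; an open terminal interval is
    appended with ``L = l / m`` (``terminal_m`` defaults to the central rate
    implied by the last closed interval's ``q``).
    """
    qx = np.asarray(qx, dtype=float)
    if (qx < 0).any() or (qx > 1).any():
        raise DataError("qx outside [0, 1]")
    n = len(qx)
    lx = np.empty(n + 1)
    lx[0] = 1.0
    for i in range(n):
        lx[i + 1] = lx[i] * (1.0 - qx[i])
    dx = lx[:-1] - lx[1:]
    Lx_closed = width * (lx[:-1] - 0.5 * dx)

    l_term = lx[-1]
    if terminal_m is None:
        q_last = qx[-1]
        terminal_m = q_last / (width * (1.0 - 0.5 * q_last)) if q_last < 1 else np.inf
    if l_term > 0:
        if not terminal_m > 0:
            raise DataError(
                "terminal central death rate must be positive while survivors remain "
                f"(age {start_age + n * width:g})"
            )
        L_term = l_term / terminal_m
    else:
        L_term = 0.0

    ages = start_age + width * np.arange(n + 1)
    frame = pd.DataFrame(
        {
            "age": ages,
            "width": np.append(np.full(n, width), np.nan),
            "qx": np.append(qx, 1.0),
            "lx": lx,
            "Lx": np.append(Lx_closed, L_term),
        }
    )
    frame["Tx"] = frame["Lx"][::-1].cumsum()[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(frame["lx"] > 0, frame["Tx"] / frame["lx"], 0.0)
    frame["ex"] = ex
    return LifeTable(frame, stratum or {})


def life_table_from_rates(
    m, start_age: float = 65.0, width: float = 1.0, terminal_m: float | None = None,
    stratum: dict | None = None,
) -> LifeTable:
    """Convert central death rates to ``qx`` and build the table."""
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise DataError("negative central death rate")
    # mid-interval conversion; capped at 1 (the formula exceeds 1 when
    # m > 1/(w/2), which sparse high-mortality intervals can produce)
    qx = np.minimum(width * m / (1.0 + 0.5 * width * m), 1.0)
    return life_table_from_qx(
        qx, start_age=start_age, width=width, terminal_m=terminal_m, stratum=stratum
    )


def build_period_life_table(
    experience: pd.DataFrame,
    stratum: dict | None = None,
    years=None,
    start_age: int = 65,
    width: int = 1,
    terminal_age: int = 100,
) -> LifeTable:
    """Period life table from an occurrence/exposure mortality experience.

    Parameters
    ----------
    experience : DataFrame
        Columns ``year, age, female, education, deaths, exposure`` as
        produced by :func:`caresim.engine.simulate`.
    stratum : dict, optional
        Filter, e.g. ``{"female": 1}`` or ``{"female": 0, "education": 2}``.
    years : int or iterable of int, optional
        Calendar years pooled into the period (default: all present).
    width : int
        Closed-interval width in years (1 = single-year, 5 = abridged).
    terminal_age : int
        Start of the open terminal interval.

    Raises
    ------
    DataError
        If any age interval in ``[start_age, terminal_age]`` has zero
        exposure (the error names the cell).
    """
    df = experience
    if years is not None:
        years = [years] if np.isscalar(years) else list(years)
        df = df[df["year"].isin(years)]
    stratum = stratum or {}
    for key, val in stratum.items():
        df = df[df[key] == val]
    df = df[df["age"] >= start_age]
    if df.empty:
        raise DataError(f"no mortality experience for stratum {stratum} years {years}")

    edges = list(range(start_age, terminal_age, width))
    bins = np.digitize(df["age"], edges[1:] + [terminal_age], right=False)
    # bins index into closed intervals 0..len(edges)-1, terminal = len(edges)
    agg = (
        pd.DataFrame(
            {"bin": bins, "deaths": df["deaths"].to_numpy(), "exposure": df["exposure"].to_numpy()}
        )
        .groupby("bin")
        .sum()
        .reindex(range(len(edges) + 1), fill_value=0.0)
    )
    for b in range(len(edges) + 1):
        if agg["exposure"].iloc[b] <= 0:
            lo = terminal_age if b == len(edges) else edges[b]
            label = f"{lo}+" if b == len(edges) else f"{lo}-{lo + width - 1}"
            raise DataError(f"zero exposure in age interval {label} for stratum {stratum}")
    m = (agg["deaths"] / agg["exposure"]).to_numpy()
    terminal_m = float(m[-1])
    if terminal_m <= 0 and m[:-1].max() > 0:
        # no deaths observed in the open interval: carry the last closed
        # interval's central rate forward rather than implying immortality
        terminal_m = float(m[:-1][m[:-1] > 0][-1])
    return life_table_from_rates(
        m[:-1], start_age=start_age, width=width, terminal_m=terminal_m,
        stratum={**stratum, "years": years},
    )


@dataclass
class StateLifeExpectancy:
    """Sullivan partition of life expectancy for one condition/stratum."""

    condition: str
    total_ex: float
    years_with: float
    years_without: float
    stratum: dict = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.years_with + self.years_without - self.total_ex) > 1e-9:
            raise DataError("Sullivan partition identity violated beyond 1e-9")


def sullivan_partition(
    table: LifeTable, prevalence, condition: str = "condition"
) -> StateLifeExpectancy:
    """Split ``e_start`` into years with and without a condition.

    ``prevalence`` is the age-specific proportion with the condition,
    aligned with the life-table rows: an array of the same length, or a
    mapping / :class:`pandas.Series` keyed by interval start age.
    """
    f = table.frame
    if isinstance(prevalence, (dict, pd.Series)):
        prev = np.array([float(pd.Series(prevalence).get(a, np.nan)) for a in f["age"]])
        if np.isnan(prev).any():
            missing = [a for a, p in zip(f["age"], prev) if np.isnan(p)]
            raise DataError(f"prevalence missing for ages {missing}")
    else:
        prev = np.asarray(prevalence, dtype=float)
        if prev.shape != (len(f),):
            raise DataError(
                f"prevalence length {prev.shape} does not match table rows {len(f)}"
            )
    if (prev < 0).any() or (prev > 1).any():
        raise DataError("prevalence outside [0, 1]")
    l0 = float(f["lx"].iloc[0])
    years_with = float((prev * f["Lx"].to_numpy()).sum() / l0)
    total = table.ex_start
    return StateLifeExpectancy(
        condition=condition,
        total_ex=total,
        years_with=years_with,
        years_without=total - years_with,
        stratum=dict(table.stratum),
    )
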