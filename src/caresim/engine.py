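"""Half-year Markov transition engine for the simulated population.

The population evolves in first-order Markov cycles of half a year.  Within
one cycle the event order is fixed: (1) a mortality draw from the
age-band x sex x education table, with optional multiplicative log-hazard
offsets for current chronic conditions; (2) incidence draws for each chronic
condition the survivor does not yet have (conditions are non-reversible);
(3) functional decline (ADL/IADL limitation increments), depression onset and
self-reported-health drift; finally ages advance by half a year.  Dead
individuals are frozen.  Entry cohorts aged 60-62 are injected once per
calendar year from an education-stratified schedule, thinned by pre-entry
mortality.

Every draw in a step consumes a fixed number of uniforms per row regardless
of vital status, so two runs sharing a seed use common random numbers and
differ only where parameters differ; this makes monotonicity comparisons
(e.g. raising one mortality cell) sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ADL_ITEMS,
    AGE_BANDS,
    CONDITIONS,
    EDUCATION_LEVELS,
    IADL_ITEMS,
    MAX_AGE,
    N_AGE_BANDS,
    SEXES,
    age_band_index,
    condition_matrix,
    validate_population,
)
from .errors import ConfigurationError, DataError, MissingStratumError

__all__ = [
    "TransitionParameters",
    "PopulationState",
    "Trajectory",
    "step_half_year",
    "inject_entry_cohort",
    "simulate",
    "half_year_from_interval",
    "interval_from_half_year",
]

_FUNCTIONAL_KEYS = ("adl", "iadl", "depression", "srh_worsen")
# uniform-draw layout per row per step: mortality, 11 incidences, 4 functional
_N_DRAWS = 1 + len(CONDITIONS) + len(_FUNCTIONAL_KEYS)


def half_year_from_interval(p: np.ndarray | float, years: float = 3.0):
    """Convert an interval transition probability to the half-year cycle.

    ``p_half = 1 - (1 - p)**(0.5 / years)``; with ``years=3`` this is the
    1/6-power relation between the 3-year reporting grid and the engine cycle.
    """
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** (0.5 / years)


def interval_from_half_year(p_half: np.ndarray | float, years: float = 3.0):
    """Inverse of :func:`half_year_from_interval`."""
    return 1.0 - (1.0 - np.asarray(p_half, dtype=float)) ** (years / 0.5)


@dataclass
class TransitionParameters:
    """Half-year transition probability tables.

    Attributes
    ----------
    incidence : ndarray, shape (bands, 2, 3, 11)
        Half-year incidence probability per age band x sex x education x
        condition.
    mortality : ndarray, shape (bands, 2, 3)
        Baseline half-year death probability per age band x sex x education.
    condition_mortality_loghr : ndarray, shape (11,)
        Log hazard-ratio of death per current condition, applied
        multiplicatively on the hazard scale.
    functional : dict of ndarray, shape (bands,)
        Half-year probabilities for ADL-limitation increment, IADL-limitation
        increment, depression onset, and a one-step worsening of
        self-reported health (keys ``adl``, ``iadl``, ``depression``,
        ``srh_worsen``).
    entry_schedule : DataFrame or None
        Columns ``year``, ``count``, ``share_less_than_high_school``,
        ``share_high_school``, ``share_college_or_higher``, ``share_female``,
        ``pre_entry_survival``; one row per calendar year of cohort entry.
    entry_condition_prob : ndarray, shape (3, 11)
        Prevalence of each condition among entrants, by education.
    entry_depression_prob : float
        Depression prevalence among entrants.
    """

    incidence: np.ndarray
    mortality: np.ndarray
    condition_mortality_loghr: np.ndarray = field(
        default_factory=lambda: np.zeros(len(CONDITIONS))
    )
    functional: dict = field(
        default_factory=lambda: {k: np.zeros(N_AGE_BANDS) for k in _FUNCTIONAL_KEYS}
    )
    entry_schedule: pd.DataFrame | None = None
    entry_condition_prob: np.ndarray = field(
        default_factory=lambda: np.zeros((3, len(CONDITIONS)))
    )
    entry_depression_prob: float = 0.03

    def __post_init__(self):
        self.incidence = np.asarray(self.incidence, dtype=float)
        self.mortality = np.asarray(self.mortality, dtype=float)
        self.condition_mortality_loghr = np.asarray(
            self.condition_mortality_loghr, dtype=float
        )
        self.validate()

    def validate(self) -> None:
        if self.incidence.shape != (N_AGE_BANDS, 2, 3, len(CONDITIONS)):
            raise DataError(
                f"incidence table has shape {self.incidence.shape}, expected "
                f"{(N_AGE_BANDS, 2, 3, len(CONDITIONS))}"
            )
        if self.mortality.shape != (N_AGE_BANDS, 2, 3):
            raise DataError(
                f"mortality table has shape {self.mortality.shape}, expected "
                f"{(N_AGE_BANDS, 2, 3)}"
            )
        for name, table in (("incidence", self.incidence), ("mortality", self.mortality)):
            if np.isnan(table).any():
                idx = np.argwhere(np.isnan(table))[0]
                raise MissingStratumError(
                    name,
                    age_band=AGE_BANDS[idx[0]],
                    sex=SEXES[idx[1]],
                    education=EDUCATION_LEVELS[idx[2]],
                    **({"condition": CONDITIONS[idx[3]]} if name == "incidence" else {}),
                )
            if (table < 0).any() or (table > 1).any():
                raise DataError(f"{name} probabilities outside [0, 1]")
        for key in _FUNCTIONAL_KEYS:
            p = np.asarray(self.functional[key], dtype=float)
            if p.shape != (N_AGE_BANDS,) or (p < 0).any() or (p > 1).any():
                raise DataError(f"functional[{key!r}] must be (bands,) probabilities")
            self.functional[key] = p

    # -- CSV round trip -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format view of the incidence/mortality/functional tables."""
        rows = []
        for b, band in enumerate(AGE_BANDS):
            for s, sex in enumerate(SEXES):
                for e, edu in enumerate(EDUCATION_LEVELS):
                    rows.append(("mortality", band, sex, edu, "", self.mortality[b, s, e]))
                    for c, cond in enumerate(CONDITIONS):
                        rows.append(
                            ("incidence", band, sex, edu, cond, self.incidence[b, s, e, c])
                        )
            for key in _FUNCTIONAL_KEYS:
                rows.append(("functional", band, "", "", key, self.functional[key][b]))
        for c, cond in enumerate(CONDITIONS):
            rows.append(("mortality_loghr", "", "", "", cond, self.condition_mortality_loghr[c]))
        return pd.DataFrame(
            rows, columns=["table", "age_band", "sex", "education", "key", "value"]
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, entry_schedule: pd.DataFrame | None = None, **kwargs
    ) -> "TransitionParameters":
        incidence = np.full((N_AGE_BANDS, 2, 3, len(CONDITIONS)), np.nan)
        mortality = np.full((N_AGE_BANDS, 2, 3), np.nan)
        functional = {k: np.zeros(N_AGE_BANDS) for k in _FUNCTIONAL_KEYS}
        loghr = np.zeros(len(CONDITIONS))
        band_i = {b: i for i, b in enumerate(AGE_BANDS)}
        sex_i = {s: i for i, s in enumerate(SEXES)}
        edu_i = {e: i for i, e in enumerate(EDUCATION_LEVELS)}
        cond_i = {c: i for i, c in enumerate(CONDITIONS)}
        for row in frame.itertuples(index=False):
            if row.table == "mortality":
                mortality[band_i[row.age_band], sex_i[row.sex], edu_i[row.education]] = row.value
            elif row.table == "incidence":
                incidence[
                    band_i[row.age_band], sex_i[row.sex], edu_i[row.education], cond_i[row.key]
                ] = row.value
            elif row.table == "functional":
                functional[row.key][band_i[row.age_band]] = row.value
            elif row.table == "mortality_loghr":
                loghr[cond_i[row.key]] = row.value
        return cls(
            incidence=incidence,
            mortality=mortality,
            condition_mortality_loghr=loghr,
            functional=functional,
            entry_schedule=entry_schedule,
            **kwargs,
        )


@dataclass
class PopulationState:
    """A population snapshot: person table plus calendar time.

    ``time`` is the calendar year with half-year resolution (e.g. 2016.0,
    2016.5, ...).
    """

    frame: pd.DataFrame
    time: float

    def __post_init__(self):
        validate_population(self.frame)

    @property
    def n_alive(self) -> int:
        return int(self.frame["alive"].sum())

    @property
    def year(self) -> int:
        return int(np.floor(self.time + 1e-9))

    def copy(self) -> "PopulationState":
        return PopulationState(self.frame.copy(), self.time)

    def alive_frame(self) -> pd.DataFrame:
        return self.frame.loc[self.frame["alive"]]


def _effective_mortality(frame: pd.DataFrame, params: TransitionParameters,
                         band, sexi, edui) -> np.ndarray:
    q = params.mortality[band, sexi, edui]
    loghr = condition_matrix(frame) @ params.condition_mortality_loghr
    if np.any(loghr != 0.0):
        hazard = -np.log1p(-np.clip(q, 0.0, 1.0 - 1e-12))
        q = -np.expm1(-hazard * np.exp(loghr))
    return q


def step_half_year(
    state: PopulationState, params: TransitionParameters, rng: np.random.Generator
) -> PopulationState:
    """Advance the population by one half-year Markov cycle.

    Returns a new :class:`PopulationState`; the input is not modified.
    """
    frame = state.frame.copy()
    n = len(frame)
    draws = rng.random((n, _N_DRAWS)) if n else np.empty((0, _N_DRAWS))

    alive0 = frame["alive"].to_numpy()
    age = frame["age"].to_numpy()
    band = age_band_index(age)
    sexi = frame["female"].to_numpy(dtype=np.intp)
    edui = frame["education"].to_numpy(dtype=np.intp)

    # (1) mortality
    q = _effective_mortality(frame, params, band, sexi, edui)
    dies = alive0 & (draws[:, 0] < q)
    alive1 = alive0 & ~dies
    frame["alive"] = alive1

    # (2) condition incidence among survivors
    for j, cond in enumerate(CONDITIONS):
        p = params.incidence[band, sexi, edui, j]
        onset = alive1 & (frame[cond].to_numpy() == 0) & (draws[:, 1 + j] < p)
        if onset.any():
            frame.loc[onset, cond] = np.int8(1)

    # (3) functional decline, depression, self-reported health
    base = 1 + len(CONDITIONS)
    f = params.functional
    adl_up = alive1 & (draws[:, base] < f["adl"][band])
    iadl_up = alive1 & (draws[:, base + 1] < f["iadl"][band])
    dep_on = (
        alive1
        & (frame["depression"].to_numpy() == 0)
        & (draws[:, base + 2] < f["depression"][band])
    )
    srh_worse = alive1 & (draws[:, base + 3] < f["srh_worsen"][band])
    frame.loc[adl_up, "adl_limited"] = np.minimum(
        frame.loc[adl_up, "adl_limited"] + 1, ADL_ITEMS
    ).astype(np.int8)
    frame.loc[iadl_up, "iadl_limited"] = np.minimum(
        frame.loc[iadl_up, "iadl_limited"] + 1, IADL_ITEMS
    ).astype(np.int8)
    if dep_on.any():
        frame.loc[dep_on, "depression"] = np.int8(1)
    frame.loc[srh_worse, "self_reported_health"] = np.minimum(
        frame.loc[srh_worse, "self_reported_health"] + 1, 5
    ).astype(np.int8)

    # survivors age by half a year (dead individuals stay frozen)
    frame.loc[alive1, "age"] = np.minimum(age[alive1] + 0.5, float(MAX_AGE))

    return PopulationState(frame, state.time + 0.5)


def inject_entry_cohort(
    state: PopulationState, params: TransitionParameters, rng: np.random.Generator
) -> PopulationState:
    """Append the entry cohort (ages 60-62) for the current calendar year.

    Entrant counts per education stratum are thinned binomially by the
    schedule's pre-entry cumulative survival, emulating attrition between
    the census cohort and model entry at age 60.
    """
    schedule = params.entry_schedule
    if schedule is None:
        raise DataError("no entry schedule configured")
    year = state.year
    row = schedule.loc[schedule["year"] == year]
    if row.empty:
        raise DataError(f"entry schedule has no row for year {year}")
    row = row.iloc[0]
    total = int(row["count"])
    if total <= 0:
        return state.copy()

    shares = np.array(
        [row[f"share_{e}"] for e in EDUCATION_LEVELS], dtype=float
    )
    if shares.min() < 0 or abs(shares.sum() - 1.0) > 1e-9:
        raise ConfigurationError("entry education shares must be a distribution")
    survival = float(row["pre_entry_survival"])
    if not 0.0 <= survival <= 1.0:
        raise ConfigurationError("pre_entry_survival must be in [0, 1]")

    # largest-remainder split of the scheduled count across strata
    raw = shares * total
    counts = np.floor(raw).astype(int)
    rem = total - counts.sum()
    if rem > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
    realized = np.array([rng.binomial(c, survival) for c in counts])
    m = int(realized.sum())
    if m == 0:
        return state.copy()

    from .core import empty_population

    entrants = empty_population(m)
    next_id = int(state.frame["id"].max()) + 1 if len(state.frame) else 0
    entrants["id"] = np.arange(next_id, next_id + m, dtype=np.int64)
    entrants["education"] = np.repeat(np.arange(3, dtype=np.int8), realized)
    entrants["age"] = rng.integers(60, 63, size=m).astype(float)
    entrants["female"] = (rng.random(m) < float(row.get("share_female", 0.5))).astype(np.int8)
    for e in range(3):
        mask = entrants["education"].to_numpy() == e
        if mask.any():
            probs = params.entry_condition_prob[e]
            u = rng.random((int(mask.sum()), len(CONDITIONS)))
            flags = (u < probs).astype(np.int8)
            for j, cond in enumerate(CONDITIONS):
                entrants.loc[mask, cond] = flags[:, j]
    entrants["depression"] = (rng.random(m) < params.entry_depression_prob).astype(np.int8)
    entrants["self_reported_health"] = np.int8(2)

    frame = pd.concat([state.frame, entrants], ignore_index=True)
    return PopulationState(frame, state.time)


@dataclass
class Trajectory:
    """Result of :func:`simulate`: snapshots on the reporting grid plus the
    mortality occurrence/exposure experience needed for period life tables."""

    snapshots: list
    mortality_experience: pd.DataFrame
    entrants: dict
    report_interval: int

    @property
    def years(self):
        return [s.year for s in self.snapshots]

    def snapshot_at(self, year: int) -> PopulationState:
        for s in self.snapshots:
            if s.year == year:
                return s
        raise DataError(f"no snapshot for year {year}; available: {self.years}")


def simulate(
    baseline: PopulationState,
    params: TransitionParameters,
    horizon_years: int,
    rng: np.random.Generator,
    report_interval: int = 3,
    inject_entrants: bool = True,
) -> Trajectory:
    """Run ``2 * horizon_years`` half-year cycles with annual cohort entry.

    Snapshots are taken at the baseline and every ``report_interval`` years.
    The returned mortality experience table records deaths and person-years
    of exposure by calendar year x single year of age x sex x education,
    with the mid-interval convention (a death contributes a quarter-year of
    exposure within its half-year cycle).
    """
    if horizon_years % report_interval != 0:
        raise ConfigurationError(
            f"horizon ({horizon_years}) must be divisible by the report "
            f"interval ({report_interval})"
        )
    params.validate()
    state = baseline.copy()
    snapshots = [state.copy()]
    exposure_parts = []
    entrants: dict[int, int] = {}

    steps = 2 * horizon_years
    for k in range(1, steps + 1):
        pre = state
        year = pre.year
        state = step_half_year(pre, params, rng)

        alive0 = pre.frame["alive"].to_numpy()
        died = alive0 & ~state.frame["alive"].to_numpy()
        if alive0.any():
            part = pd.DataFrame(
                {
                    "year": year,
                    "age": np.floor(pre.frame["age"].to_numpy()[alive0]).astype(int),
                    "female": pre.frame["female"].to_numpy()[alive0],
                    "education": pre.frame["education"].to_numpy()[alive0],
                    "deaths": died[alive0].astype(int),
                    "exposure": 0.5 - 0.25 * died[alive0],
                }
            )
            exposure_parts.append(
                part.groupby(["year", "age", "female", "education"], as_index=False).sum()
            )

        if inject_entrants and k % 2 == 0 and params.entry_schedule is not None:
            before = len(state.frame)
            state = inject_entry_cohort(state, params, rng)
            entrants[state.year] = len(state.frame) - before

        if k % (2 * report_interval) == 0:
            snapshots.append(state.copy())

    if exposure_parts:
        experience = (
            pd.concat(exposure_parts, ignore_index=True)
            .groupby(["year", "age", "female", "education"], as_index=False)
            .sum()
        )
    else:
        experience = pd.DataFrame(
            columns=["year", "age", "female", "education", "deaths", "exposure"]
        )
    return Trajectory(snapshots, experience, entrants, report_interval)
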