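"""Bootstrap uncertainty quantification for the projection pipeline.

The pipeline is replicated (default 50 iterations) with independent derived
seeds: every iteration redraws the stochastic baseline population, the
entry cohorts and all transition/classification randomness, while the
estimated model coefficients are held fixed across iterations.  Uncertainty
is summarised per cell as the mean, the 5th-95th percentile range
(nearest-rank convention) and the Monte-Carlo standard error
``sd / sqrt(n_iterations)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import derive_int_seed
from .errors import DataError
from .pipeline import FittedModels, PipelineConfig, fit_models, run_once

__all__ = ["ResultEnsemble", "bootstrap_run", "percentile_interval", "nearest_rank"]

#: Value columns per result table; all other columns are grouping keys.
VALUE_COLUMNS = {
    "prevalence": ("count", "population", "proportion_pct"),
    "life_expectancy": ("life_expectancy", "years_with", "years_without"),
    "costs_total": ("total",),
    "costs_per_capita": ("n", "healthcare", "formal_ltc", "informal", "n_comorbidities"),
    "thresholds": (
        "theta_dementia",
        "theta_mci",
        "theta_frail",
        "achieved_dementia",
        "achieved_mci",
        "achieved_frailty",
    ),
}


def nearest_rank(values, p: float) -> float:
    """Empirical percentile by the nearest-rank convention.

    For ``n`` sorted values the ``p``-th percentile is the value at rank
    ``ceil(p/100 * n)`` (at least 1).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise DataError("no values")
    rank = max(int(np.ceil(p / 100.0 * v.size)), 1)
    return float(v[min(rank, v.size) - 1])


@dataclass
class ResultEnsemble:
    """Per-iteration result tables plus summary utilities.

    ``tables[name]`` stacks one pipeline table across iterations with an
    ``iteration`` column; ``seeds[i]`` is the master seed of iteration i
    (for replay).
    """

    tables: dict
    seeds: list
    config_digest: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.seeds)

    def summary(self, lower: float = 5.0, upper: float = 95.0) -> dict:
        return {
            name: percentile_interval(frame, name, lower=lower, upper=upper)
            for name, frame in self.tables.items()
        }


def percentile_interval(
    frame_or_ensemble,
    table: str | None = None,
    lower: float = 5.0,
    upper: float = 95.0,
):
    """Summarise an ensemble table: mean, percentile range, Monte-Carlo s.e.

    Accepts either a stacked per-iteration DataFrame (with its table name,
    to select the value columns) or a whole :class:`ResultEnsemble` (then
    returns a dict of summaries).  Percentiles use the nearest-rank
    convention and are invariant to iteration order.
    """
    if isinstance(frame_or_ensemble, ResultEnsemble):
        return frame_or_ensemble.summary(lower=lower, upper=upper)
    frame = frame_or_ensemble
    if table not in VALUE_COLUMNS:
        raise DataError(f"unknown result table {table!r}")
    value_cols = [c for c in VALUE_COLUMNS[table] if c in frame.columns]
    keys = [c for c in frame.columns if c not in value_cols and c != "iteration"]
    lo_name = f"p{lower:g}"
    hi_name = f"p{upper:g}"

    def agg(part: pd.DataFrame) -> pd.Series:
        out = {}
        for c in value_cols:
            v = part[c].to_numpy(dtype=float)
            out[f"{c}_mean"] = float(np.mean(v))
            out[f"{c}_{lo_name}"] = nearest_rank(v, lower)
            out[f"{c}_{hi_name}"] = nearest_rank(v, upper)
            out[f"{c}_mc_se"] = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        out["n_iterations"] = len(part)
        return pd.Series(out)

    if keys:
        result = frame.groupby(keys, dropna=False).apply(agg, include_groups=False).reset_index()
    else:
        result = agg(frame).to_frame().T
    return result


def _digest(config: PipelineConfig) -> str:
    text = repr(config).encode()
    return hashlib.sha256(text).hexdigest()[:16]


def bootstrap_run(
    config: PipelineConfig,
    n_iterations: int | None = None,
    master_seed: int = 0,
    fitted: FittedModels | None = None,
    refit_each_iteration: bool = False,
) -> ResultEnsemble:
    """Replicate the full pipeline with independent derived seeds.

    Model coefficients are estimated once (from the fixture seed derived
    from ``master_seed``) and held fixed across iterations; pass
    ``refit_each_iteration=True`` to also resample the estimation surveys
    per iteration (beyond the default design).  Any iteration failure
    aborts the run, reporting the iteration id and seed for replay.
    """
    n_iterations = n_iterations if n_iterations is not None else config.n_bootstrap
    if n_iterations < 1:
        raise DataError("need at least one iteration")
    if fitted is None and not refit_each_iteration:
        fitted = fit_models(config, derive_int_seed(master_seed, "fit"))

    tables: dict[str, list] = {name: [] for name in VALUE_COLUMNS}
    seeds = []
    for i in range(n_iterations):
        seed_i = derive_int_seed(master_seed, "iteration", i)
        seeds.append(seed_i)
        try:
            iter_fitted = (
                fit_models(config, derive_int_seed(seed_i, "fit"))
                if refit_each_iteration
                else fitted
            )
            result = run_once(config, seed_i, fitted=iter_fitted)
        except Exception as exc:
            raise RuntimeError(
                f"bootstrap iteration {i} (seed {seed_i}) failed: {exc}"
            ) from exc
        for name, frame in result.tables().items():
            tables[name].append(frame.assign(iteration=i))

    stacked = {name: pd.concat(parts, ignore_index=True) for name, parts in tables.items()}
    return ResultEnsemble(
        tables=stacked,
        seeds=seeds,
        config_digest=_digest(config),
        meta={"master_seed": master_seed, "n_iterations": n_iterations},
    )
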