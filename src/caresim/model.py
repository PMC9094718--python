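"""Model/results facade over the projection pipeline.

`DementiaFrailtyModel` is constructed from a configuration (or built with
sensible defaults); its :meth:`~DementiaFrailtyModel.fit` estimates the
classification and cost models, runs the bootstrap ensemble of projections
and returns a :class:`ProjectionResults` carrying the prevalence,
life-expectancy and cost estimates with their 5th-95th percentile
uncertainty and a formatted :meth:`~ProjectionResults.summary`.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .bootstrap import ResultEnsemble, bootstrap_run
from .pipeline import FittedModels, PipelineConfig, fit_models
from .reporting import build_prevalence_table
from .synthetic import GeneratorConfig

__all__ = ["DementiaFrailtyModel", "ProjectionResults"]


class DementiaFrailtyModel:
    """Joint dementia-frailty microsimulation model.

    Parameters
    ----------
    config : PipelineConfig, optional
        Full pipeline configuration; built from defaults when omitted.
    population_size, horizon_years, n_bootstrap : optional overrides of the
        most common settings.

    Examples
    --------
    >>> model = DementiaFrailtyModel(population_size=2000, horizon_years=12,
    ...                              n_bootstrap=10)
    >>> results = model.fit(seed=1)
    >>> print(results.summary())          # doctest: +SKIP
    """

    def __init__(
        self,
        config: PipelineConfig | None = None,
        population_size: int | None = None,
        horizon_years: int | None = None,
        n_bootstrap: int | None = None,
        **generator_overrides,
    ):
        if config is None:
            gen = GeneratorConfig(
                population_size=population_size or 20_000, **generator_overrides
            )
            config = PipelineConfig(generator=gen)
        else:
            if population_size is not None:
                config = replace(
                    config, generator=replace(config.generator, population_size=population_size)
                )
        if horizon_years is not None:
            config = replace(config, horizon_years=horizon_years)
        if n_bootstrap is not None:
            config = replace(config, n_bootstrap=n_bootstrap)
        self.config = config

    @classmethod
    def from_config(cls, path) -> "DementiaFrailtyModel":
        from .io import load_pipeline_config

        return cls(config=load_pipeline_config(path))

    def fit(self, n_iterations: int | None = None, seed: int = 0) -> "ProjectionResults":
        """Estimate models and run the bootstrap projection ensemble."""
        fitted = fit_models(self.config, seed)
        ensemble = bootstrap_run(
            self.config,
            n_iterations=n_iterations,
            master_seed=seed,
            fitted=fitted,
        )
        return ProjectionResults(self, fitted, ensemble, seed)


class ProjectionResults:
    """Fitted projection: ensembles, summaries, presentation tables."""

    def __init__(
        self,
        model: DementiaFrailtyModel,
        fitted: FittedModels,
        ensemble: ResultEnsemble,
        seed: int,
    ):
        self.model = model
        self.fitted = fitted
        self.ensemble = ensemble
        self.seed = seed
        self._summaries = ensemble.summary()

    @property
    def prevalence(self) -> pd.DataFrame:
        """Prevalence summary (counts/proportions with intervals)."""
        return self._summaries["prevalence"]

    @property
    def life_expectancy(self) -> pd.DataFrame:
        """Sullivan life-expectancy partition summary by year/sex/condition."""
        return self._summaries["life_expectancy"]

    @property
    def costs(self) -> pd.DataFrame:
        """Annual cost totals summary by year/component/condition group."""
        return self._summaries["costs_total"]

    @property
    def costs_per_capita(self) -> pd.DataFrame:
        return self._summaries["costs_per_capita"]

    @property
    def thresholds(self) -> pd.DataFrame:
        return self._summaries["thresholds"]

    def prevalence_table(self, years=None) -> pd.DataFrame:
        """Headline-style formatted prevalence table."""
        years = years if years is not None else self.model.config.presentation_years
        avail = set(self.prevalence["year"].unique())
        years = [y for y in years if y in avail]
        return build_prevalence_table(self.prevalence, years=years)

    def summary(self) -> str:
        """Formatted text report of the key projection quantities."""
        cfg = self.model.config
        lines = []
        push = lines.append
        push("Dementia-frailty microsimulation projection")
        push("=" * 60)
        push(
            f"baseline {cfg.generator.start_year}, n={cfg.generator.population_size}, "
            f"horizon {cfg.horizon_years} y, bootstrap n={self.ensemble.n_iterations}, "
            f"seed {self.seed}"
        )
        thr = self.thresholds.iloc[0]
        push(
            f"calibrated cutoffs: dementia {thr['theta_dementia_mean']:.4f}, "
            f"MCI {thr['theta_mci_mean']:.4f}, frailty {thr['theta_frail_mean']:.4f}"
        )
        push("")
        push("Prevalence, age >=60 (% of population; 5th-95th percentile):")
        prev = self.prevalence
        for cond in ("dementia", "mci", "frailty", "dementia_and_frailty"):
            for sex in ("female", "male"):
                part = prev[
                    (prev["condition"] == cond)
                    & (prev["sex"] == sex)
                    & (prev["age_group"] == "60plus")
                ].sort_values("year")
                vals = ", ".join(
                    f"{int(r.year)}: {r.proportion_pct_mean:.2f} "
                    f"({r.proportion_pct_p5:.2f}-{r.proportion_pct_p95:.2f})"
                    for r in part.itertuples()
                )
                push(f"  {cond:22s} {sex:6s} {vals}")
        push("")
        push("Life expectancy at 65 (years; with condition / total):")
        le = self.life_expectancy
        for cond in ("dementia", "frailty"):
            for sex in ("female", "male"):
                part = le[(le["condition"] == cond) & (le["sex"] == sex)].sort_values("year")
                vals = ", ".join(
                    f"{int(r.year)}: {r.years_with_mean:.1f}/{r.life_expectancy_mean:.1f}"
                    for r in part.itertuples()
                )
                push(f"  {cond:10s} {sex:6s} {vals}")
        push("")
        push("Annual cost totals (all components, simulated persons):")
        ct = self.costs
        all_rows = ct[ct["group"] == "all"]
        for year, part in all_rows.groupby("year"):
            total = part["total_mean"].sum()
            push(f"  {int(year)}: {total:,.0f} (2016 US$)")
        return "\n".join(lines)

    def plot_prevalence(self, condition: str = "dementia", ax=None):
        """Prevalence trajectory plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prev = self.prevalence
        for sex, style in (("female", "-o"), ("male", "--s")):
            part = prev[
                (prev["condition"] == condition)
                & (prev["sex"] == sex)
                & (prev["age_group"] == "60plus")
            ].sort_values("year")
            ax.plot(part["year"], part["proportion_pct_mean"], style, label=sex)
            ax.fill_between(
                part["year"],
                part["proportion_pct_p5"],
                part["proportion_pct_p95"],
                alpha=0.2,
            )
        ax.set_xlabel("year")
        ax.set_ylabel(f"{condition} prevalence, age >=60 (%)")
        ax.legend()
        return ax
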