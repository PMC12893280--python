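"""Posterior trends: mean derivatives of predicted log abundance.

A "trend" is the per-draw mean of successive difference quotients of the
predicted log abundance over a year grid,

    trend = mean[ (log a_t - log a_{t-1}) / (year_t - year_{t-1}) ],

reported on the log scale (Delta log abundance per year) and as percent per
year via 100 * (exp(trend) - 1).  For the linear predictors of this model
the derivative is grid-independent, but the machinery accepts arbitrary
strictly increasing grids (irregular grids are averaged unweighted, as the
estimand is written).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .draws import PosteriorDraws
from .threat_design import ThreatDesign, build_context_design

INTERVALS = (0.50, 0.80, 0.95)


@dataclass
class TrendPosterior:
    """Per-draw trend for one prediction context (a threat combination, a
    scenario, ...)."""

    trend: np.ndarray           # (n_draws,) Delta log abundance / year
    context: str = ""
    linear_percent: bool = False

    @property
    def percent_per_year(self) -> np.ndarray:
        if self.linear_percent:
            return 100.0 * self.trend
        return to_percent_per_year(self.trend)

    @property
    def median(self) -> float:
        return float(np.median(self.trend))

    def interval(self, level: float = 0.80) -> tuple[float, float]:
        lo, hi = np.quantile(self.trend, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    def summary(self, levels: Sequence[float] = INTERVALS) -> pd.DataFrame:
        row: dict[str, float | str] = {"context": self.context, "median": self.median}
        pct = self.percent_per_year
        row["median_percent"] = float(np.median(pct))
        for lev in levels:
            lo, hi = self.interval(lev)
            row[f"lo{int(lev * 100)}"] = lo
            row[f"hi{int(lev * 100)}"] = hi
        return pd.DataFrame([row])


def to_percent_per_year(trend: np.ndarray) -> np.ndarray:
    """Multiplicative percent change per year: 100 * (exp(trend) - 1)."""
    trend = np.asarray(trend, dtype=float)
    if not np.all(np.isfinite(trend)):
        raise ValueError("non-finite trend")
    return 100.0 * np.expm1(trend)


def predict_log_abundance(
    draws: PosteriorDraws,
    design: ThreatDesign,
    include_random: str = "none",
    model=None,
    identity: tuple[str, str, str] | None = None,
) -> np.ndarray:
    """Per-draw predicted log abundance for the rows of ``design``.

    ``include_random="none"`` gives conditional predictions (random effects
    zero).  ``"all"`` adds the across-population average random slope
    (marginal predictions; requires ``model`` for the grouping maps).  An
    explicit ``identity=(species_id, population_id, site_id)`` adds that
    identity's slopes.
    """
    pred = draws.beta_flat() @ design.matrix.T
    if include_random == "none" and identity is None:
        return pred

    if identity is not None:
        try:
            si = draws.species_ids.index(identity[0])
            pi = draws.population_ids.index(identity[1])
            li = draws.site_ids.index(identity[2])
        except ValueError as exc:
            raise KeyError(f"unknown identity {identity!r}") from exc
        slope = draws.r_species()[:, si] + draws.r_population()[:, pi] + draws.r_site()[:, li]
    elif include_random == "all":
        if model is None:
            raise ValueError("include_random='all' needs the model for grouping maps")
        slopes = (
            draws.r_species()[:, model.species_of_population]
            + draws.r_population()
            + draws.r_site()[:, model.site_of_population]
        )
        slope = slopes.mean(axis=1)
    else:
        raise ValueError(f"unknown include_random {include_random!r}")
    return pred + slope[:, None] * design.centered_year[None, :]


def trend_derivative(
    predicted: np.ndarray, years: np.ndarray, context: str = ""
) -> TrendPosterior:
    """Unweighted mean of successive difference quotients, per draw."""
    years = np.asarray(years, dtype=float)
    if years.size < 2:
        raise ValueError("need at least two years")
    dy = np.diff(years)
    if np.any(dy <= 0):
        raise ValueError("years must be strictly increasing (no duplicates)")
    predicted = np.atleast_2d(predicted)
    quotients = np.diff(predicted, axis=1) / dy[None, :]
    return TrendPosterior(trend=quotients.mean(axis=1), context=context)


def default_year_grid(model=None, half_width: int = 12) -> np.ndarray:
    """Unit-spaced integer grid of centered years for prediction contexts.

    With a model, spans the data's centered-year range; otherwise a
    symmetric grid of +/- ``half_width`` years."""
    if model is not None:
        lo = int(np.floor(model.centered_year.min()))
        hi = int(np.ceil(model.centered_year.max()))
        if hi <= lo:
            hi = lo + 1
        return np.arange(lo, hi + 1, dtype=float)
    return np.arange(-half_width, half_width + 1, dtype=float)


def context_trend(
    draws: PosteriorDraws,
    threats: frozenset[str] | set[str],
    years: np.ndarray | None = None,
    model=None,
    include_random: str = "none",
    design: ThreatDesign | None = None,
) -> TrendPosterior:
    """Trend posterior for a hypothetical population exposed to ``threats``."""
    if years is None:
        years = default_year_grid(model)
    if design is None:
        design = build_context_design(_labels_of(draws), frozenset(threats), years)
    pred = predict_log_abundance(draws, design, include_random=include_random, model=model)
    label = ".".join(sorted(threats)) if threats else "none"
    return trend_derivative(pred, years, context=label)


def _labels_of(draws: PosteriorDraws) -> list[str]:
    from .threat_design import INTERCEPT, YEAR, YEAR_SUFFIX

    return [
        l
        for l in draws.beta_labels
        if l not in (INTERCEPT, YEAR) and not l.endswith(YEAR_SUFFIX)
    ]


def population_trends(
    draws: PosteriorDraws,
    model,
    removal_set: frozenset[str] = frozenset(),
    include_random: bool = True,
    populations: Sequence[int] | None = None,
) -> np.ndarray:
    """(n_draws, n_populations) per-draw trends, one column per population.

    Each population is predicted on its own unit-spaced centered-year grid
    with its threat set; ``removal_set`` zeroes every design column involving
    a removed threat (via :func:`popthreat.threat_design.remove_threat`)
    before predicting.
    """
    from .threat_design import remove_threats

    if populations is None:
        populations = range(len(model.series))
    labels = model.labels
    cols = []
    r_s = draws.r_species() if include_random else None
    r_p = draws.r_population() if include_random else None
    r_l = draws.r_site() if include_random else None
    for j in populations:
        s = model.series[j]
        cy = model.prepared[j].centered_year
        span = max(int(np.ceil(cy.max() - cy.min())), 1)
        grid = np.arange(span + 1, dtype=float) - span / 2.0
        design = build_context_design(labels, s.threats, grid, s.population_id)
        if removal_set:
            design = remove_threats(design, removal_set)
        pred = draws.beta_flat() @ design.matrix.T
        if include_random:
            slope = (
                r_s[:, model.species_of_population[j]]
                + r_p[:, j]
                + r_l[:, model.site_of_population[j]]
            )
            pred = pred + slope[:, None] * grid[None, :]
        cols.append(trend_derivative(pred, grid).trend)
    return np.column_stack(cols)


@dataclass
class InfluenceDecomposition:
    """Null / random / fixed trend posteriors and their contribution
    distributions.

    ``null`` is the conditional no-threat trend (random effects zero);
    ``random`` adds all random-effect identities to the null threat matrix
    and averages across series (marginal); ``fixed`` sets every threat
    combination column to one (conditional).  A contribution distribution
    centered at zero means that component does not move the trend direction.
    """

    null: TrendPosterior
    random: TrendPosterior
    fixed: TrendPosterior
    random_minus_null: np.ndarray = field(repr=False, default=None)
    fixed_minus_null: np.ndarray = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        rows = [t.summary() for t in (self.null, self.random, self.fixed)]
        rows.append(
            TrendPosterior(self.random_minus_null, "random - null").summary()
        )
        rows.append(TrendPosterior(self.fixed_minus_null, "fixed - null").summary())
        return pd.concat(rows, ignore_index=True)


def influence_decomposition(
    draws: PosteriorDraws, model, years: np.ndarray | None = None
) -> InfluenceDecomposition:
    """Decompose trend contributions into random-effect and threat components."""
    if years is None:
        years = default_year_grid(model)
    null = context_trend(draws, frozenset(), years, model, include_random="none")
    null.context = "null (no threats, no random effects)"
    random = context_trend(draws, frozenset(), years, model, include_random="all")
    random.context = "random effects (marginal, no threats)"
    all_threats = frozenset().union(*[frozenset(l.split(".")) for l in model.labels]) if model.labels else frozenset()
    fixed = context_trend(draws, all_threats, years, model, include_random="none")
    fixed.context = "fixed effects (all threats on)"
    return InfluenceDecomposition(
        null=null,
        random=random,
        fixed=fixed,
        random_minus_null=random.trend - null.trend,
        fixed_minus_null=fixed.trend - null.trend,
    )


def trend_table(trends: Sequence[TrendPosterior]) -> pd.DataFrame:
    """Stacked summary table (context, median, 50/80/95% bounds, percent)."""
    return pd.concat([t.summary() for t in trends], ignore_index=True)
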