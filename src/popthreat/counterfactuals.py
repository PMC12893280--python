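"""Counterfactual threat-removal scenarios.

A scenario asks: what would the predicted trends of the *threatened*
populations have been had one or more threats been absent?  Following the
three-step procedure: (1) drop unthreatened populations; (2) zero every
design column involving a removed threat (interactions containing it
included); (3) re-estimate each population's trend under the modified
matrix and pool the per-population trends into a scenario distribution.

Baseline and counterfactual use the same posterior draws (paired
comparison), so Monte-Carlo noise cancels in differences and an empty
removal set reproduces the baseline bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import THREATS
from .draws import PosteriorDraws
from .trends import population_trends


@dataclass(frozen=True)
class RelativeChange:
    """Percent change of the counterfactual median relative to baseline:
    100 * (counterfactual - baseline) / |baseline|.  With a zero baseline the
    percent form is undefined and the absolute difference is reported with
    ``absolute_fallback=True``."""

    value: float
    absolute_fallback: bool = False


def relative_change(baseline_median: float, counterfactual_median: float) -> RelativeChange:
    if baseline_median == 0.0:
        return RelativeChange(counterfactual_median - baseline_median, absolute_fallback=True)
    return RelativeChange(
        100.0 * (counterfactual_median - baseline_median) / abs(baseline_median)
    )


@dataclass
class CounterfactualScenario:
    removal_set: frozenset[str]
    population_ids: tuple[str, ...]
    baseline_pop_trends: np.ndarray = field(repr=False)       # (n_pop,) per-pop medians
    counterfactual_pop_trends: np.ndarray = field(repr=False)
    baseline_draws: np.ndarray = field(repr=False)            # (n_draws, n_pop)
    counterfactual_draws: np.ndarray = field(repr=False)
    statistic: str = "median"

    @property
    def baseline_median(self) -> float:
        return float(np.median(self.baseline_pop_trends))

    @property
    def counterfactual_median(self) -> float:
        return float(np.median(self.counterfactual_pop_trends))

    @property
    def relative_change_percent(self) -> RelativeChange:
        return relative_change(self.baseline_median, self.counterfactual_median)

    def to_row(self) -> dict:
        rc = self.relative_change_percent
        return {
            "removal_set": "+".join(sorted(self.removal_set)) or "(none)",
            "baseline_median": self.baseline_median,
            "counterfactual_median": self.counterfactual_median,
            "relative_change_percent": rc.value,
            "absolute_fallback": rc.absolute_fallback,
        }


def run_counterfactual(
    draws: PosteriorDraws,
    model,
    removal_set: Iterable[str],
    include_random: bool = True,
    statistic: str = "median",
    _baseline_cache: np.ndarray | None = None,
) -> CounterfactualScenario:
    """Predict trends of the threatened populations with ``removal_set``
    threats removed from the design."""
    removal = frozenset(removal_set)
    unknown = removal - set(THREATS)
    if unknown:
        raise ValueError(f"unknown threat(s) in removal set: {sorted(unknown)}")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")

    threatened = [j for j, s in enumerate(model.series) if s.threats]
    if not threatened:
        raise ValueError("no threatened populations in the dataset")
    pop_ids = tuple(model.series[j].population_id for j in threatened)

    if _baseline_cache is None:
        baseline = population_trends(
            draws, model, frozenset(), include_random=include_random, populations=threatened
        )
    else:
        baseline = _baseline_cache
    if removal:
        counterfactual = population_trends(
            draws, model, removal, include_random=include_random, populations=threatened
        )
    else:
        counterfactual = baseline

    reduce = np.median if statistic == "median" else np.mean
    return CounterfactualScenario(
        removal_set=removal,
        population_ids=pop_ids,
        baseline_pop_trends=reduce(baseline, axis=0),
        counterfactual_pop_trends=reduce(counterfactual, axis=0),
        baseline_draws=baseline,
        counterfactual_draws=counterfactual,
        statistic=statistic,
    )


def scenario_grid(
    draws: PosteriorDraws,
    model,
    removal_sets: Sequence[Iterable[str]],
    include_random: bool = True,
    statistic: str = "median",
) -> tuple[list[CounterfactualScenario], pd.DataFrame]:
    """One scenario per removal set, with a shared baseline (paired draws)."""
    threatened = [j for j, s in enumerate(model.series) if s.threats]
    baseline = population_trends(
        draws, model, frozenset(), include_random=include_random, populations=threatened
    )
    scenarios = [
        run_counterfactual(
            draws,
            model,
            rs,
            include_random=include_random,
            statistic=statistic,
            _baseline_cache=baseline,
        )
        for rs in removal_sets
    ]
    table = pd.DataFrame([s.to_row() for s in scenarios]).sort_values(
        "relative_change_percent", ascending=False, ignore_index=True
    )
    return scenarios, table


def single_threat_grid(draws: PosteriorDraws, model, **kw):
    """The six single-threat removals plus the all-threats removal."""
    sets: list[set[str]] = [{t} for t in THREATS] + [set(THREATS)]
    return scenario_grid(draws, model, sets, **kw)
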