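"""Results object: posterior draws plus every downstream analysis."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .counterfactuals import (
    CounterfactualScenario,
    run_counterfactual,
    scenario_grid,
    single_threat_grid,
)
from .diagnostics import (
    ConvergenceReport,
    PosteriorPredictiveReport,
    diagnostics,
    posterior_predictive,
)
from .draws import PosteriorDraws
from .interactions import (
    InteractionVerdict,
    classify_interaction,
    sensitivity_scan,
    summarize_classes,
)
from .trends import (
    InfluenceDecomposition,
    TrendPosterior,
    context_trend,
    influence_decomposition,
    trend_table,
)


class ThreatTrendResults:
    """Fitted posterior of a :class:`~popthreat.model.ThreatTrendModel`.

    Wraps the :class:`PosteriorDraws` and exposes trends, interaction
    verdicts, influence decomposition and counterfactual scenarios, all
    computed from the same draws.
    """

    def __init__(self, model, draws: PosteriorDraws, spec) -> None:
        self.model = model
        self.draws = draws
        self.spec = spec

    # ------------------------------------------------------------- summaries
    def summary(self, level: float = 0.90) -> pd.DataFrame:
        """Posterior medians and equal-tailed intervals for hyperparameters
        and fixed effects, with split-Rhat and bulk ESS."""
        report = self.diagnostics().table.set_index("parameter")
        q = [(1 - level) / 2, 0.5, (1 + level) / 2]
        rows = []
        hypers = ("sigma", "rho", "sigma_species", "sigma_population", "sigma_site")
        for name in hypers:
            lo, med, hi = np.quantile(self.draws.hyper_flat(name), q)
            rows.append({"parameter": name, "median": med, "lo": lo, "hi": hi})
        for j, label in enumerate(self.draws.beta_labels):
            lo, med, hi = np.quantile(self.draws.beta_flat()[:, j], q)
            rows.append({"parameter": f"beta[{label}]", "median": med, "lo": lo, "hi": hi})
        out = pd.DataFrame(rows).set_index("parameter")
        out = out.join(report[["rhat", "ess_bulk"]])
        return out.reset_index()

    def diagnostics(self) -> ConvergenceReport:
        return diagnostics(self.draws)

    def posterior_predictive(self, n_rep: int = 200, seed: int = 0) -> PosteriorPredictiveReport:
        return posterior_predictive(self.draws, self.model, n_rep=n_rep, seed=seed)

    # ----------------------------------------------------------------- trends
    def trend(
        self,
        threats: Iterable[str] = (),
        include_random: str = "none",
        years: np.ndarray | None = None,
    ) -> TrendPosterior:
        """Conditional (or marginal) trend posterior for a threat context."""
        return context_trend(
            self.draws,
            frozenset(threats),
            years=years,
            model=self.model,
            include_random=include_random,
        )

    def trend_table(self, contexts: Sequence[Iterable[str]] | None = None) -> pd.DataFrame:
        if contexts is None:
            contexts = [frozenset()] + [
                frozenset(l.split(".")) for l in self.model.labels
            ]
        return trend_table([self.trend(c) for c in contexts])

    def influence_decomposition(self) -> InfluenceDecomposition:
        return influence_decomposition(self.draws, self.model)

    # ----------------------------------------------------------- interactions
    def interaction_labels(self) -> list[str]:
        return [l for l in self.model.labels if "." in l]

    def classify_interaction(self, combo: str, ci_level: float = 0.80) -> InteractionVerdict:
        return classify_interaction(
            self.draws, combo, ci_level=ci_level, model=self.model, labels=self.model.labels
        )

    def sensitivity_scan(self, combo: str, ci_levels: Iterable[float] = (0.5, 0.8, 0.95)):
        return sensitivity_scan(
            self.draws, combo, ci_levels, model=self.model, labels=self.model.labels
        )

    def classify_all_interactions(self, ci_level: float = 0.80) -> list[InteractionVerdict]:
        return [self.classify_interaction(c, ci_level) for c in self.interaction_labels()]

    def interaction_class_shares(
        self, ci_level: float = 0.80, weighting: str = "combination"
    ) -> pd.DataFrame:
        return summarize_classes(self.classify_all_interactions(ci_level), weighting)

    # --------------------------------------------------------- counterfactuals
    def counterfactual(
        self, removal_set: Iterable[str], include_random: bool = True
    ) -> CounterfactualScenario:
        return run_counterfactual(
            self.draws, self.model, removal_set, include_random=include_random
        )

    def scenario_grid(self, removal_sets: Sequence[Iterable[str]], **kw):
        return scenario_grid(self.draws, self.model, removal_sets, **kw)

    def single_threat_scenarios(self, **kw):
        return single_threat_grid(self.draws, self.model, **kw)

    # ------------------------------------------------------------------- misc
    def recovery_report(self, truth, level: float = 0.90):
        from .simulate import recovery_report

        return recovery_report(truth, self.draws, level=level)

    def save(self, path) -> None:
        self.draws.to_json(path)
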