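"""Additive / antagonistic / synergistic classification of threat interactions.

For a multi-threat combination the model provides two conditional trend
posteriors: the *interactive* prediction (all interaction columns of the
combination active) and the *additive* prediction (the same context with
every statistical interaction among the combination's members turned off, so
only the single-threat effects contribute).  Differencing the two per draw
gives the interaction posterior:

* 80% credible interval (default) straddles zero  -> additive;
* entirely negative (interaction worsens the trend) -> synergistic;
* entirely positive                                  -> antagonistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _combos
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .draws import PosteriorDraws
from .threat_design import build_context_design, combo_label, label_threats, switch_interactions
from .trends import default_year_grid, predict_log_abundance, trend_derivative

VERDICTS = ("additive", "antagonistic", "synergistic")


@dataclass
class InteractionVerdict:
    combo: str
    median: float
    ci_low: float
    ci_high: float
    ci_level: float
    verdict: str
    prob_negative: float
    difference: np.ndarray = field(repr=False, default=None)

    def to_row(self) -> dict:
        return {
            "combo": self.combo,
            "median": self.median,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "verdict": self.verdict,
        }


def interaction_difference(
    draws: PosteriorDraws,
    combo: str,
    years: np.ndarray | None = None,
    model=None,
    labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-draw (interactive - additive) trend difference for ``combo``."""
    threats = label_threats(combo)
    if len(threats) < 2:
        raise ValueError(f"{combo!r} is not an interaction label")
    if labels is None:
        from .trends import _labels_of

        labels = _labels_of(draws)
    canon = combo_label(threats)
    if canon not in labels:
        raise ValueError(f"interaction {canon!r} not present in the design")
    if years is None:
        years = default_year_grid(model)

    interactive = build_context_design(labels, threats, years)
    additive = interactive
    for k in range(2, len(threats) + 1):
        for sub in _combos(sorted(threats), k):
            lab = combo_label(sub)
            if lab in labels:
                additive = switch_interactions(additive, lab, "off")

    t_int = trend_derivative(predict_log_abundance(draws, interactive), years).trend
    t_add = trend_derivative(predict_log_abundance(draws, additive), years).trend
    return t_int - t_add


def classify_difference(diff: np.ndarray, combo: str, ci_level: float = 0.80) -> InteractionVerdict:
    """Equal-tailed-interval verdict on a difference posterior."""
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    lo, hi = np.quantile(diff, [(1 - ci_level) / 2, (1 + ci_level) / 2])
    if hi < 0.0:
        verdict = "synergistic"
    elif lo > 0.0:
        verdict = "antagonistic"
    else:
        verdict = "additive"
    return InteractionVerdict(
        combo=combo,
        median=float(np.median(diff)),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        verdict=verdict,
        prob_negative=float(np.mean(diff < 0.0)),
        difference=diff,
    )


def classify_interaction(
    draws: PosteriorDraws,
    combo: str,
    ci_level: float = 0.80,
    years: np.ndarray | None = None,
    model=None,
    labels: Sequence[str] | None = None,
) -> InteractionVerdict:
    """Classify one multi-threat combination from fitted draws."""
    diff = interaction_difference(draws, combo, years=years, model=model, labels=labels)
    return classify_difference(diff, combo_label(label_threats(combo)), ci_level)


def sensitivity_scan(
    draws: PosteriorDraws,
    combo: str,
    ci_levels: Iterable[float],
    years: np.ndarray | None = None,
    model=None,
    labels: Sequence[str] | None = None,
) -> dict[float, InteractionVerdict]:
    """Verdicts across CI levels.  Nested equal-tailed intervals make the
    classification monotone: non-additive at level c implies non-additive at
    every smaller level."""
    diff = interaction_difference(draws, combo, years=years, model=model, labels=labels)
    return {
        lev: classify_difference(diff, combo_label(label_threats(combo)), lev)
        for lev in sorted(ci_levels)
    }


def summarize_classes(
    verdicts: Sequence[InteractionVerdict],
    weighting: str = "combination",
) -> pd.DataFrame:
    """Per-threat percentages of additive / antagonistic / synergistic.

    ``weighting="combination"``: each combination involving the threat casts
    one vote for its verdict class.  ``weighting="draw"``: a combination with
    a non-additive verdict contributes fractional mass equal to the posterior
    probability of its verdict's direction, the remainder counting as
    additive (a certainty-weighted aggregation producing fractional
    percentages).  Threats with no classified interaction are omitted.
    """
    if weighting not in ("combination", "draw"):
        raise ValueError("weighting must be 'combination' or 'draw'")
    buckets: dict[str, dict[str, float]] = {}
    for v in verdicts:
        for threat in label_threats(v.combo):
            b = buckets.setdefault(threat, {k: 0.0 for k in VERDICTS})
            if weighting == "combination":
                b[v.verdict] += 1.0
            else:
                if v.verdict == "synergistic":
                    mass = v.prob_negative
                elif v.verdict == "antagonistic":
                    mass = 1.0 - v.prob_negative
                else:
                    mass = 0.0
                if v.verdict != "additive":
                    b[v.verdict] += mass
                    b["additive"] += 1.0 - mass
                else:
                    b["additive"] += 1.0
    rows = []
    for threat in sorted(buckets):
        b = buckets[threat]
        total = sum(b.values())
        rows.append(
            {
                "threat": threat,
                "n_combinations": int(round(total)),
                **{f"{k}_percent": 100.0 * b[k] / total for k in VERDICTS},
            }
        )
    return pd.DataFrame(rows)


def verdict_table(verdicts: Sequence[InteractionVerdict]) -> pd.DataFrame:
    return pd.DataFrame([v.to_row() for v in verdicts])
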