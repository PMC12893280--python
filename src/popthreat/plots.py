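"""Figure helpers (matplotlib)."""

from __future__ import annotations

from typing import Sequence

import numpy as np


def plot_interaction_posteriors(results, combo: str, ci_level: float = 0.80, ax=None):
    """Additive, interactive and difference trend posteriors for one
    combination (density sketches, interval shading on the difference)."""
    import matplotlib.pyplot as plt

    from .interactions import classify_difference
    from .threat_design import label_threats, switch_interactions, build_context_design
    from .trends import default_year_grid, predict_log_abundance, trend_derivative
    from itertools import combinations as _combos
    from .threat_design import combo_label

    threats = label_threats(combo)
    years = default_year_grid(results.model)
    labels = list(results.model.labels)
    interactive = build_context_design(labels, threats, years)
    additive = interactive
    for k in range(2, len(threats) + 1):
        for sub in _combos(sorted(threats), k):
            lab = combo_label(sub)
            if lab in labels:
                additive = switch_interactions(additive, lab, "off")
    t_int = trend_derivative(predict_log_abundance(results.draws, interactive), years).trend
    t_add = trend_derivative(predict_log_abundance(results.draws, additive), years).trend
    verdict = classify_difference(t_int - t_add, combo, ci_level)

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, arr in (("additive", t_add), ("interactive", t_int), ("difference", t_int - t_add)):
        xs = np.linspace(arr.min(), arr.max(), 200)
        from scipy.stats import gaussian_kde

        ax.plot(xs, gaussian_kde(arr)(xs), label=name)
    ax.axvline(0.0, color="gray", lw=0.8)
    ax.axvspan(verdict.ci_low, verdict.ci_high, alpha=0.15)
    ax.set_xlabel("trend (Δ log abundance / year)")
    ax.set_title(f"{combo}: {verdict.verdict}")
    ax.legend(frameon=False)
    return ax


def plot_counterfactual_scenarios(scenarios: Sequence, ax=None):
    """Box plots of per-population trend distributions per removal scenario."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    data = [s.counterfactual_pop_trends for s in scenarios]
    labels = ["+".join(sorted(s.removal_set)) or "(none)" for s in scenarios]
    ax.boxplot(data, tick_labels=labels)
    baseline = scenarios[0].baseline_median if scenarios else 0.0
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.axhline(baseline, color="gray", ls="--", lw=0.8)
    ax.set_ylabel("population trend (Δ log abundance / year)")
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    return ax
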