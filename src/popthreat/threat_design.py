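"""Binary threat-combination design matrices with toggle / removal semantics.

Threat exposure enters the trend model as a bank of binary indicator columns:
one column per observed threat combination (singles such as ``disease``,
interactions such as ``disease.exploitation``), each paired with a year
interaction twin (indicator times centered year) that carries the
combination's trend moderation.  A combination indicator is 1 for an
observation exactly when the combination is a subset of the population's
threat set, which makes every interaction indicator the elementwise product
of its constituent single indicators.

Two structural edits drive the downstream analyses:

* ``switch_interactions`` turns one interaction column (and its year twin)
  off/on — the additive prediction of the interaction classifier is the
  design with the statistical interaction turned off;
* ``remove_threat`` zeroes every column whose combination contains a given
  threat — the counterfactual scenarios are built from these removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _combos
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import THREATS, PreparedSeries

INTERCEPT = "intercept"
YEAR = "year"
YEAR_SUFFIX = "·year"  # "·year"


def combo_label(threats: Iterable[str]) -> str:
    """Canonical label of a combination: members alphabetical, joined by '.'."""
    return ".".join(sorted(threats))


def label_threats(label: str) -> frozenset[str]:
    return frozenset(label.split("."))


def enumerate_combinations(
    threat_sets: Iterable[frozenset[str] | set[str]],
    max_order: int = 3,
    observed_only: bool = True,
    categories: Sequence[str] = THREATS,
) -> list[str]:
    """Canonically ordered combination labels for a collection of threat sets.

    With ``observed_only`` (default), the labels are the combinations present
    in the data plus all sub-combinations of observed multi-threat sets, so
    that every interaction has its constituent singles available.  With
    ``observed_only=False``, all combinations of the six categories up to
    ``max_order`` are returned (41 for six categories and order 3).

    Order: by combination size, then alphabetically.
    """
    threat_sets = [frozenset(ts) for ts in threat_sets]
    for ts in threat_sets:
        if len(ts) > max_order:
            raise ValueError(f"threat set {sorted(ts)} exceeds max_order={max_order}")
        unknown = ts - set(categories)
        if unknown:
            raise ValueError(f"unknown threat(s) {sorted(unknown)}")
    if observed_only:
        labels: set[frozenset[str]] = set()
        for ts in threat_sets:
            for k in range(1, len(ts) + 1):
                labels.update(frozenset(c) for c in _combos(sorted(ts), k))
    else:
        labels = {
            frozenset(c)
            for k in range(1, max_order + 1)
            for c in _combos(sorted(categories), k)
        }
    return sorted((combo_label(s) for s in labels), key=lambda l: (l.count(".") + 1, l))


def count_fixed_effects(labels: Sequence[str], crossing_levels: int = 1) -> int:
    """Number of fixed-effect coefficients: (intercept + year + 2 per
    combination), times the number of levels of a fully crossed factor."""
    if crossing_levels < 1:
        raise ValueError("crossing_levels must be >= 1")
    return (2 + 2 * len(labels)) * crossing_levels


@dataclass(frozen=True)
class ThreatDesign:
    """A realized fixed-effect model matrix over observations.

    ``column_labels`` is ``[intercept, year, c1, c1·year, c2, c2·year, ...]``.
    ``row_threats`` keeps each row's *original* threat set so interaction
    columns can be reconstructed by the product rule after an off-toggle.
    """

    column_labels: tuple[str, ...]
    matrix: np.ndarray
    row_threats: tuple[frozenset[str], ...]
    centered_year: np.ndarray
    row_population: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.row_threats), len(self.column_labels)):
            raise ValueError("matrix shape does not match labels/rows")

    @property
    def combo_labels(self) -> tuple[str, ...]:
        return tuple(
            l for l in self.column_labels
            if l not in (INTERCEPT, YEAR) and not l.endswith(YEAR_SUFFIX)
        )

    def column_index(self, label: str) -> int:
        try:
            return self.column_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown design column {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.column_labels))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _indicator(combo: frozenset[str], row_threats: Sequence[frozenset[str]]) -> np.ndarray:
    return np.array([float(combo <= ts) for ts in row_threats])


def build_design(
    prepared: Sequence[PreparedSeries],
    threats_per_series: Sequence[frozenset[str] | set[str]],
    labels: Sequence[str],
    populations: Sequence[str] | None = None,
) -> ThreatDesign:
    """Assemble the observation-level design matrix.

    Rows are the concatenated observations of ``prepared`` (one block per
    series, years ascending).  Every combination indicator follows the subset
    rule; its year twin is the indicator times the centered year.
    """
    if len(prepared) != len(threats_per_series):
        raise ValueError("prepared series and threat sets differ in length")
    threat_sets = [frozenset(ts) for ts in threats_per_series]
    label_sets = {label_threats(l) for l in labels}
    for ts in threat_sets:
        if ts and ts not in label_sets:
            raise ValueError(f"threat set {sorted(ts)} has no matching label")

    cyear = np.concatenate([p.centered_year for p in prepared]) if prepared else np.empty(0)
    row_threats: list[frozenset[str]] = []
    row_pop: list[str] = []
    for p, ts in zip(prepared, threat_sets):
        row_threats.extend([ts] * len(p.centered_year))
        row_pop.extend([p.population_id] * len(p.centered_year))

    return _assemble(labels, row_threats, cyear, tuple(row_pop))


def build_context_design(
    labels: Sequence[str],
    threats: frozenset[str] | set[str],
    centered_years: np.ndarray,
    population_id: str = "<context>",
) -> ThreatDesign:
    """Design rows for a hypothetical population exposed to ``threats`` over a
    year grid — the prediction contexts used by the trend and interaction
    analyses."""
    threats = frozenset(threats)
    cyear = np.asarray(centered_years, dtype=float)
    return _assemble(
        labels, [threats] * cyear.size, cyear, tuple([population_id] * cyear.size)
    )


def _assemble(labels, row_threats, cyear, row_pop) -> ThreatDesign:
    cols = [np.ones(cyear.size), cyear]
    names: list[str] = [INTERCEPT, YEAR]
    for label in labels:
        ind = _indicator(label_threats(label), row_threats)
        cols.append(ind)
        cols.append(ind * cyear)
        names.extend([label, label + YEAR_SUFFIX])
    matrix = np.column_stack(cols) if cyear.size else np.empty((0, len(names)))
    return ThreatDesign(tuple(names), matrix, tuple(row_threats), cyear, row_pop)


def switch_interactions(d: ThreatDesign, combo: str, state: str) -> ThreatDesign:
    """Return a copy with one interaction column toggled ``"on"`` or ``"off"``.

    ``on`` restores the product rule from the rows' original threat sets;
    ``off`` zeroes the indicator and its year twin.  All other columns are
    untouched.
    """
    if "." not in combo:
        raise ValueError(f"{combo!r} is not an interaction label")
    if state not in ("on", "off"):
        raise ValueError("state must be 'on' or 'off'")
    j = d.column_index(combo)
    jy = d.column_index(combo + YEAR_SUFFIX)
    matrix = d.matrix.copy()
    if state == "on":
        ind = _indicator(label_threats(combo), d.row_threats)
        matrix[:, j] = ind
        matrix[:, jy] = ind * d.centered_year
    else:
        matrix[:, j] = 0.0
        matrix[:, jy] = 0.0
    return ThreatDesign(d.column_labels, matrix, d.row_threats, d.centered_year, d.row_population)


def remove_threat(d: ThreatDesign, threat: str) -> ThreatDesign:
    """Zero every combination column (and year twin) whose label contains
    ``threat`` — the single-threat removal step of the counterfactuals."""
    if threat not in THREATS:
        raise ValueError(f"unknown threat {threat!r}")
    matrix = d.matrix.copy()
    for label in d.combo_labels:
        if threat in label_threats(label):
            matrix[:, d.column_index(label)] = 0.0
            matrix[:, d.column_index(label + YEAR_SUFFIX)] = 0.0
    return ThreatDesign(d.column_labels, matrix, d.row_threats, d.centered_year, d.row_population)


def remove_threats(d: ThreatDesign, threats: Iterable[str]) -> ThreatDesign:
    for t in sorted(threats):
        d = remove_threat(d, t)
    return d
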