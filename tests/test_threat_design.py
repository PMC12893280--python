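import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popthreat.data_io import THREATS, PreparedSeries
from popthreat.threat_design import (
    YEAR_SUFFIX,
    build_context_design,
    build_design,
    combo_label,
    count_fixed_effects,
    enumerate_combinations,
    label_threats,
    remove_threat,
    remove_threats,
    switch_interactions,
)

FOUR = ("climate_change", "disease", "exploitation", "pollution")


def _subsets(cats, max_order=3, include_empty=True):
    from itertools import combinations

    out = [frozenset()] if include_empty else []
    for k in range(1, max_order + 1):
        out.extend(frozenset(c) for c in combinations(cats, k))
    return out


def _prepared(threat_sets, n_obs=3):
    prepared = [
        PreparedSeries(
            f"p{i}",
            np.arange(n_obs) - (n_obs - 1) / 2,
            np.zeros(n_obs),
        )
        for i in range(len(threat_sets))
    ]
    return prepared


class TestEnumerateCombinations:
    def test_ordering_singles_before_pairs(self):
        sets = [{"exploitation"}, {"disease"}, {"exploitation", "disease"}]
        assert enumerate_combinations(sets) == [
            "disease",
            "exploitation",
            "disease.exploitation",
        ]

    def test_full_enumeration_counts(self):
        # C(6,1) + C(6,2) + C(6,3) = 6 + 15 + 20
        assert len(enumerate_combinations([], observed_only=False)) == 41

    def test_subcombinations_of_observed_triples(self):
        labels = enumerate_combinations([{"disease", "pollution", "invasive"}])
        assert "disease.pollution" in labels
        assert "disease" in labels
        assert len(labels) == 7

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            enumerate_combinations([set(THREATS[:4])], max_order=3)


class TestCountFixedEffects:
    @pytest.mark.parametrize(
        "n_labels, crossing, expected",
        [(36, 1, 74), (36, 5, 370), (0, 1, 2)],
    )
    def test_counts(self, n_labels, crossing, expected):
        labels = [f"t{i}" for i in range(n_labels)]
        assert count_fixed_effects(labels, crossing) == expected


class TestBuildDesign:
    def test_worked_example_row(self):
        """A population under exploitation+disease activates both singles and
        their interaction, and nothing involving pollution."""
        sets = _subsets(("disease", "exploitation", "pollution"), include_empty=False)
        labels = enumerate_combinations(sets)
        design = build_design(_prepared([{"disease", "exploitation"}]), [{"disease", "exploitation"}], labels)
        row = design.matrix[0]

        def col(label):
            return row[design.column_index(label)]

        assert col("exploitation") == 1 and col("disease") == 1
        assert col("disease.exploitation") == 1
        assert col("pollution") == 0
        assert col("exploitation.pollution") == 0
        assert col("disease.pollution") == 0
        assert col("disease.exploitation.pollution") == 0

    def test_no_threat_baseline_rows_are_zero(self):
        labels = enumerate_combinations([{"disease"}])
        design = build_design(_prepared([set()]), [set()], labels)
        assert np.all(design.matrix[:, 2:] == 0.0)
        assert np.all(design.matrix[:, 0] == 1.0)

    def test_interaction_is_product_of_singles(self, ):
        sets = [{"disease", "pollution"}, {"disease"}, {"pollution"}, set()]
        labels = enumerate_combinations(sets)
        design = build_design(_prepared(sets), sets, labels)
        d = design.matrix[:, design.column_index("disease")]
        p = design.matrix[:, design.column_index("pollution")]
        dp = design.matrix[:, design.column_index("disease.pollution")]
        assert np.array_equal(dp, d * p)

    def test_unlabelled_threat_set_rejected(self):
        with pytest.raises(ValueError, match="invasive"):
            build_design(_prepared([{"invasive"}]), [{"invasive"}], ["disease"])


def brute_force_design(threat_sets, labels, centered_years):
    """Independent construction: every column by direct set membership and
    elementwise products, row by row."""
    rows = []
    for ts, cy in zip(threat_sets, centered_years):
        for t in cy:
            row = [1.0, t]
            for label in labels:
                members = label.split(".")
                ind = 1.0
                for m in members:
                    ind *= 1.0 if m in ts else 0.0
                row.extend([ind, ind * t])
            rows.append(row)
    return np.array(rows)


class TestDesignOracle:
    def test_matches_brute_force_on_all_sets_of_four_categories(self):
        sets = _subsets(FOUR, max_order=3)
        labels = enumerate_combinations(sets, categories=FOUR, observed_only=False)
        assert len(labels) == 4 + 6 + 4
        prepared = _prepared(sets, n_obs=4)
        design = build_design(prepared, sets, labels)
        expected = brute_force_design(
            sets, labels, [p.centered_year for p in prepared]
        )
        assert np.array_equal(design.matrix, expected)


class TestSwitchInteractions:
    @pytest.fixture
    def pair_design(self):
        sets = [{"disease", "exploitation"}, {"disease"}, set()]
        labels = enumerate_combinations(sets)
        return build_design(_prepared(sets), sets, labels)

    def test_off_zeroes_indicator_and_year_twin(self, pair_design):
        off = switch_interactions(pair_design, "disease.exploitation", "off")
        j = off.column_index("disease.exploitation")
        jy = off.column_index("disease.exploitation" + YEAR_SUFFIX)
        assert np.all(off.matrix[:, j] == 0) and np.all(off.matrix[:, jy] == 0)
        others = [
            k for k in range(off.matrix.shape[1]) if k not in (j, jy)
        ]
        assert np.array_equal(off.matrix[:, others], pair_design.matrix[:, others])

    def test_on_after_off_restores_bit_exactly(self, pair_design):
        off = switch_interactions(pair_design, "disease.exploitation", "off")
        on = switch_interactions(off, "disease.exploitation", "on")
        assert np.array_equal(on.matrix, pair_design.matrix)

    def test_absent_combo_toggle_is_noop(self, pair_design):
        # the pair column exists but a different interaction has no support
        sets = [{"disease"}, {"pollution"}]
        labels = ["disease", "pollution", "disease.pollution"]
        d = build_design(_prepared(sets), sets, labels)
        off = switch_interactions(d, "disease.pollution", "off")
        assert np.array_equal(off.matrix, d.matrix)

    def test_single_label_rejected(self, pair_design):
        with pytest.raises(ValueError):
            switch_interactions(pair_design, "disease", "off")


class TestRemoveThreat:
    @pytest.fixture
    def design(self):
        sets = [{"disease", "exploitation"}, {"disease"}, {"exploitation"}, set()]
        labels = enumerate_combinations(sets)
        return build_design(_prepared(sets), sets, labels)

    def test_removal_zeroes_threat_and_its_interactions(self, design):
        out = remove_threat(design, "exploitation")
        row = out.matrix[0]  # population with disease+exploitation
        assert row[out.column_index("exploitation")] == 0
        assert row[out.column_index("disease.exploitation")] == 0
        assert row[out.column_index("disease")] == 1

    def test_removal_is_idempotent(self, design):
        once = remove_threat(design, "exploitation")
        twice = remove_threat(once, "exploitation")
        assert np.array_equal(once.matrix, twice.matrix)

    def test_removal_order_commutes(self, design):
        ab = remove_threat(remove_threat(design, "disease"), "exploitation")
        ba = remove_threat(remove_threat(design, "exploitation"), "disease")
        assert np.array_equal(ab.matrix, ba.matrix)

    def test_absent_threat_removal_is_noop(self, design):
        out = remove_threat(design, "invasive")
        assert np.array_equal(out.matrix, design.matrix)

    def test_removing_all_threats_zeroes_all_combination_columns(self, design):
        out = remove_threats(design, THREATS)
        assert np.all(out.matrix[:, 2:] == 0.0)

    def test_unknown_threat_rejected(self, design):
        with pytest.raises(ValueError):
            remove_threat(design, "asteroids")


@given(
    data=st.data(),
    n_sets=st.integers(1, 6),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_property_design_matches_brute_force(data, n_sets):
    cats = FOUR
    sets = [
        frozenset(
            data.draw(
                st.sets(st.sampled_from(cats), max_size=3), label=f"set{i}"
            )
        )
        for i in range(n_sets)
    ]
    labels = enumerate_combinations(sets)
    prepared = _prepared(sets, n_obs=3)
    design = build_design(prepared, sets, labels)
    expected = brute_force_design(sets, labels, [p.centered_year for p in prepared])
    assert np.array_equal(design.matrix, expected)
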