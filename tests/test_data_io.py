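import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popthreat.data_io import (
    DataFormatError,
    PopulationSeries,
    RecordError,
    UnusableSeriesError,
    filter_series,
    prepare_series,
    read_lpd_table,
    write_lpd_table,
)

HEADER = (
    "population_id,species_id,latitude,longitude,system,taxon,"
    "climate_change,disease,exploitation,habitat_loss,invasive,pollution"
)


def _write(tmp_path, rows, years):
    path = tmp_path / "lpd.csv"
    head = HEADER + "," + ",".join(str(y) for y in years)
    path.write_text("\n".join([head] + rows) + "\n")
    return path


class TestReadLpdTable:
    def test_row_count_and_missing_cells(self, tmp_path):
        years = list(range(2000, 2011))
        meta = "S1,3.2,10.1,marine,fish,0,0,1,0,0,0"
        p2_cells = ["5", "", "", "", "4", "4", "", "", "", "", ""]  # 2000, 2004, 2005
        rows = [
            f"p1,{meta}," + ",".join("5" for _ in years),
            f"p2,{meta}," + ",".join(p2_cells),
            f"p3,{meta}," + ",".join(str(i + 1) for i in range(len(years))),
        ]
        series = read_lpd_table(_write(tmp_path, rows, years))
        assert len(series) == 3
        assert all(s.n_observations <= 11 for s in series)
        assert series[1].n_observations == 3
        assert series[1].years.tolist() == [2000, 2004, 2005]

    def test_threat_flags_parse_to_set(self, tmp_path):
        years = [2000, 2001]
        rows = ["p1,S1,0,0,marine,fish,0,1,1,0,0,0,2,3"]
        (s,) = read_lpd_table(_write(tmp_path, rows, years))
        assert s.threats == {"exploitation", "disease"}

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("population_id,species_id,2000\np1,S1,4\n")
        with pytest.raises(DataFormatError, match="latitude"):
            read_lpd_table(path)

    def test_unparseable_abundance_names_row(self, tmp_path):
        rows = ["p9,S1,0,0,marine,fish,0,0,0,0,0,0,oops"]
        with pytest.raises(RecordError, match="p9"):
            read_lpd_table(_write(tmp_path, rows, [2000]))

    def test_round_trip_preserves_observations(self, tmp_path, toy_series):
        orig = [
            toy_series("a", [2000, 2002, 2005], [1.0, 2.0, 3.0], {"disease"}),
            toy_series("b", [1990, 1995], [7.5, 8.5]),
        ]
        path = tmp_path / "rt.csv"
        write_lpd_table(orig, path)
        back = read_lpd_table(path)
        assert [(s.population_id, tuple(s.observations)) for s in back] == [
            (s.population_id, tuple(s.observations)) for s in orig
        ]
        assert back[0].threats == {"disease"}


class TestFilterSeries:
    def test_paper_thresholds(self, toy_series):
        ten_span = toy_series("keep", [1990, 1992, 1994, 1997, 1999], [1, 2, 3, 4, 5])
        nine_span = toy_series("drop_span", list(range(1990, 1999)), [1] * 9)
        few_points = toy_series("drop_pts", [1990, 1995, 2000, 2004], [1, 2, 3, 4])
        kept = filter_series([ten_span, nine_span, few_points])
        assert [s.population_id for s in kept] == ["keep"]

    def test_threat_status_requirement(self, toy_series):
        s = toy_series("u", [1990, 1999, 2000, 2001, 2002], [1, 2, 3, 4, 5])
        unknown = PopulationSeries(
            **{**s.__dict__, "population_id": "unk", "threat_status_known": False}
        )
        assert filter_series([s, unknown]) == [s]
        assert len(filter_series([s, unknown], require_threat_status=False)) == 2

    @given(
        spans=st.lists(
            st.tuples(st.integers(1, 30), st.integers(2, 40)), min_size=0, max_size=12
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_filtering_is_idempotent(self, spans):
        from popthreat.data_io import PopulationSeries

        series = []
        for i, (span, pts) in enumerate(spans):
            years = sorted(set(np.linspace(1990, 1990 + span - 1, pts, dtype=int)))
            if len(years) < 2:
                continue
            series.append(
                PopulationSeries(
                    population_id=f"p{i}",
                    species_id="S",
                    site=(0.0, 0.0),
                    system="marine",
                    taxon="fish",
                    observations=tuple((y, 1.0) for y in years),
                )
            )
        once = filter_series(series)
        assert filter_series(once) == once


class TestPrepareSeries:
    def test_constant_series_centers_to_zero(self, toy_series):
        p = prepare_series(toy_series("c", [2000, 2001, 2002], [10, 10, 10]))
        assert np.allclose(p.centered_log_abundance, 0.0)

    def test_year_centering(self, toy_series):
        p = prepare_series(toy_series("y", list(range(2000, 2005)), [1, 2, 3, 4, 5]))
        assert p.centered_year.tolist() == [-2, -1, 0, 1, 2]

    def test_zero_offset_policy(self, toy_series):
        p = prepare_series(toy_series("z", [2000, 2001, 2002], [0.0, 4.0, 8.0]))
        assert p.offset_applied == pytest.approx(0.04)
        logs = np.log(np.array([0.04, 4.04, 8.04]))
        assert np.allclose(p.centered_log_abundance, logs - logs.mean())

    def test_positive_series_gets_no_offset(self, toy_series):
        p = prepare_series(toy_series("p", [2000, 2001], [3.0, 4.0]))
        assert p.offset_applied == 0.0

    def test_all_zero_series_rejected(self, toy_series):
        with pytest.raises(UnusableSeriesError):
            prepare_series(toy_series("z0", [2000, 2001], [0.0, 0.0]))

    def test_raw_centering_switch(self, toy_series):
        p = prepare_series(
            toy_series("r", [2000, 2001, 2002], [1.0, 2.0, 3.0]), centering="raw"
        )
        assert np.allclose(p.centered_log_abundance, [-1.0, 0.0, 1.0])

    @given(
        abund=st.lists(
            st.floats(0.01, 1e6, allow_nan=False, allow_infinity=False),
            min_size=2,
            max_size=30,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_centering_removes_mean_exactly(self, abund):
        from popthreat.data_io import PopulationSeries

        s = PopulationSeries(
            population_id="h",
            species_id="S",
            site=(0.0, 0.0),
            system="marine",
            taxon="fish",
            observations=tuple((2000 + i, a) for i, a in enumerate(abund)),
        )
        p = prepare_series(s)
        assert abs(p.centered_log_abundance.mean()) < 1e-10
        assert abs(p.centered_year.mean()) < 1e-10
        assert len(p.centered_year) == s.n_observations
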