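"""Readers, writers and validation of the tabular exchange formats."""

import pandas as pd
import pytest

from nichepop.errors import SchemaError, ValidationError
from nichepop.simulate import CommunitySimParams, gen_community
from nichepop.survey_io import (
    CensusRecord,
    PlotDescriptor,
    PlotObservation,
    PlotSurveyTable,
    overlap_to_markdown,
    read_census,
    read_plot_survey,
    round_half_up,
    write_table,
)


def test_plot_survey_round_trip(tmp_path):
    """A generated survey written to CSV reads back with identical values."""
    table = gen_community(CommunitySimParams(n_species=13, n_plots=4, seed=3))
    path = tmp_path / "survey.csv"
    table.to_frame().to_csv(path, index=False)
    again = read_plot_survey(path)
    pd.testing.assert_frame_equal(table.to_frame(), again.to_frame())
    assert 13 <= len(again.observations) <= 52


def test_missing_column_is_a_schema_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("plot_id,species,count,mean_height_cm\nP1,x,1,10\n")
    with pytest.raises(SchemaError, match="cover_pct"):
        read_plot_survey(path)


def test_schema_map_resolves_renamed_columns(tmp_path):
    path = tmp_path / "renamed.csv"
    path.write_text("quadrat,taxon,n,height,cov\nP1,x,2,12.5,40\n")
    table = read_plot_survey(
        path,
        schema={
            "plot_id": "quadrat",
            "species": "taxon",
            "count": "n",
            "mean_height_cm": "height",
            "cover_pct": "cov",
        },
    )
    assert table.observations[0].cover == 40.0


@pytest.mark.parametrize(
    "row",
    [
        "P1,x,1,10,120",  # cover out of bounds
        "P1,x,-2,10,30",  # negative count
    ],
)
def test_out_of_bounds_values_are_validation_errors(tmp_path, row):
    path = tmp_path / "bad.csv"
    path.write_text(f"plot_id,species,count,mean_height_cm,cover_pct\n{row}\n")
    with pytest.raises(ValidationError):
        read_plot_survey(path)


def test_duplicate_plot_species_pair_reports_row():
    with pytest.raises(ValidationError, match="duplicate"):
        PlotSurveyTable(
            plots=[PlotDescriptor("P1")],
            observations=[
                PlotObservation("P1", "x", 1, 10.0, 5.0),
                PlotObservation("P1", "x", 2, 11.0, 6.0),
            ],
        )


def test_census_parses_bounds_missing_and_checks_sums(census_records):
    """The bundled census carries bounds, missing stages and verified sums."""
    tnfp2_2022 = next(
        r for r in census_records if r.site == "TNFP2" and r.year == 2022
    )
    assert (tnfp2_2022.adult, tnfp2_2022.juvenile, tnfp2_2022.seedling) == (65, 90, 18)
    assert tnfp2_2022.total == 173
    bounded = next(r for r in census_records if r.site == "TGM" and r.year == 2019)
    assert bounded.total is None and bounded.upper_bound == 200
    assert not bounded.stages_complete
    # sorted by (site, year)
    keys = [(r.site, r.year) for r in census_records]
    assert keys == sorted(keys)


def test_census_stage_sum_violation_names_site_and_year(tmp_path):
    path = tmp_path / "census.csv"
    path.write_text("site,year,total,adult,juvenile,seedling\nS1,2022,10,4,5,2\n")
    with pytest.raises(ValidationError, match="S1/2022"):
        read_census(path)


def test_census_empty_file_gives_empty_list(tmp_path):
    path = tmp_path / "census.csv"
    path.write_text("site,year,total,adult,juvenile,seedling\n")
    assert read_census(path) == []


def test_write_table_is_bit_stable(tmp_path):
    df = pd.DataFrame({"a": [1.23456, 2.0], "b": ["x", "y"]})
    p1, p2 = tmp_path / "one.tsv", tmp_path / "two.tsv"
    write_table(df, p1, "tsv")
    write_table(df, p2, "tsv")
    assert p1.read_bytes() == p2.read_bytes()
    assert "1.23" in p1.read_text()  # default 2-decimal rendering


def test_write_table_refuses_empty_unless_allowed(tmp_path):
    with pytest.raises(ValidationError):
        write_table(pd.DataFrame(), tmp_path / "e.tsv")
    write_table(pd.DataFrame(), tmp_path / "e.tsv", allow_empty=True)


def test_overlap_markdown_single_species_is_dash_diagonal():
    md = overlap_to_markdown(pd.DataFrame([[1.0]], index=["only"], columns=["only"]))
    assert "—" in md
    assert md.count("|") > 0


def test_round_half_up_matches_printed_convention():
    assert round_half_up(2.735) == 2.74
    assert round_half_up(2.005) == 2.01
    assert round_half_up(-2.675) == -2.68
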