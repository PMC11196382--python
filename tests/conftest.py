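import pytest

from nichepop import datasets
from nichepop.survey_io import PlotDescriptor, PlotObservation, PlotSurveyTable


@pytest.fixture(scope="session")
def dominant_iv():
    """Bundled 13-species × 4-plot importance-value matrix (percent)."""
    return datasets.load_dominant_importance()


@pytest.fixture(scope="session")
def census_records():
    """Bundled 2019–2022 five-site census records."""
    return datasets.load_census()


@pytest.fixture(scope="session")
def printed_overlap():
    """Bundled published pairwise overlap matrix (2-decimal)."""
    return datasets.load_printed_overlap()


@pytest.fixture
def toy_survey():
    """Two plots; plot P1 has the hand-checkable two-species configuration."""
    plots = [PlotDescriptor("P1", site="A"), PlotDescriptor("P2", site="B")]
    observations = [
        PlotObservation("P1", "sp_a", count=3, mean_height=10.0, cover=30.0),
        PlotObservation("P1", "sp_b", count=1, mean_height=30.0, cover=10.0),
        PlotObservation("P2", "sp_a", count=2, mean_height=20.0, cover=50.0),
    ]
    return PlotSurveyTable(plots=plots, observations=observations)
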