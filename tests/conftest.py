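import pytest

from n2fix.synth import SurveyDesign, generate_survey


@pytest.fixture(scope="session")
def small_design():
    return SurveyDesign(n_stations=3, seed=20)


@pytest.fixture(scope="session")
def survey(small_design):
    return generate_survey(small_design)
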