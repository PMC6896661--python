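import pytest

from visualdata import classify_study, fixture_f2, fixture_f4, fixture_f5


@pytest.fixture(scope="session")
def f5_study():
    return fixture_f5()


@pytest.fixture(scope="session")
def f2_study():
    return fixture_f2()


@pytest.fixture(scope="session")
def f4_study():
    return fixture_f4()


@pytest.fixture(scope="session")
def f5_classified(f5_study):
    return classify_study(f5_study)


@pytest.fixture(scope="session")
def f2_classified(f2_study):
    return classify_study(f2_study)


@pytest.fixture(scope="session")
def f4_classified(f4_study):
    return classify_study(f4_study)
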