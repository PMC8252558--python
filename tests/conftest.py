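import dataclasses

import pytest

from trauma_ehr.config import CohortConfig
from trauma_ehr.detector import Detector
from trauma_ehr.lexicon import load_lexicon
from trauma_ehr.meddose import load_gazetteer
from trauma_ehr.synthetic import generate_cohort


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def detector(lexicon):
    return Detector(lexicon)


@pytest.fixture(scope="session")
def gazetteer():
    return load_gazetteer()


@pytest.fixture(scope="session")
def small_config():
    """A 400-patient cohort: big enough for every downstream stage to see
    exposed/unexposed patients, distractors and dosed mentions."""
    return dataclasses.replace(CohortConfig(), n_patients=400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)
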