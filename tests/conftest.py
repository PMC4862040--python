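import logging

import pytest

from hcst.config import default_config
from hcst.pipeline import build_profiles
from hcst.synthetic_data import CohortSpec, DietSpec, generate_cohort, generate_foods
from hcst.tier_classifier import classify_foods

logging.getLogger("hcst").setLevel(logging.ERROR)

COHORT_SEED = 20260915


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def diet_spec():
    return DietSpec()


@pytest.fixture(scope="session")
def foods(config, diet_spec):
    return generate_foods(diet_spec, COHORT_SEED, config)


@pytest.fixture(scope="session")
def assignments(foods, config):
    return classify_foods(foods, config)


@pytest.fixture(scope="session")
def cohort2000(config, diet_spec):
    """The default-condition synthetic cohort (n = 2000, one recall day)."""
    spec = CohortSpec(n_respondents=2000)
    respondents, items, truth = generate_cohort(spec, diet_spec, COHORT_SEED, config)
    return respondents, items, truth


@pytest.fixture(scope="session")
def profiles2000(cohort2000, foods, assignments, config):
    respondents, items, _ = cohort2000
    return build_profiles(respondents, items, foods, assignments, config)
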