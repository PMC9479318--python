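import numpy as np
import pandas as pd
import pytest

from moralargs.scoring import DUMMY_COLUMNS
from moralargs.synthetic import SurveyDGP, gen_survey


def judgment_row(**set_to_one):
    """A single judgment dict with all 14 dummies 0 except those named."""
    row = {c: 0 for c in DUMMY_COLUMNS}
    for k in set_to_one:
        if k not in row:
            raise KeyError(k)
        row[k] = 1
    return row


@pytest.fixture(scope="session")
def flat_survey():
    """A small survey with no effects at all: betas 0, RE SDs 0."""
    dgp = SurveyDGP(n_respondents=800, n_issues=6,
                    beta1_by_group={}, seed=100)
    table, truth = gen_survey(dgp)
    return table, truth


@pytest.fixture(scope="session")
def effect_survey():
    """Survey with a liberal DF effect of 0.12 and moderate random
    intercepts — the workhorse for estimation tests."""
    dgp = SurveyDGP(
        n_respondents=2500,
        n_issues=10,
        beta1_by_group={"liberal": 0.12, "moderate": 0.06, "conservative": 0.0},
        re_sd_individual=0.5,
        re_sd_issuewave=0.2,
        re_sd_issue=0.3,
        seed=101,
    )
    table, truth = gen_survey(dgp)
    return table, truth
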