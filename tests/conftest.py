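import numpy as np
import pandas as pd
import pytest

import jemkit as jk


@pytest.fixture(scope="session")
def item_set():
    return jk.default_item_set()


@pytest.fixture(scope="session")
def small_scenario():
    """20 codes in 8 groups, one wave, moderate cells — fast end-to-end runs."""
    return jk.random_scenario(
        11, n_codes=20, n_groups=8, waves=[2016], n_per_cell=40, missing_rate=0.05
    )


@pytest.fixture(scope="session")
def small_survey(small_scenario):
    return jk.generate_survey(small_scenario)


def survey_from_rows(rows, item_set):
    """Assemble a survey DataFrame from (code, gender, {item: value}) triples."""
    records = []
    for i, (code, gender, responses) in enumerate(rows):
        rec = {
            "respondent_id": f"R{i:04d}",
            "wave": 2016,
            "occupation_code": code,
            "gender": gender,
            **{item: np.nan for item in item_set.item_ids},
        }
        rec.update(responses)
        records.append(rec)
    return pd.DataFrame(records)


def constant_survey(values, item_set, code="1000", gender="female"):
    """One respondent per value, the same value on every item."""
    return survey_from_rows(
        [(code, gender, {i: v for i in item_set.item_ids}) for v in values],
        item_set,
    )
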