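import math

import pandas as pd
import pytest

from vitdfort.burden import LifeTable, MortalityTable
from vitdfort.meta_pool import StudyEffect, keum2019_studies


@pytest.fixture(scope="session")
def evidence_studies() -> list[StudyEffect]:
    """The five packaged cancer-mortality RCT effects."""
    return keum2019_studies()


@pytest.fixture()
def toy_mortality() -> MortalityTable:
    """Two strata: 100 male deaths at 70-74, 50 female deaths at 80-84."""
    return MortalityTable(
        frame=pd.DataFrame(
            [
                {"sex": "male", "age_low": 70, "age_high": 74.0, "deaths": 100},
                {"sex": "female", "age_low": 80, "age_high": 84.0, "deaths": 50},
            ]
        )
    )


@pytest.fixture()
def toy_life() -> LifeTable:
    """Life table hitting the toy midpoints exactly: LE(m,72.5)=14.5, LE(f,82.5)=8.9."""
    rows = []
    for sex, pairs in {
        "male": [(70, 15.75), (75, 13.25), (80, 10.0), (85, 8.0)],
        "female": [(70, 18.0), (75, 14.0), (80, 10.3), (85, 7.5)],
    }.items():
        rows.extend({"sex": sex, "age": float(a), "ex": e} for a, e in pairs)
    table = LifeTable(frame=pd.DataFrame(rows))
    assert math.isclose(table.lookup("male", 72.5), 14.5)
    assert math.isclose(table.lookup("female", 82.5), 8.9)
    return table
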