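import numpy as np
import pandas as pd
import pytest

from phenovis.io import SurveySchema, make_survey_table


@pytest.fixture(scope="session")
def tiny_schema():
    """Two sections, two/three questions, levels 0-3."""
    return SurveySchema(
        sections=("mood", "sleep"),
        questions={"mood": ("m1", "m2"), "sleep": ("s1", "s2", "s3")},
        levels={
            ("mood", "m1"): (0, 1, 2, 3),
            ("mood", "m2"): (0, 1, 2, 3),
            ("sleep", "s1"): (0, 1, 2, 3),
            ("sleep", "s2"): (0, 1, 2, 3),
            ("sleep", "s3"): (0, 1, 2, 3),
        },
    )


def long_rows(schema, values_by_day, patient_id="p1", start="2021-06-01"):
    """values_by_day: list of {(section, question): response-or-nan} dicts."""
    start = pd.Timestamp(start)
    rows = []
    for i, day in enumerate(values_by_day):
        for (section, q), v in day.items():
            rows.append((patient_id, start + pd.Timedelta(days=i), section, q, v))
    return pd.DataFrame(
        rows, columns=["patient_id", "date", "section", "question_id", "response"]
    )


@pytest.fixture
def complete_table(tiny_schema):
    """Six days of complete responses with day-to-day variation."""
    rng = np.random.default_rng(7)
    days = []
    for _ in range(6):
        day = {}
        for s in tiny_schema.sections:
            for q in tiny_schema.questions[s]:
                day[(s, q)] = int(rng.integers(0, 4))
        days.append(day)
    return make_survey_table(long_rows(tiny_schema, days), tiny_schema)
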