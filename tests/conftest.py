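"""Shared fixtures: records, toy tables, and small deterministic cohorts."""

import numpy as np
import pytest

from dentalage.scores import ScoreTable, builtin_modified_tables
from dentalage.simulate import CohortSpec, generate_cohort, scaled_spec
from dentalage.staging import SCOREABLE_STAGES, TEETH, Sex, Stage, StagingRecord


def make_record(sid="S1", sex=Sex.MALE, age=10.0, stages="HHHHHHH"):
    """Build a record from a 7-letter stage string ('.' = MISSING)."""
    mapping = {}
    for tooth, letter in zip(TEETH, stages):
        mapping[tooth] = Stage.MISSING if letter == "." else Stage[letter]
    return StagingRecord(sid, sex, age, mapping)


def uniform_table(value=1.0, sex=Sex.MALE, name="toy", kind="age_sum"):
    """Score table with every cell set to the same value."""
    scores = {t: {s: value for s in SCOREABLE_STAGES} for t in TEETH}
    return ScoreTable(name=name, sex=sex, kind=kind, scores=scores)


@pytest.fixture(scope="session")
def modified_tables():
    female, male = builtin_modified_tables()
    return {"female": female, "male": male}


@pytest.fixture(scope="session")
def small_cohort():
    """200-subject cohort with the reference age/sex profile, fixed seed."""
    cohort, _ = generate_cohort(scaled_spec(200, seed=3))
    return cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (n = 1477), fixed seed."""
    cohort, _ = generate_cohort(CohortSpec(seed=11))
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
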