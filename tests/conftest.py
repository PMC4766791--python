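import numpy as np
import pytest

from vahier.rules_engine import (
    And,
    CauseRule,
    Or,
    RuleSet,
    SymptomAtom,
    SymptomDef,
    VARecord,
)


def binary_dictionary(*symptom_ids):
    return {s: SymptomDef(kind="binary") for s in symptom_ids}


def record(death_id="d1", age_group="neonate", responses=None, numerics=None):
    return VARecord(death_id, age_group, responses or {}, numerics or {})


@pytest.fixture
def two_rule_set():
    """X := s1=yes AND s2=yes ; Y := s3=yes OR s4=yes."""
    return RuleSet(
        age_group="neonate",
        rules=(
            CauseRule("X", And((SymptomAtom("s1", "yes"), SymptomAtom("s2", "yes")))),
            CauseRule("Y", Or((SymptomAtom("s3", "yes"), SymptomAtom("s4", "yes")))),
        ),
        symptom_dictionary=binary_dictionary("s1", "s2", "s3", "s4"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
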