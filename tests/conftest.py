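import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from primellm.grading import GRADED_COLUMNS, AnswerKey

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_graded(rows):
    """Build a graded table from (model, qid, vignette, domain, rep, score,
    excluded[, age, sex]) tuples."""
    full = []
    for r in rows:
        r = tuple(r) + ("adult", "female")[: 9 - len(r)]
        full.append(r)
    df = pd.DataFrame(full, columns=list(GRADED_COLUMNS))
    df["score"] = df["score"].astype("Int64")
    df.loc[df["excluded"].astype(bool), "score"] = pd.NA
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def two_question_keys():
    return [
        AnswerKey("q1", "v1", "DD", frozenset("ABCD"), frozenset("AC"),
                  False, "young_adult", "female"),
        AnswerKey("q2", "v1", "FD", frozenset("ABC"), frozenset("B"),
                  True, "young_adult", "female"),
    ]


@pytest.fixture
def random_graded(rng):
    """A small random but complete benchmark: 3 models x 2 replicates x
    5 domains over 4 vignettes with 1-3 questions per (vignette, domain)."""
    from primellm.grading import DOMAINS

    rows = []
    qid = 0
    for v in range(4):
        age = ["pediatric", "young_adult", "middle_aged"][v % 3]
        sex = ["female", "male"][v % 2]
        for d in DOMAINS:
            for _ in range(int(rng.integers(1, 4))):
                qid += 1
                for m in range(3):
                    for rep in (1, 2):
                        rows.append(
                            (f"m{m}", f"q{qid}", f"v{v}", d, rep,
                             int(rng.random() < 0.6), False, age, sex)
                        )
    return make_graded(rows)
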