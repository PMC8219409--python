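import math
from collections import Counter

import pandas as pd
import pytest

from gainselect.cohort import CohortDataset, FeatureSpec


def make_dataset(columns: dict, kinds: dict | None = None,
                 target: str = "PTB") -> CohortDataset:
    """Build a small cohort from literal column lists."""
    kinds = kinds or {}
    frame = pd.DataFrame(columns)
    schema = []
    for col in frame.columns:
        role = "target" if col == target else "candidate"
        kind = kinds.get(col, "binary" if role == "target" else "numeric")
        schema.append(FeatureSpec(col, col, kind, role))
    return CohortDataset(frame=frame, schema=schema)


# --- independent first-principles oracle for entropy and gain ---------------

def oracle_entropy(labels) -> float:
    n = len(labels)
    return -sum((c / n) * math.log2(c / n) for c in Counter(labels).values())


def oracle_gain(x, y) -> float:
    """Information gain computed by literal partition enumeration."""
    total = oracle_entropy(y)
    for v in set(x):
        sub = [yi for xi, yi in zip(x, y) if xi == v]
        total -= (len(sub) / len(y)) * oracle_entropy(sub)
    return total


@pytest.fixture(scope="session")
def default_cohort():
    """One shared draw of the default 1300-row synthetic cohort."""
    from gainselect.simulate import default_config, generate_cohort
    return generate_cohort(default_config(seed=42))
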