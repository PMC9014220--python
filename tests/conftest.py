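import numpy as np
import pandas as pd
import pytest

from cerna_weaver import CountMatrix, StudyDesign


@pytest.fixture
def small_counts() -> CountMatrix:
    """3 features x 2 samples with explicit library sizes."""
    df = pd.DataFrame(
        {"s1": [2, 3, 5], "s2": [10, 0, 10]},
        index=["f1", "f2", "f3"],
    )
    lib = pd.Series({"s1": 100, "s2": 200})
    lengths = pd.Series({"f1": 1000, "f2": 2000, "f3": 500})
    return CountMatrix(df, library_size=lib, feature_length_bp=lengths)


@pytest.fixture
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
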