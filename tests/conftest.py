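import numpy as np
import pandas as pd
import pytest

from strandage.io import MethylationMatrix, ReadPatternSet, SampleMetadata


@pytest.fixture
def small_matrix() -> MethylationMatrix:
    return MethylationMatrix(pd.DataFrame(
        [[0.1, 0.9], [0.5, 0.5]],
        index=["cg000001", "cg000002"],
        columns=["s1", "s2"],
    ))


@pytest.fixture
def linear_cohort() -> tuple[MethylationMatrix, SampleMetadata]:
    """Noiseless cohort where age = 10 + 50*beta1 + 30*beta2 exactly."""
    rng = np.random.default_rng(42)
    n = 30
    b1 = rng.uniform(0.0, 1.0, n)
    b2 = rng.uniform(0.0, 1.0, n)
    ages = 10 + 50 * b1 + 30 * b2
    samples = [f"s{i:02d}" for i in range(n)]
    matrix = MethylationMatrix(pd.DataFrame(
        [b1, b2], index=["cgA", "cgB"], columns=samples))
    meta = SampleMetadata(pd.DataFrame(
        {"age": ages, "study": "sim"}, index=pd.Index(samples, name="sample_id")))
    return matrix, meta


@pytest.fixture
def elovl2_like_patterns() -> ReadPatternSet:
    return ReadPatternSet("S1", "ELOVL2", 3,
                          {"101": 12, "111": 10, "000": 10, "110": 9,
                           "011": 3, "001": 1, "100": 1})
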