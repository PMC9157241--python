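import numpy as np
import pandas as pd
import pytest

from acetrend.design import ComparisonWindow, Sample, StudyDesign
from acetrend.matrix import CountMatrix


@pytest.fixture
def two_group_design():
    """Minimal injury design: N vs C1d (distal), n replicates each."""

    def make(n: int = 3) -> StudyDesign:
        samples = []
        for tp in ("N", "C1d"):
            for r in range(1, n + 1):
                samples.append(Sample(f"{tp}.d.r{r}", "injury", tp, "distal", r))
        return StudyDesign(samples)

    return make


@pytest.fixture
def injury_window():
    return ComparisonWindow("injury-distal", "injury", ("N", "distal"), ("C1d", "distal"))


@pytest.fixture
def make_matrix():
    """CountMatrix from a dict sample -> counts, uniform 1 kb genes."""

    def make(columns: dict[str, list[int]], lengths=None) -> CountMatrix:
        df = pd.DataFrame(columns, dtype=np.int64)
        df.index = [f"g{i}" for i in range(len(df))]
        if lengths is None:
            lengths = pd.Series(1000, index=df.index)
        else:
            lengths = pd.Series(lengths, index=df.index)
        return CountMatrix(df, lengths)

    return make
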