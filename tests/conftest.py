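import numpy as np
import pandas as pd
import pytest

from sigperm import CountMatrix, ExpressionMatrix, SampleDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20150321)


@pytest.fixture
def small_counts(rng):
    """50 genes x 6 samples of Poisson-ish counts with known lengths."""
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"S{j}" for j in range(6)]
    counts = pd.DataFrame(rng.poisson(100.0, size=(50, 6)),
                          index=genes, columns=samples)
    lengths = pd.Series(rng.integers(500, 5000, size=50), index=genes)
    return CountMatrix(counts, lengths)


@pytest.fixture
def two_group_design():
    samples = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
    return SampleDesign(pd.Series(["a"] * 4 + ["b"] * 4, index=samples))


def make_expression(values: np.ndarray, stage: str = "log2_centered",
                    prefix: str = "S") -> ExpressionMatrix:
    genes = [f"G{i:04d}" for i in range(values.shape[0])]
    samples = [f"{prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            stage=stage)
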