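import numpy as np
import pandas as pd
import pytest

from metasig.data_model import ExpressionMatrix, SampleAnnotation, Scale
from metasig.simulate import hotpam_like_config, simulate_expression_cohort


@pytest.fixture
def make_expr():
    """Factory: build an ExpressionMatrix from a 2-D array."""

    def _make(arr, genes=None, samples=None, scale=Scale.RAW_LOG2):
        arr = np.atleast_2d(np.asarray(arr, float))
        genes = list(genes) if genes is not None else [f"g{i}" for i in range(arr.shape[0])]
        samples = list(samples) if samples is not None else [f"s{j}" for j in range(arr.shape[1])]
        return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), scale)

    return _make


@pytest.fixture
def make_ann():
    """Factory: build a SampleAnnotation from a class-label list."""

    def _make(classes, samples=None, **extra_cols):
        samples = list(samples) if samples is not None else [f"s{j}" for j in range(len(classes))]
        df = pd.DataFrame({"disease_class": list(classes), **extra_cols}, index=samples)
        return SampleAnnotation(df)

    return _make


@pytest.fixture(scope="session")
def hotpam_study():
    """One realization of the default synthetic cohort, shared across tests."""
    return simulate_expression_cohort(hotpam_like_config(seed=0))
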