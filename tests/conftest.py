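import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from orthoverlap import ExpressionStudy
from orthoverlap.simulate import SyntheticConfig, generate

settings.register_profile(
    "default",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_study(counts, lengths=None, samples=None, groups=None, kind="counts"):
    """Small ExpressionStudy from a dict gene -> list of values."""
    df = pd.DataFrame.from_dict(counts, orient="index", dtype=float)
    if samples is not None:
        df.columns = samples
    else:
        df.columns = [f"s{i + 1}" for i in range(df.shape[1])]
    if groups is None:
        half = df.shape[1] // 2
        groups = {s: ("A" if i < half else "B") for i, s in enumerate(df.columns)}
    lengths_s = pd.Series(lengths) if lengths is not None else None
    return ExpressionStudy(
        values=df, sample_groups=groups, lengths=lengths_s, value_kind=kind
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic dataset shared across read-only tests."""
    return generate(SyntheticConfig(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
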