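import numpy as np
import pandas as pd
import pytest

from immunomark.expression import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts():
    """4 genes x 3 samples of raw counts."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[10, 20, 30], [5, 5, 5], [100, 50, 25], [0, 3, 7]],
            index=["gA", "gB", "gC", "gD"],
            columns=["s1", "s2", "s3"],
        ),
        stage="raw",
    )


@pytest.fixture
def control_panel():
    """5 genes x 4 control samples, strictly positive (pseudo-counted)."""
    rng = np.random.default_rng(7)
    vals = np.exp(rng.normal(3.0, 0.4, size=(5, 4))) + 1.0
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(5)],
            columns=[f"n{i}" for i in range(4)],
        ),
        stage="normalized",
    )


def random_survival(rng, n, censor=0.3):
    """Convenience: exponential times with uniform censoring."""
    t_event = rng.exponential(10.0, size=n)
    t_cens = rng.uniform(0, 10.0 / censor, size=n)
    return np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int)
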