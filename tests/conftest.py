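import numpy as np
import pandas as pd
import pytest

from harshcv.model_space import CandidateEffectSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def three_main_effects():
    return CandidateEffectSet(("x1", "x2", "x3"))


def make_linear_dataset(rng, n, betas, noise_sd=1.0, extra=(),
                        outcome="harsh_discipline"):
    """Standard-normal predictors, y = sum(beta * x) + noise."""
    cols = {name: rng.standard_normal(n) for name in betas}
    for name in extra:
        cols[name] = rng.standard_normal(n)
    y = sum(b * cols[name] for name, b in betas.items())
    y = np.asarray(y, dtype=float) + noise_sd * rng.standard_normal(n)
    df = pd.DataFrame(cols)
    df[outcome] = y
    return df
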