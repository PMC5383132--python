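import numpy as np
import pandas as pd
import pytest

from gma.model_core import build_meta_model


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def linear_model():
    return build_meta_model("linear", ("x1", "x2", "x3"))


@pytest.fixture
def small_table(rng):
    return pd.DataFrame(rng.standard_normal((40, 3)), columns=["x1", "x2", "x3"])
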