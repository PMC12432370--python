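import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

from igesbs import ExpressionMatrix, GeneSet, GeneSetCollection

hypothesis_settings.register_profile("stable", derandomize=True)
hypothesis_settings.load_profile("stable")


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    """5 genes x 4 samples, linear scale, hand-friendly values."""
    values = pd.DataFrame(
        [
            [1.0, 3.0, 5.0, 7.0],
            [2.0, 2.0, 2.0, 2.0],   # constant gene
            [0.0, 1.0, 4.0, 9.0],
            [8.0, 6.0, 4.0, 2.0],
            [1.0, 0.0, 3.0, 2.0],
        ],
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{i}" for i in range(4)],
    )
    return ExpressionMatrix(values=values, log_transformed=False)


@pytest.fixture
def toy_sets() -> GeneSetCollection:
    return GeneSetCollection([
        GeneSet(name="A", genes=["g0", "g2"]),
        GeneSet(name="B", genes=["g1"]),
        GeneSet(name="C", genes=["g3", "g4", "gX"]),  # gX absent
    ])
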