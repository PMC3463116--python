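import numpy as np
import pytest

from ibbig import AssociationMatrix, GAParams


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_matrix():
    """3 x 4 binary matrix used throughout the score examples."""
    return AssociationMatrix(
        values=np.array(
            [
                [1, 1, 1, 0],
                [1, 1, 0, 0],
                [0, 0, 1, 0],
            ]
        ),
        row_ids=["a", "b", "c"],
        col_ids=["p", "q", "r", "s"],
    )


@pytest.fixture
def fast_params():
    """Default parameters with a short stagnation for small fixtures."""
    return GAParams(stagnation=15)
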