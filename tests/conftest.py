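import numpy as np
import pytest

from persistsig import ExpressionMatrix, SignatureCollection


@pytest.fixture
def toy_counts() -> ExpressionMatrix:
    """5 genes x 4 samples, small integers, some ties and zeros."""
    rng = np.random.default_rng(7)
    values = rng.integers(0, 6, size=(5, 4)).astype(float)
    values[0, 0] = 1.0  # keep every column non-degenerate
    return ExpressionMatrix([f"g{i}" for i in range(5)],
                            [f"s{j}" for j in range(4)], values, "counts")


@pytest.fixture
def toy_lognorm() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    values = np.abs(rng.normal(1.0, 0.5, size=(30, 8)))
    return ExpressionMatrix([f"g{i:02d}" for i in range(30)],
                            [f"s{j}" for j in range(8)], values, "lognorm")


@pytest.fixture
def two_sigs() -> SignatureCollection:
    return SignatureCollection(
        ["top", "pair"],
        {"top": ["g00", "g01", "g02"], "pair": ["g03", "g04"]})
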