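import numpy as np
import pytest

from sumosite.seqio import PeptideWindow, CENTER_POSITION, WINDOW_LENGTH


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_window(rng, alphabet="ARNDCEQGHILKMFPSTWYVX") -> PeptideWindow:
    letters = rng.choice(list(alphabet), size=WINDOW_LENGTH)
    letters[CENTER_POSITION - 1] = "K"
    return PeptideWindow(
        source_id="random",
        center_position=CENTER_POSITION,
        residues="".join(letters),
    )


@pytest.fixture
def random_windows(rng):
    return [random_window(rng) for _ in range(25)]


@pytest.fixture
def separable_dataset(rng):
    """Two well-separated Gaussian blobs in 2 informative + 192 zero columns."""
    n = 200
    X = np.zeros((2 * n, 194))
    X[:n, 0] = rng.normal(4.0, 0.3, n)
    X[:n, 1] = rng.normal(-4.0, 0.3, n)
    X[n:, 0] = rng.normal(-4.0, 0.3, n)
    X[n:, 1] = rng.normal(4.0, 0.3, n)
    y = np.array([1] * n + [0] * n)
    return X, y
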