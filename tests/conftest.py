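import numpy as np
import pytest

from kmcut.simulate import example_fixture, example_table_text


@pytest.fixture(scope="session")
def example_tsv() -> str:
    return example_table_text("tab")


@pytest.fixture()
def example10():
    return example_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_survival(rng, n, hr=1.0, censor=0.3):
    """Small ad-hoc two-group survival sample for unit tests."""
    g = rng.integers(0, 2, size=n)
    t = rng.exponential(1.0 / (0.1 * np.where(g == 1, hr, 1.0)))
    c = rng.exponential(1.0 / (0.1 * censor / max(1 - censor, 1e-9)))
    e = (t <= c).astype(int)
    return np.minimum(t, c), e, g
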