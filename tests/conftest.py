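import numpy as np
import pytest

from splinewin import MarkerSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_series(rng, n=60, span=100_000, kind="mixed", chrom="1"):
    """Small random marker series for property tests."""
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=n, replace=False))
    if kind == "noise":
        y = rng.normal(0.2, 0.1, n)
    elif kind == "sine":
        y = np.sin(2 * np.pi * pos / (span / 3)) + rng.normal(0, 0.1, n)
    else:
        c = rng.uniform(0.2, 0.8) * span
        y = 0.1 + 0.5 * np.exp(-0.5 * ((pos - c) / (span / 15)) ** 2)
        y = y + rng.normal(0, 0.05, n)
    return MarkerSeries(chrom, pos, y)
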