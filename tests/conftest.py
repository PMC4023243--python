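import numpy as np
import pandas as pd
import pytest

from mratax import MeasurementTable
from mratax.moldist import AlignedSeqSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, otu=None, sex="female", characters=None):
    """Build a MeasurementTable from a plain (n, p) array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if characters is None:
        characters = tuple(f"ch{j:02d}" for j in range(p))
    if otu is None:
        otu = ["g1"] * n
    elif isinstance(otu, str):
        otu = [otu] * n
    sexes = [sex] * n if isinstance(sex, str) else list(sex)
    return MeasurementTable(
        specimen_id=np.array([f"s{i}" for i in range(n)]),
        otu=np.asarray(otu, dtype=object),
        sex=np.asarray(sexes, dtype=object),
        characters=tuple(characters),
        values=values,
    )


@pytest.fixture
def toy_table():
    """3 specimens x 3 characters with hand-checkable structure."""
    return make_table([[100.0, 200.0, 400.0],
                       [110.0, 220.0, 440.0],
                       [90.0, 150.0, 300.0]])


@pytest.fixture
def two_group_table(rng):
    """Two groups of 20 separated along ch0/ch1 in log-shape space."""
    base = np.log([300.0, 400.0, 500.0, 600.0])
    rows, otus = [], []
    for g, off in (("a", 0.15), ("b", -0.15)):
        for _ in range(20):
            shape = np.array([off, -off, 0.0, 0.0])
            size = rng.normal(0.0, 0.05)
            rows.append(np.exp(base + size + shape + rng.normal(0, 0.02, 4)))
            otus.append(g)
    return make_table(np.array(rows), otu=otus)


def make_alignment(seqs, otus=None, ids=None):
    n = len(seqs)
    if ids is None:
        ids = [f"t{i}" for i in range(n)]
    if otus is None:
        otus = list(ids)
    return AlignedSeqSet(tuple(ids), tuple(otus), tuple(seqs))
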