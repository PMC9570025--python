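import numpy as np
import pytest

from venomsig.io_formats import fixture_precursors, load_table1_fixture
from venomsig.maturation import expand_alleles


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_precursors(table1):
    return fixture_precursors(table1)


@pytest.fixture(scope="session")
def table1_matures(table1):
    """Per row: list of (mature sequence, amidated, n_disulfides, printed mh)."""
    out = {}
    for row in table1.itertuples(index=False):
        refs = [float(x) for x in row.predicted_mh.split("/")]
        seqs = expand_alleles(row.mature)
        out[row.name] = [
            (s, bool(row.amidated), int(row.n_disulfides), ref)
            for s, ref in zip(seqs, refs)
        ]
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
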