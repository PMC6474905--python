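import numpy as np
import pytest

from itsphylo import SimConfig, load_table3, simulate_alignment
from itsphylo.seqio import ItsRecord


@pytest.fixture(scope="session")
def table3():
    """The packaged 14-taxon printed K2P matrix."""
    return load_table3()


@pytest.fixture(scope="session")
def sim14():
    """A 14-taxon synthetic ITS dataset with no indels (fixed seed)."""
    return simulate_alignment(SimConfig(n_taxa=14, seed=140))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def make_records(seqs, prefix="t"):
    return [ItsRecord(id=f"{prefix}{i + 1}", seq=s) for i, s in enumerate(seqs)]
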