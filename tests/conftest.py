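import numpy as np
import pytest
from hypothesis import strategies as st

from methylshape import TruthModel, methylate
from methylshape.tableset import QueryTable
from methylshape.alphabet import enumerate_pentamers


@pytest.fixture(scope="session")
def truth():
    """Planted truth with the default methylation-effect magnitudes."""
    return TruthModel(seed=7)


@pytest.fixture(scope="session")
def pqt(truth):
    """Noise-free unmethylated pentamer table (512 keys)."""
    return truth.as_query_table("unmethylated")


@pytest.fixture(scope="session")
def mpqt(truth):
    """Noise-free methylation-aware pentamer table (987 keys)."""
    return truth.as_query_table("all")


@pytest.fixture(scope="session")
def uniform_table():
    """All 987 keys share one feature tuple — profiles must be constant."""
    vals = np.array([5.0, -7.0, 1.0, 1.0, 34.0, 34.0])
    table = QueryTable()
    for key in enumerate_pentamers("all"):
        table.entries[key] = vals.copy()
        table.counts[key] = 1
    return table


@st.composite
def methyl_seqs(draw, min_size=5, max_size=30):
    """Random fragment-valid sequences: ACGT core with a random subset of
    CpG steps methylated."""
    base = draw(st.text(alphabet="ACGT", min_size=min_size, max_size=max_size))
    cpgs = [i for i in range(len(base) - 1) if base[i : i + 2] == "CG"]
    chosen = [i for i in cpgs if draw(st.booleans())]
    return methylate(base, chosen)
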