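import numpy as np
import pandas as pd
import pytest

from methdiff.meth_io import CpGTable


def make_table(records, sample_id="s1", condition="UN"):
    """Build a CpGTable from (chrom, pos, coverage, meth_calls) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "coverage", "meth_calls"])
    return CpGTable(sample_id=sample_id, condition=condition, data=df)


def make_counts(records):
    """Pooled count frame from (chrom, pos, coverage, meth_calls) tuples."""
    return pd.DataFrame(records, columns=["chrom", "pos", "coverage", "meth_calls"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def block_counts():
    """A 7-CpG differential block: 30x coverage, rates 0.9 vs 0.1."""
    pos = list(range(0, 700, 100))
    a = make_counts([("chr1", p, 30, 27) for p in pos])
    b = make_counts([("chr1", p, 30, 3) for p in pos])
    return a, b
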