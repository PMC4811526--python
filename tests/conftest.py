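import numpy as np
import pandas as pd
import pytest

from refstab.cp_data import CpTable


def make_table(cp, genes=None, classes=None, bio=None, tech=None):
    """Build a CpTable from a 2-D array with minimal annotations.

    Defaults: gene names G1..Gk, all samples in class 'control', distinct
    biological replicates, single technical replicate.
    """
    cp = np.asarray(cp, float)
    k, n = cp.shape
    genes = genes or [f"G{i+1}" for i in range(k)]
    classes = classes or ["control"] * n
    bio = bio if bio is not None else list(range(1, n + 1))
    tech = tech if tech is not None else [1] * n
    ids = [f"s{j+1}" for j in range(n)]
    frame = pd.DataFrame(cp, index=genes, columns=ids)
    samples = pd.DataFrame({
        "condition_class": classes,
        "biological_replicate": bio,
        "technical_replicate": tech,
    }, index=ids)
    return CpTable(frame, samples)


@pytest.fixture
def table_factory():
    return make_table
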