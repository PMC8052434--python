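import numpy as np
import pandas as pd
import pytest

from omiclink.io_model import OmicsLayer, SampleTable
from omiclink.knowledge import load_fixture_kb
from omiclink import synthetic


@pytest.fixture(scope="session")
def kb():
    return load_fixture_kb()


@pytest.fixture(scope="session")
def cs1():
    return synthetic.cs1_miniature()


@pytest.fixture(scope="session")
def cs2():
    return synthetic.cs2_miniature()


@pytest.fixture(scope="session")
def cs3():
    return synthetic.cs3_miniature()


def make_layer(values, ids, name="toy", id_column="id", vocab=None, extra_meta=None):
    """Small helper to build an OmicsLayer from a matrix and identifier list."""
    values = np.asarray(values, dtype=float)
    meta = {id_column: [str(i) for i in ids]}
    if extra_meta:
        meta.update({k: [str(x) for x in v] for k, v in extra_meta.items()})
    tags = {id_column: vocab} if vocab else {}
    return OmicsLayer(
        name=name,
        metadata=pd.DataFrame(meta, dtype=str),
        values=pd.DataFrame(values, columns=[f"S{k + 1}" for k in range(values.shape[1])]),
        standard_id_tags=tags,
    )


def make_samples(names, **phenotypes):
    return SampleTable(sample_names=list(names), phenotypes=pd.DataFrame(dict(phenotypes)))
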