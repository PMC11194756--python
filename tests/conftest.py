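import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from spotica import SpotMatrix, TranscriptTable, make_reference, simulate_spots


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spots():
    """3 spots x 4 genes with known totals."""
    counts = sp.csr_matrix(np.array([[1, 0, 2, 0], [0, 3, 0, 1], [4, 0, 0, 5]]))
    return SpotMatrix(
        counts=counts,
        spot_ids=np.array(["s1", "s2", "s3"], dtype=object),
        gene_ids=np.array(["gA", "gB", "gC", "gD"], dtype=object),
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
    )


@pytest.fixture
def small_reference():
    return make_reference(n_types=4, n_genes=200, markers_per_type=10, seed=7)


@pytest.fixture
def small_sim(small_reference):
    return simulate_spots(small_reference, n_spots=120, n_regions=3, seed=7)


def make_transcripts(xy, genes=None):
    xy = np.asarray(xy, dtype=float)
    if genes is None:
        genes = ["g1"] * len(xy)
    return TranscriptTable(
        records=pd.DataFrame({"gene": genes, "x": xy[:, 0], "y": xy[:, 1]}), units="um"
    )
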