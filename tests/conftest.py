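import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import atlasdecon as ad


@pytest.fixture(scope="session")
def small_spec():
    return ad.AtlasSpec(
        n_cell_types=3,
        cells_per_type=60,
        n_genes=300,
        markers_per_type=10,
        marker_fold_change=8.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    return ad.generate_reference_atlas(small_spec)


@pytest.fixture(scope="session")
def small_normalized(small_atlas):
    counts, _ = small_atlas
    return ad.normalize_log1p(counts)


@pytest.fixture(scope="session")
def small_labels(small_atlas):
    _, annot = small_atlas
    return annot["cluster"]


@pytest.fixture(scope="session")
def small_signature(small_normalized, small_labels):
    markers = ad.wilcoxon_de_one_vs_rest(small_normalized, small_labels)
    return ad.build_signature_matrix(small_normalized, small_labels, markers)


def make_counts(array, genes=None, cells=None):
    """Build a CountMatrix from a dense genes x cells array."""
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    cells = cells or [f"c{j}" for j in range(array.shape[1])]
    return ad.CountMatrix(sp.csr_matrix(array), pd.Index(genes), pd.Index(cells))
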