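import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy import sparse

from stressccc.preprocess import CellMatrix, lognormalize

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cell_matrix(dense, gene_ids=None, **meta) -> CellMatrix:
    """CellMatrix from a dense genes x cells array with filler metadata."""
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    base = {
        "mouse": "m1",
        "group": "control",
        "region": "dorsal",
        "hemisphere": "left",
        "cell_type": "microglia",
    }
    base.update(meta)
    cell_meta = pd.DataFrame(
        {k: (v if not np.isscalar(v) else [v] * n_cells) for k, v in base.items()},
        index=[f"c{i}" for i in range(n_cells)],
    )
    return CellMatrix(
        counts=sparse.csr_matrix(dense), gene_ids=gene_ids, cell_meta=cell_meta
    )


@pytest.fixture
def small_norm():
    """Log-normalized 6-gene x 8-cell matrix with two cluster labels."""
    rng = np.random.default_rng(7)
    dense = rng.poisson(2.0, size=(6, 8)) + 1  # no zero-total cells
    m = make_cell_matrix(dense)
    labels = np.array(["A"] * 4 + ["B"] * 4)
    return lognormalize(m), labels
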