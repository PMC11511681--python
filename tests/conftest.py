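import numpy as np
import pandas as pd
import pytest

from avekit.expression import ExpressionMatrix
from avekit.simulate import ExpressionSimSpec, simulate_counts
from avekit.expression import normalize_log, select_hvgs


@pytest.fixture(scope="session")
def three_cluster_data():
    """300 cells in 3 well-separated NB clusters, log-normalized, with HVGs."""
    spec = ExpressionSimSpec(n_cells_per_cluster=[100, 100, 100],
                             n_genes=2000, seed=0)
    m, truth = simulate_counts(spec)
    mn = normalize_log(m, method="library")
    hvgs = select_hvgs(mn, n_top=300)
    return mn, truth, hvgs


@pytest.fixture()
def lognorm_matrix():
    """Small deterministic log-normalized matrix builder."""

    def build(values, labels=None):
        values = np.asarray(values, float)
        n, g = values.shape
        meta = None
        if labels is not None:
            meta = pd.DataFrame({"cluster": labels},
                                index=[f"c{i}" for i in range(n)])
        return ExpressionMatrix(values, [f"c{i}" for i in range(n)],
                                [f"g{j}" for j in range(g)],
                                layer="lognorm", cell_metadata=meta)

    return build
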