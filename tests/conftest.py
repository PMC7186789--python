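import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import ercell
from ercell.containers import ExpressionMatrix, make_annotation


def build_matrix(counts, genes=None, cells=None) -> ExpressionMatrix:
    """Dense array -> ExpressionMatrix with auto ids."""
    counts = np.asarray(counts)
    n_g, n_c = counts.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_g)]
    cells = cells if cells is not None else [f"c{j}" for j in range(n_c)]
    return ExpressionMatrix(np.array(genes, dtype=object),
                            np.array(cells, dtype=object),
                            sp.csc_matrix(counts))


def rate_frame(ratios, dN=None, genes=None) -> pd.DataFrame:
    """Minimal filtered rate table from a vector of dN/dS ratios."""
    ratios = np.asarray(ratios, dtype=float)
    dN = np.asarray(dN, dtype=float) if dN is not None else ratios * 0.1
    genes = genes if genes is not None else [f"g{i}" for i in range(len(ratios))]
    df = pd.DataFrame(
        {"dN": dN, "dS": dN / np.where(ratios == 0, 1, ratios),
         "ratio": ratios, "age_label": "unassigned"},
        index=pd.Index(genes, name="gene_id"),
    )
    return df


@pytest.fixture(scope="session")
def filtered_rates_500():
    recs = ercell.simulate_rate_table(500, seed=905)
    return ercell.filter_rates(ercell.collapse_duplicates(recs))


@pytest.fixture
def make_ann():
    return make_annotation
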