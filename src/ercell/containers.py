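"""Shared in-memory containers: expression matrix and cell annotation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class ExpressionMatrix:
    """Sparse gene x cell matrix of non-negative integer counts.

    ``counts`` is stored CSC (cells are columns; per-cell access is the hot
    path). Gene and cell identifiers are parallel to the matrix axes and
    must be unique.
    """

    genes: np.ndarray
    cells: np.ndarray
    counts: sp.csc_matrix = field(repr=False)

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        for name, ids in (("gene", self.genes), ("cell", self.cells)):
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {name} ids")
        if (self.counts.data < 0).any():
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def detected_genes(self) -> np.ndarray:
        """Number of genes with nonzero count per cell."""
        return np.diff(self.counts.indptr)

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.genes[mask], self.cells, self.counts[mask, :])

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.genes, self.cells[mask], self.counts[:, mask])


def make_annotation(
    matrix: ExpressionMatrix,
    cell_type: np.ndarray | str = "unknown",
    tissue: np.ndarray | str = "unknown",
    stage: np.ndarray | str = "",
    stage_ordinal: np.ndarray | int = 0,
) -> pd.DataFrame:
    """Build a per-cell annotation frame aligned to ``matrix.cells``.

    Columns: cell_type, tissue, stage, stage_ordinal, detected_genes.
    """
    n = matrix.n_cells
    df = pd.DataFrame(
        {
            "cell_type": np.broadcast_to(np.asarray(cell_type, dtype=object), n).copy(),
            "tissue": np.broadcast_to(np.asarray(tissue, dtype=object), n).copy(),
            "stage": np.broadcast_to(np.asarray(stage, dtype=object), n).copy(),
            "stage_ordinal": np.broadcast_to(np.asarray(stage_ordinal), n).copy(),
            "detected_genes": matrix.detected_genes(),
        },
        index=pd.Index(matrix.cells, name="cell_id"),
    )
    return df
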