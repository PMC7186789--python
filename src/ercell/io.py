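"""Disk formats: Matrix Market triplets, annotation TSVs, gene sets, truth JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .containers import ExpressionMatrix
from .synthetic import SyntheticTruth


def write_matrix(matrix: ExpressionMatrix, directory) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv (cellranger-style triplet)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(d / "matrix.mtx", sp.coo_matrix(matrix.counts), field="integer")
    (d / "genes.tsv").write_text("\n".join(map(str, matrix.genes)) + "\n")
    (d / "barcodes.tsv").write_text("\n".join(map(str, matrix.cells)) + "\n")


def read_matrix(directory) -> ExpressionMatrix:
    d = Path(directory)
    counts = sp.csc_matrix(sio.mmread(d / "matrix.mtx"))
    genes = np.array((d / "genes.tsv").read_text().split(), dtype=object)
    cells = np.array((d / "barcodes.tsv").read_text().split(), dtype=object)
    return ExpressionMatrix(genes, cells, counts)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="cell_id")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell_id")


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "coupling": truth.coupling,
        "copula_r": truth.copula_r,
        "gene_rate_scores": truth.gene_rate_scores.round(6).to_dict(),
        "age_label": truth.age_label.to_dict(),
        "library_size": truth.library_size.round(3).to_dict(),
        "cell_type": truth.cell_type.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_gene_set(path) -> list[str]:
    """Plain-text gene set, one gene id per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_set(genes, path) -> None:
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, sep="\t", index_label="cell_id")


def read_series_manifest(path) -> pd.DataFrame:
    """TSV of (stage_label, ordinal, matrix_dir, annotation_path)."""
    df = pd.read_csv(path, sep="\t")
    required = {"stage_label", "ordinal", "matrix_dir", "annotation_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"series manifest missing columns: {sorted(missing)}")
    return df.sort_values("ordinal")


def load_series(manifest: pd.DataFrame, root=".") -> list:
    root = Path(root)
    series = []
    for row in manifest.itertuples(index=False):
        matrix = read_matrix(root / row.matrix_dir)
        ann = read_annotation(root / row.annotation_path)
        ann["stage"] = row.stage_label
        ann["stage_ordinal"] = int(row.ordinal)
        series.append((str(row.stage_label), matrix, ann))
    return series
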