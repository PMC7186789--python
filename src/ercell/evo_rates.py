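"""Ortholog evolutionary-rate tables: loading, collapsing, filtering, age labels.

Rates are dN and dS (Ka/Ks) per ortholog pair, typically exported from a
BioMart query with one row per ortholog pair. Genes paired with several
orthologs carry several rows; those are averaged per gene before the
dN/dS ratio is formed, and genes with dS = 0 (ratio undefined) or
dN/dS > 2 (positive selection / alignment artifacts) are discarded
before any correlation is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: age label values used throughout the package
YOUNG, OLD, UNASSIGNED = "young", "old", "unassigned"

DEFAULT_DIALECT = {"gene_id": "Gene stable ID", "dN": "dN", "dS": "dS"}


@dataclass(frozen=True)
class OrthologRateRecord:
    """One ortholog pair: gene identifier with its dN and dS (subs/site)."""

    gene_id: str
    dN: float
    dS: float

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.dN < 0 or self.dS < 0:
            raise ValueError(f"negative rate for {self.gene_id}")


def load_rate_table(path, dialect: dict | None = None) -> list[OrthologRateRecord]:
    """Read a BioMart-style TSV of ortholog dN/dS values.

    ``dialect`` maps the logical names ``gene_id``/``dN``/``dS`` to column
    headers; a header containing the mapped name as a prefix also matches
    (BioMart exports e.g. ``dN with Rat``). Rows with missing or
    unparseable dN or dS are dropped and the drop count logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep="\t", dtype=str)

    def find_col(wanted: str) -> str:
        if wanted in df.columns:
            return wanted
        matches = [c for c in df.columns if c.startswith(wanted)]
        if len(matches) == 1:
            return matches[0]
        raise ValueError(f"cannot map column {wanted!r} in {list(df.columns)}")

    cols = {k: find_col(v) for k, v in dialect.items()}
    sub = df[[cols["gene_id"], cols["dN"], cols["dS"]]].copy()
    sub.columns = ["gene_id", "dN", "dS"]
    sub["dN"] = pd.to_numeric(sub["dN"], errors="coerce")
    sub["dS"] = pd.to_numeric(sub["dS"], errors="coerce")
    ok = sub["dN"].notna() & sub["dS"].notna() & sub["gene_id"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("load_rate_table: dropped %d rows with missing dN/dS", n_dropped)
    return [
        OrthologRateRecord(str(r.gene_id), float(r.dN), float(r.dS))
        for r in sub[ok].itertuples(index=False)
    ]


def collapse_duplicates(records: list[OrthologRateRecord]) -> list[OrthologRateRecord]:
    """Average dN and dS over a gene's ortholog pairs (one record per gene).

    dN and dS are averaged separately; the ratio is formed only after
    averaging (mean(dN)/mean(dS), not the mean of per-pair ratios).
    First-appearance order of genes is preserved.
    """
    sums: dict[str, list[float]] = {}
    for rec in records:
        acc = sums.setdefault(rec.gene_id, [0.0, 0.0, 0])
        acc[0] += rec.dN
        acc[1] += rec.dS
        acc[2] += 1
    return [
        OrthologRateRecord(g, sn / k, ss / k) for g, (sn, ss, k) in sums.items()
    ]


def filter_rates(records: list[OrthologRateRecord]) -> pd.DataFrame:
    """Apply the dS > 0 and dN/dS <= 2 retention rules.

    Returns the rate table: a DataFrame indexed by unique ``gene_id`` with
    columns ``dN``, ``dS``, ``ratio`` (= dN/dS) and ``age_label``
    (initially all ``unassigned``). Removal counts per rule are logged and
    attached as ``table.attrs["removed_ds_zero"]`` / ``["removed_high_ratio"]``.
    """
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "dN": [r.dN for r in records],
            "dS": [r.dS for r in records],
        }
    )
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids: collapse_duplicates first")
    if len(df) == 0:
        df = df.set_index("gene_id")
        df["ratio"] = np.array([], dtype=float)
        df["age_label"] = np.array([], dtype=object)
        df.attrs.update(removed_ds_zero=0, removed_high_ratio=0)
        return df
    ds_zero = df["dS"] == 0
    with np.errstate(divide="ignore"):
        ratio = np.where(ds_zero, np.inf, df["dN"] / df["dS"].where(~ds_zero, 1.0))
    high = ~ds_zero & (ratio > 2)
    n_zero, n_high = int(ds_zero.sum()), int(high.sum())
    logger.info(
        "filter_rates: removed %d genes with dS=0, %d with dN/dS>2", n_zero, n_high
    )
    keep = ~ds_zero & ~high
    out = df[keep].copy()
    out["ratio"] = out["dN"] / out["dS"]
    out["age_label"] = UNASSIGNED
    out = out.set_index("gene_id")
    out.attrs.update(removed_ds_zero=n_zero, removed_high_ratio=n_high)
    return out


def assign_gene_age(
    table: pd.DataFrame, ages: pd.DataFrame, young_branch_threshold: int = 8
) -> pd.DataFrame:
    """Label genes young/old by phylogenetic branch of origin.

    ``ages`` is a DataFrame with columns ``gene_id`` and ``branch``
    (1-based branch index along the vertebrate tree, higher = more recent).
    A gene is ``young`` when branch >= threshold (default 8,
    i.e. lineage-specific), ``old`` when below, ``unassigned`` when it has
    no age record.
    """
    if young_branch_threshold < 1:
        raise ValueError("young_branch_threshold must be >= 1")
    if (ages["branch"] < 1).any():
        raise ValueError("branch indices must be >= 1")
    branch = ages.set_index("gene_id")["branch"]
    if branch.index.duplicated().any():
        raise ValueError("duplicate gene_ids in age table")
    out = table.copy()
    aligned = branch.reindex(out.index)
    out["age_label"] = np.where(
        aligned.isna(),
        UNASSIGNED,
        np.where(aligned >= young_branch_threshold, YOUNG, OLD),
    )
    return out


def write_rate_table(table: pd.DataFrame, path) -> None:
    """Write the filtered table as TSV (gene_id, dN, dS, ratio, age_label)."""
    table.to_csv(path, sep="\t", index_label="gene_id")


def read_filtered_rate_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_rate_table`."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "age_label" not in df.columns:
        df["age_label"] = UNASSIGNED
    return df
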