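"""Per-cell expression-evolutionary-rate (E-R) statistics.

The central quantity is the Spearman correlation, within one cell, between
the expression counts of the cell's detected genes and those genes'
evolutionary rates (dN, and dN/dS as the headline statistic). A negative
value -- the E-R anticorrelation -- indicates that the cell's transcriptome
is dominated by slowly evolving genes, i.e. is under evolutionary
constraint. Because deeper-sequenced cells detect more genes and show
systematically stronger anticorrelation, a depth-corrected statistic (the
residual from an OLS regression of the per-cell coefficient on the
detected-gene count) is used for all between-group comparisons.
"""

from __future__ import annotations

import logging
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, make_annotation

logger = logging.getLogger(__name__)

#: below this sample size the Spearman p-value is computed by exhaustive
#: enumeration of orderings instead of the t approximation
EXACT_P_MAX_N = 10


def _midranks(x: np.ndarray) -> np.ndarray:
    return st.rankdata(x, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("constant input: correlation undefined")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all orderings of one rank vector."""
    n = len(rx)
    perms = np.array(list(permutations(rx)))
    pc = perms - perms.mean(axis=1, keepdims=True)
    yc = ry - ry.mean()
    denom = np.sqrt((pc[0] @ pc[0]) * (yc @ yc))
    rhos = (pc @ yc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman correlation (Pearson of mid-ranks) with a two-sided p-value.

    Ties receive average ranks. For n < 10 the p-value is exact (all
    orderings enumerated); otherwise the usual t approximation with
    n - 2 degrees of freedom is used. Raises on constant input or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    rho = _pearson(rx, ry)
    if n < EXACT_P_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    elif abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * st.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def filter_cells(
    matrix: ExpressionMatrix,
    min_detected: int = 200,
    annotation: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove shallow cells, then orphan genes.

    Cells with fewer than ``min_detected`` expressed (nonzero) genes are
    removed; genes expressed in no retained cell are then dropped. The
    returned annotation is the input one restricted to retained cells with
    ``detected_genes`` recomputed, or a fresh minimal one.
    """
    if min_detected < 0:
        raise ValueError("min_detected must be >= 0")
    detected = matrix.detected_genes()
    keep_cells = detected >= min_detected
    n_removed = int((~keep_cells).sum())
    if not keep_cells.any():
        raise ValueError(
            f"all {matrix.n_cells} cells fall below min_detected={min_detected} "
            f"(max detected = {detected.max() if len(detected) else 0})"
        )
    if n_removed:
        logger.info("filter_cells: removed %d cells below %d detected genes",
                    n_removed, min_detected)
    out = matrix.subset_cells(keep_cells)
    gene_nnz = np.diff(out.counts.tocsr().indptr)
    keep_genes = gene_nnz > 0
    if (~keep_genes).any():
        logger.info("filter_cells: dropped %d genes expressed in no retained cell",
                    int((~keep_genes).sum()))
        out = out.subset_genes(keep_genes)
    if annotation is None:
        ann = make_annotation(out)
    else:
        ann = annotation.loc[out.cells].copy()
        ann["detected_genes"] = out.detected_genes()
    return out, ann


def _aligned_rates(matrix: ExpressionMatrix, rates: pd.DataFrame):
    """dN / ratio arrays aligned to matrix genes; NaN where no rate."""
    dN = rates["dN"].reindex(matrix.genes).to_numpy(dtype=float)
    ratio = rates["ratio"].reindex(matrix.genes).to_numpy(dtype=float)
    n_missing = int(np.isnan(ratio).sum())
    if n_missing:
        logger.info("%d/%d genes lack evolutionary rates and are excluded",
                    n_missing, matrix.n_genes)
    return dN, ratio


def er_profiles(
    matrix: ExpressionMatrix,
    rates: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Per-cell E-R profile for every cell of the matrix.

    For each cell the correlation uses only genes that are detected
    (nonzero) in that cell AND present in the rate table. Cells with fewer
    than ``min_genes`` usable genes, or a degenerate (constant) vector, are
    flagged ``valid = False`` and excluded downstream.

    Returns a DataFrame indexed by cell_id with columns rho_dN, rho_ratio,
    p_dN, p_ratio, adj_p_ratio (BH across the dataset's valid cells),
    n_genes_used, valid, plus detected_genes and any annotation columns.
    """
    dN, ratio = _aligned_rates(matrix, rates)
    csc = matrix.counts
    rows = {}
    for j, cell in enumerate(matrix.cells):
        sl = slice(csc.indptr[j], csc.indptr[j + 1])
        idx = csc.indices[sl]
        vals = csc.data[sl].astype(float)
        usable = ~np.isnan(ratio[idx])
        x = vals[usable]
        yr = ratio[idx[usable]]
        yd = dN[idx[usable]]
        rec = dict(rho_dN=np.nan, rho_ratio=np.nan, p_dN=np.nan, p_ratio=np.nan,
                   n_genes_used=int(len(x)), valid=False)
        if len(x) >= min_genes:
            try:
                rec["rho_ratio"], rec["p_ratio"] = spearman_rho(x, yr)
                rec["rho_dN"], rec["p_dN"] = spearman_rho(x, yd)
                rec["valid"] = True
            except ValueError:
                pass
        rows[cell] = rec
    prof = pd.DataFrame.from_dict(rows, orient="index")
    prof.index.name = "cell_id"
    prof["adj_p_ratio"] = np.nan
    valid = prof["valid"].to_numpy()
    if valid.any():
        prof.loc[valid, "adj_p_ratio"] = adjust_pvalues(
            prof.loc[valid, "p_ratio"].to_numpy()
        )
    prof["detected_genes"] = matrix.detected_genes()
    if annotation is not None:
        for col in ("cell_type", "tissue", "stage", "stage_ordinal"):
            if col in annotation.columns:
                prof[col] = annotation.loc[prof.index, col]
    return prof


def cell_er_profile(
    matrix: ExpressionMatrix, rates: pd.DataFrame, cell_id, min_genes: int = 3
) -> pd.Series:
    """E-R profile of a single cell (row of :func:`er_profiles`)."""
    (j,) = np.nonzero(matrix.cells == cell_id)
    if len(j) == 0:
        raise KeyError(cell_id)
    sub = matrix.subset_cells(np.isin(np.arange(matrix.n_cells), j))
    return er_profiles(sub, rates, min_genes=min_genes).iloc[0]


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method != "BH":
        raise ValueError(f"unsupported adjustment method {method!r}")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def correct_for_depth(profiles: pd.DataFrame, keep_level: bool = False) -> pd.DataFrame:
    """Regress rho_ratio on detected-gene count; residual = corrected value.

    One OLS fit over all valid cells of the dataset (types pooled, so
    between-type differences are preserved). With ``keep_level`` the fitted
    grand mean is added back (value = rho adjusted to the average depth),
    which preserves the sign and level of the anticorrelation; the default
    returns plain residuals (centred at 0).

    Degenerate case: if every cell has the same detected-gene count the
    values are mean-centred with a warning instead of failing.
    """
    prof = profiles.copy()
    valid = prof["valid"].to_numpy(dtype=bool)
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid profiles for depth correction")
    d = prof.loc[valid, "detected_genes"].to_numpy(dtype=float)
    rho = prof.loc[valid, "rho_ratio"].to_numpy(dtype=float)
    if np.ptp(d) == 0:
        logger.warning("all cells have equal detected-gene counts; mean-centering")
        fitted = np.full_like(rho, rho.mean())
    else:
        slope, intercept = np.polyfit(d, rho, 1)
        fitted = intercept + slope * d
    resid = rho - fitted
    if keep_level:
        resid = resid + rho.mean()
    prof["corrected"] = np.nan
    prof.loc[valid, "corrected"] = resid
    return prof


def significant_profiles(
    profiles: pd.DataFrame, alpha: float = 0.05, require_negative: bool = True
) -> pd.DataFrame:
    """Cells whose E-R anticorrelation is significant.

    Keeps valid cells with BH-adjusted p <= alpha; by default cells with a
    significantly *positive* rho are also dropped, since the retained
    quantity is an anticorrelation.
    """
    keep = profiles["valid"] & (profiles["adj_p_ratio"] <= alpha)
    if require_negative:
        keep &= profiles["rho_ratio"] < 0
    return profiles[keep]
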