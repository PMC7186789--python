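"""Permutation nulls, group comparisons, constraint ranking, gene-set effects.

The permutation null for a cell subtype breaks the pairing between the
subtype's mean-expression profile and the gene-wise evolutionary rates:
gene identity of the expression vector is shuffled uniformly without
replacement (both marginals preserved) and the Spearman coefficient
recomputed. Significance is assessed in the anticorrelation tail
(null rho <= observed rho) with the add-one rule, so the empirical p is
never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _iter_permutations
from math import factorial

import numpy as np
import pandas as pd
import scipy.stats as st

from .containers import ExpressionMatrix
from .er import adjust_pvalues, er_profiles, spearman_rho

logger = logging.getLogger(__name__)


@dataclass
class SubtypeProfile:
    """Per-gene mean expression across one subtype's cells (zeros included)."""

    subtype: str
    genes: np.ndarray
    mean_expression: np.ndarray
    n_cells: int


@dataclass
class PermutationResult:
    subtype: str
    observed_rho: float
    null_rhos: np.ndarray
    empirical_p: float
    exhaustive: bool = False


@dataclass
class ComparisonResult:
    """Outcome of a rank-based group comparison."""

    groups: tuple
    statistic: float
    pvalue: float
    test: str
    alternative: str = "two-sided"

    @property
    def direction(self) -> str:
        return self.alternative


def subtype_mean_profiles(
    matrix: ExpressionMatrix, annotation: pd.DataFrame, by: str = "cell_type"
) -> list[SubtypeProfile]:
    """Mean count per gene for each subtype (arithmetic mean, zeros included)."""
    labels = annotation.loc[matrix.cells, by].to_numpy()
    profiles = []
    for subtype in pd.unique(labels):
        mask = labels == subtype
        if not mask.any():
            logger.warning("subtype %s has no cells; omitted", subtype)
            continue
        mean = np.asarray(matrix.counts[:, mask].mean(axis=1)).ravel()
        profiles.append(
            SubtypeProfile(str(subtype), matrix.genes, mean, int(mask.sum()))
        )
    return profiles


def permutation_null(
    profile: SubtypeProfile,
    rates: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation null of the subtype's E-R coefficient against dN/dS.

    Shuffles the gene assignment of the mean-expression vector and
    recomputes the Spearman coefficient. empirical_p =
    (1 + #{null <= observed}) / (1 + n_perm). In exhaustive mode (only for
    <= 8 genes) all n! orderings are enumerated and the p is the exact
    fraction of orderings at or below the observed value.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    ratio = rates["ratio"].reindex(profile.genes).to_numpy(dtype=float)
    usable = ~np.isnan(ratio)
    x = profile.mean_expression[usable]
    y = ratio[usable]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 genes with rates")
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    if denom == 0:
        raise ValueError("constant profile or rates: correlation undefined")
    observed = float((rxc @ ryc) / denom)
    tol = 1e-12
    if exhaustive:
        if factorial(n) > 50_000:
            raise ValueError("exhaustive mode supported only for <= 8 genes")
        perms = np.array(list(_iter_permutations(rxc)))
        null = (perms @ ryc) / denom
        p = float(np.mean(null <= observed + tol))
    else:
        rng = np.random.default_rng(seed)
        idx = rng.permuted(
            np.broadcast_to(np.arange(n), (n_perm, n)).copy(), axis=1
        )
        null = (rxc[idx] @ ryc) / denom
        p = float((1 + np.sum(null <= observed + tol)) / (1 + n_perm))
    return PermutationResult(profile.subtype, observed, null, p, exhaustive)


_TESTS = {"wilcoxon_one_sided", "wilcoxon_two_sided", "kruskal_wallis"}


def compare_groups(
    groups: dict[str, np.ndarray],
    test: str = "wilcoxon_two_sided",
    alternative: str = "less",
) -> ComparisonResult:
    """Rank-based comparison of independent groups.

    ``wilcoxon_*`` is the rank-sum (Mann-Whitney) test on two groups --
    for one-sided, ``alternative`` states the direction of the first group
    relative to the second (``"less"`` = first shifted toward smaller
    values). ``kruskal_wallis`` compares any number of groups.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}")
    names = tuple(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    if test == "kruskal_wallis":
        if len(arrays) < 2:
            raise ValueError("kruskal_wallis needs >= 2 groups")
        if np.ptp(np.concatenate(arrays)) == 0:
            stat, p = 0.0, 1.0  # all observations tied: no evidence of difference
        else:
            stat, p = st.kruskal(*arrays)
        return ComparisonResult(names, float(stat), float(p), test, "two-sided")
    if len(arrays) != 2:
        raise ValueError("wilcoxon comparison needs exactly 2 groups")
    alt = alternative if test == "wilcoxon_one_sided" else "two-sided"
    res = st.mannwhitneyu(arrays[0], arrays[1], alternative=alt)
    return ComparisonResult(names, float(res.statistic), float(res.pvalue), test, alt)


def rank_cell_types(
    corrected: pd.Series, cell_type: pd.Series, min_cells: int = 2
) -> tuple[list[tuple[str, float]], pd.DataFrame]:
    """Order cell types by median corrected E-R value, most constrained first.

    Returns the ordered (type, median) list -- increasing median, i.e. most
    negative (strongest anticorrelation) first -- and a square DataFrame of
    one-sided rank-sum p-values testing row-type < column-type. Types with
    fewer than ``min_cells`` cells are excluded with a warning.
    """
    df = pd.DataFrame({"corrected": corrected, "cell_type": cell_type}).dropna()
    sizes = df.groupby("cell_type").size()
    small = sizes[sizes < min_cells].index
    for t in small:
        logger.warning("cell type %s has < %d cells; excluded from ranking", t, min_cells)
    df = df[~df["cell_type"].isin(small)]
    if df["cell_type"].nunique() == 0:
        raise ValueError("no cell types with enough cells")
    medians = df.groupby("cell_type")["corrected"].median().sort_values()
    order = list(medians.index)
    pmat = pd.DataFrame(np.nan, index=order, columns=order)
    for a in order:
        for b in order:
            if a == b:
                continue
            res = compare_groups(
                {a: df.loc[df.cell_type == a, "corrected"],
                 b: df.loc[df.cell_type == b, "corrected"]},
                test="wilcoxon_one_sided", alternative="less",
            )
            pmat.loc[a, b] = res.pvalue
    return list(medians.items()), pmat


def upregulated_genes(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    target_group: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    by: str = "cell_type",
    eps: float = 1e-9,
) -> list[str]:
    """Genes upregulated in ``target_group`` versus all other cells.

    A gene is selected iff (mean_target + eps)/(mean_rest + eps) is
    strictly greater than ``fc_threshold`` and its BH-adjusted one-tailed
    rank-sum p (target > rest, across cells) is <= alpha.
    """
    labels = annotation.loc[matrix.cells, by].to_numpy()
    in_target = labels == target_group
    if not in_target.any() or in_target.all():
        raise ValueError("target group and its complement must both be non-empty")
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    tgt, rest = dense[:, in_target], dense[:, ~in_target]
    fc = (tgt.mean(axis=1) + eps) / (rest.mean(axis=1) + eps)
    pvals = np.empty(matrix.n_genes)
    for g in range(matrix.n_genes):
        if np.ptp(dense[g]) == 0:
            pvals[g] = 1.0
            continue
        pvals[g] = st.mannwhitneyu(
            tgt[g], rest[g], alternative="greater", method="asymptotic"
        ).pvalue
    adj = adjust_pvalues(pvals)
    sel = (fc > fc_threshold) & (adj <= alpha)
    return list(matrix.genes[sel])


@dataclass
class GeneSetRemovalResult:
    """Per-cell E-R coefficients before/after excluding a gene set."""

    rho_before: pd.Series
    rho_after: pd.Series
    ratio_test: ComparisonResult
    dN_test: ComparisonResult
    n_cells_excluded: int


def gene_set_removal_effect(
    matrix: ExpressionMatrix,
    rates: pd.DataFrame,
    annotation: pd.DataFrame,
    gene_set,
    min_genes: int = 3,
) -> GeneSetRemovalResult:
    """Effect of excluding a gene set on the per-cell E-R anticorrelation.

    Recomputes each cell's rho (vs dN and vs dN/dS) with the set removed
    and runs a paired one-sided signed-rank test of whether the
    anticorrelation weakens (rho increases toward 0) after removal. Cells
    left without enough usable genes are excluded and counted.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    before = er_profiles(matrix, rates, annotation, min_genes=min_genes)
    keep = ~np.isin(matrix.genes, list(gene_set))
    after = er_profiles(matrix.subset_genes(keep), rates, annotation,
                        min_genes=min_genes)
    both = before["valid"] & after["valid"]
    n_excluded = int((~both & before["valid"]).sum())
    if n_excluded:
        logger.info("gene_set_removal_effect: %d cells lost usable genes", n_excluded)
    if both.sum() < 3:
        raise ValueError("fewer than 3 cells with valid before/after profiles")
    results = {}
    for col in ("rho_ratio", "rho_dN"):
        b = before.loc[both, col].to_numpy()
        a = after.loc[both, col].to_numpy()
        stat, p = st.wilcoxon(a, b, alternative="greater")
        results[col] = ComparisonResult(
            ("after_removal", "before_removal"), float(stat), float(p),
            "wilcoxon_signed_rank", "greater",
        )
    return GeneSetRemovalResult(
        before.loc[both, "rho_ratio"], after.loc[both, "rho_ratio"],
        results["rho_ratio"], results["rho_dN"], n_excluded,
    )
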