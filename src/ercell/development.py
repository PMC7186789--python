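"""Developmental trajectories of evolutionary constraint.

A stage series is a list of (stage_label, matrix, annotation) covering an
ordered developmental axis (ordinals supplied explicitly in the
annotation -- labels like "8 pcw" or "2 y" are never parsed). Per stage
the full per-cell pipeline runs (cell filtering, Spearman coefficients,
depth adjustment) and the series-level trend is the Spearman correlation
of stage ordinal with the stage's median depth-adjusted E-R value.

Depth handling: by default one OLS fit of rho on detected-gene count is
shared across the whole series and the adjustment preserves the level of
the statistic (rho moved to the series' mean depth). Pure within-stage
residuals would centre every stage at zero and erase the cross-stage
signal the trend is meant to measure; a per-stage residual mode is kept
for series where stages come from incomparable platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evo_rates
from .containers import ExpressionMatrix
from .er import er_profiles, filter_cells, spearman_rho
from .permutation import ComparisonResult, compare_groups

logger = logging.getLogger(__name__)


@dataclass
class StageSummary:
    stage: str
    ordinal: int
    n_cells: int
    mean_corrected: float
    median_corrected: float
    young_mean: float = np.nan
    old_mean: float = np.nan
    young_vs_old: ComparisonResult | None = None


@dataclass
class TrajectoryResult:
    summaries: list[StageSummary]
    trend_rho: float
    trend_p: float
    degenerate_trend: bool  # 2-stage series: trend is +/-1 by construction

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stage": s.stage, "ordinal": s.ordinal, "n_cells": s.n_cells,
                "mean_corrected": s.mean_corrected,
                "median_corrected": s.median_corrected,
                "young_mean": s.young_mean, "old_mean": s.old_mean,
                "young_vs_old_p": s.young_vs_old.pvalue if s.young_vs_old else np.nan,
            }
            for s in self.summaries
        ]
        return pd.DataFrame(rows)


def stage_trajectory(
    series: list[tuple[str, ExpressionMatrix, pd.DataFrame]],
    rates: pd.DataFrame,
    min_detected: int = 200,
    min_cells: int = 3,
    depth_fit: str = "pooled",
    summary: str = "median",
) -> TrajectoryResult:
    """Stage-wise depth-adjusted E-R summaries and the cross-stage trend.

    depth_fit: "pooled" (default) fits one rho-vs-detected regression over
    all stages and subtracts the slope term only, keeping each cell's level;
    "per_stage" takes plain within-stage OLS residuals (stage medians then
    centre near zero; the trend is not meaningful in that mode).
    summary: per-stage summary statistic for the trend, "median" or "mean".
    """
    if len(series) < 2:
        raise ValueError("need at least 2 stages")
    if depth_fit not in ("pooled", "per_stage"):
        raise ValueError(f"unknown depth_fit {depth_fit!r}")
    per_stage = []
    for label, matrix, ann in series:
        try:
            fmat, fann = filter_cells(matrix, min_detected, ann)
        except ValueError:
            logger.warning("stage %s: all cells below min_detected; dropped", label)
            continue
        prof = er_profiles(fmat, rates, fann)
        prof = prof[prof["valid"]]
        if len(prof) < min_cells:
            logger.warning("stage %s: < %d valid cells; dropped", label, min_cells)
            continue
        ordinal = int(fann["stage_ordinal"].iloc[0])
        per_stage.append((label, ordinal, prof))
    if len(per_stage) < 2:
        raise ValueError("fewer than 2 stages survive filtering")

    if depth_fit == "pooled":
        all_rho = np.concatenate([p["rho_ratio"].to_numpy() for _, _, p in per_stage])
        all_det = np.concatenate(
            [p["detected_genes"].to_numpy(dtype=float) for _, _, p in per_stage]
        )
        if np.ptp(all_det) == 0:
            slope, center = 0.0, all_det[0]
            logger.warning("constant detected-gene counts; no depth slope removed")
        else:
            slope, _ = np.polyfit(all_det, all_rho, 1)
            center = all_det.mean()

    summaries = []
    for label, ordinal, prof in per_stage:
        rho = prof["rho_ratio"].to_numpy()
        det = prof["detected_genes"].to_numpy(dtype=float)
        if depth_fit == "pooled":
            corrected = rho - slope * (det - center)
        else:
            if np.ptp(det) == 0:
                corrected = rho - rho.mean()
            else:
                s, b = np.polyfit(det, rho, 1)
                corrected = rho - (b + s * det)
        summaries.append(
            StageSummary(
                stage=label, ordinal=ordinal, n_cells=len(prof),
                mean_corrected=float(corrected.mean()),
                median_corrected=float(np.median(corrected)),
            )
        )
    summaries.sort(key=lambda s: s.ordinal)
    ordinals = [s.ordinal for s in summaries]
    if len(set(ordinals)) != len(ordinals):
        raise ValueError("stage ordinals must be strictly increasing / unique")
    values = [getattr(s, f"{summary}_corrected") for s in summaries]
    degenerate = len(summaries) == 2
    if degenerate:
        # two points: the rank trend is +/-1 by construction, p uninformative
        logger.warning("2-stage series: trend statistic is +/-1 by construction")
        diff = values[1] - values[0]
        trend_rho = np.nan if diff == 0 else float(np.sign(diff))
        trend_p = np.nan
    else:
        try:
            trend_rho, trend_p = spearman_rho(ordinals, values)
        except ValueError:  # constant stage summaries: no trend to speak of
            trend_rho, trend_p = np.nan, np.nan
    return TrajectoryResult(summaries, trend_rho, trend_p, degenerate)


def age_expression_by_stage(
    series: list[tuple[str, ExpressionMatrix, pd.DataFrame]],
    rates: pd.DataFrame,
    min_detected: int = 0,
) -> list[StageSummary]:
    """Young- vs old-gene expression per stage.

    Per stage, each gene's mean count across the stage's cells (zeros
    included) is computed; genes are split by the rate table's age label
    and compared with a one-sided rank-sum test of young > old. Raises if
    either age class is empty among genes shared with the rate table.
    """
    age = rates["age_label"]
    out = []
    for label, matrix, ann in series:
        if min_detected > 0:
            matrix, ann = filter_cells(matrix, min_detected, ann)
        labels = age.reindex(matrix.genes)
        young_mask = (labels == evo_rates.YOUNG).to_numpy()
        old_mask = (labels == evo_rates.OLD).to_numpy()
        for name, mask in (("young", young_mask), ("old", old_mask)):
            if not mask.any():
                raise ValueError(f"no {name} genes present at stage {label}")
        mean_expr = np.asarray(matrix.counts.mean(axis=1)).ravel()
        res = compare_groups(
            {"young": mean_expr[young_mask], "old": mean_expr[old_mask]},
            test="wilcoxon_one_sided", alternative="greater",
        )
        out.append(
            StageSummary(
                stage=label, ordinal=int(ann["stage_ordinal"].iloc[0]),
                n_cells=matrix.n_cells,
                mean_corrected=np.nan, median_corrected=np.nan,
                young_mean=float(mean_expr[young_mask].mean()),
                old_mean=float(mean_expr[old_mask].mean()),
                young_vs_old=res,
            )
        )
    out.sort(key=lambda s: s.ordinal)
    return out
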