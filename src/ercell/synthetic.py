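"""Synthetic single-cell data with known expression-rate coupling.

Every downstream stage of the pipeline is exercised against data whose
ground truth is known by construction. The generator imposes a target
Spearman correlation between a gene's dN/dS and its latent log expression
through a Gaussian copula: the rate axis enters as the deterministic
normal scores of the dN/dS ranks, and each cell's latent log-expression is

    z_gc = r * z_rate_g + sqrt(1 - r^2) * eps_gc,   eps_gc ~ N(0, 1) iid,

with r = 2 sin(pi * rho_s / 6), the inverse of the Gaussian-copula rank
correlation identity rho_s = (6/pi) asin(r/2). Counts are Poisson around
library-size-scaled softmax means, so each cell's realized per-cell
Spearman fluctuates independently around rho_s and is attenuated by
counting noise, zero truncation, and dropout -- the same mechanisms that
weaken the statistic in real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from scipy.special import ndtri

from . import evo_rates
from .containers import ExpressionMatrix, make_annotation


@dataclass(frozen=True)
class CellTypeSpec:
    """One simulated cell type.

    target_spearman is the population Spearman between dN/dS and latent
    log-mean expression (negative = constrained); mean_library_size is the
    expected total count per cell (cell sizes are log-normal around it).
    """

    name: str
    n_cells: int
    target_spearman: float
    mean_library_size: float = 50_000.0
    tissue: str = "sim"
    log_mean_shift: np.ndarray | None = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if not -1.0 <= self.target_spearman <= 1.0:
            raise ValueError("|target_spearman| must be <= 1")
        if self.mean_library_size <= 0:
            raise ValueError("mean_library_size must be positive")


@dataclass(frozen=True)
class StageSpec:
    """One developmental stage: label, ordinal position, coupling, fetal flag."""

    label: str
    ordinal: int
    coupling: float
    fetal: bool = False


@dataclass
class SimulationDesign:
    """Full description of a simulated dataset.

    sigma_log sets the spread of latent log-means (natural-log scale);
    library_sigma the log-normal spread of per-cell library sizes;
    dropout_strength the expression scale of excess zeros (0 = none;
    an entry of Poisson mean mu is zeroed with probability
    exp(-mu / dropout_strength)).
    """

    n_genes: int
    cell_types: list[CellTypeSpec]
    seed: int = 0
    sigma_log: float = 1.5
    library_sigma: float = 0.25
    dropout_strength: float = 0.0
    stages: list[StageSpec] = field(default_factory=list)
    young_gene_fraction: float = 0.15
    young_fetal_boost: float = 0.0

    def __post_init__(self):
        if not self.cell_types:
            raise ValueError("at least one cell type required")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.dropout_strength < 0:
            raise ValueError("dropout_strength must be >= 0")
        if not 0.0 <= self.young_gene_fraction <= 1.0:
            raise ValueError("young_gene_fraction must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulated matrix."""

    coupling: dict[str, float]          # per cell type: target Spearman
    copula_r: dict[str, float]          # per cell type: latent Gaussian corr
    gene_rate_scores: pd.Series         # per gene: normal score of dN/dS rank
    age_label: pd.Series                # per gene
    library_size: pd.Series             # per cell: drawn library size
    cell_type: pd.Series                # per cell


def spearman_to_copula_r(rho_s: float) -> float:
    """Latent Gaussian correlation giving population Spearman rho_s."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def simulate_rate_table(
    n_genes: int,
    seed: int = 0,
    frac_ds_zero: float = 0.0,
    frac_high_ratio: float = 0.0,
) -> list[evo_rates.OrthologRateRecord]:
    """Pre-filter rate records with controlled filter-rule violations.

    dS is gamma-distributed (right-skewed, strictly positive) and dN/dS is
    drawn on (0, 2] so that ordinary rows always survive filtering; exactly
    round(frac_ds_zero * n) rows get dS = 0 and round(frac_high_ratio * n)
    disjoint rows get dN/dS > 2, making filter behavior exactly countable.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    for f in (frac_ds_zero, frac_high_ratio):
        if not 0.0 <= f < 1.0:
            raise ValueError("fractions must lie in [0, 1)")
    if frac_ds_zero + frac_high_ratio >= 1.0:
        raise ValueError("violation fractions must sum to < 1")
    rng = np.random.default_rng(seed)
    dS = rng.gamma(shape=3.0, scale=0.05, size=n_genes) + 1e-4
    ratio = 2.0 * rng.beta(1.5, 6.0, size=n_genes)
    dN = ratio * dS
    n_zero = round(frac_ds_zero * n_genes)
    n_high = round(frac_high_ratio * n_genes)
    chosen = rng.choice(n_genes, size=n_zero + n_high, replace=False)
    dS[chosen[:n_zero]] = 0.0
    high_idx = chosen[n_zero:]
    dN[high_idx] = dS[high_idx] * (2.0 + rng.gamma(1.0, 0.5, size=n_high) + 1e-6)
    width = len(str(n_genes))
    return [
        evo_rates.OrthologRateRecord(f"g{i:0{width}d}", float(dN[i]), float(dS[i]))
        for i in range(n_genes)
    ]


def simulate_gene_ages(
    gene_ids, seed: int = 0, young_fraction: float = 0.15,
    young_branch_threshold: int = 8, max_branch: int = 12,
) -> pd.DataFrame:
    """Gene-age table with a given fraction of young (recent-branch) genes.

    Age is assigned independently of the rates, so under no fetal boost
    young and old genes are exchangeable in expression.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    rng = np.random.default_rng(seed)
    n = len(gene_ids)
    n_young = round(young_fraction * n)
    young = np.zeros(n, dtype=bool)
    young[rng.choice(n, size=n_young, replace=False)] = True
    branch = np.where(
        young,
        rng.integers(young_branch_threshold, max_branch + 1, size=n),
        rng.integers(1, young_branch_threshold, size=n),
    )
    return pd.DataFrame({"gene_id": gene_ids, "branch": branch})


def _rate_normal_scores(rates: pd.DataFrame) -> np.ndarray:
    ranks = st.rankdata(rates["ratio"].to_numpy(), method="average")
    return ndtri((ranks - 0.5) / len(ranks))


def simulate_expression(
    design: SimulationDesign,
    rates: pd.DataFrame,
    rng: np.random.Generator | None = None,
    extra_log_shift: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a count matrix with the designed per-type E-R coupling.

    ``rates`` must be the filtered rate table whose length equals
    ``design.n_genes``; its dN/dS ranks define the copula's rate axis.
    ``extra_log_shift`` (length n_genes) is added to every cell's latent
    log-mean -- the hook used for stage-specific young-gene boosts.
    Deterministic for a fixed design seed.
    """
    if len(rates) != design.n_genes:
        raise ValueError(
            f"rate table has {len(rates)} genes, design expects {design.n_genes}"
        )
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n = design.n_genes
    z_rate = _rate_normal_scores(rates)
    shift_common = np.zeros(n) if extra_log_shift is None else np.asarray(extra_log_shift)

    blocks, cell_ids, type_labels, tissues, libsizes = [], [], [], [], []
    coupling, copula_r = {}, {}
    for ct in design.cell_types:
        r = spearman_to_copula_r(ct.target_spearman)
        coupling[ct.name] = ct.target_spearman
        copula_r[ct.name] = r
        shift = shift_common if ct.log_mean_shift is None else (
            shift_common + np.asarray(ct.log_mean_shift)
        )
        mu_lib = np.log(ct.mean_library_size) - design.library_sigma**2 / 2
        cols = np.empty((n, ct.n_cells), dtype=np.int64)
        for c in range(ct.n_cells):
            eps = rng.standard_normal(n)
            z = r * z_rate + np.sqrt(1.0 - r * r) * eps
            logw = design.sigma_log * z + shift
            w = np.exp(logw - logw.max())
            L = rng.lognormal(mean=mu_lib, sigma=design.library_sigma)
            lam = L * (w / w.sum())
            counts = rng.poisson(lam)
            if design.dropout_strength > 0:
                drop = rng.random(n) < np.exp(-lam / design.dropout_strength)
                counts[drop] = 0
            cols[:, c] = counts
            libsizes.append(L)
        blocks.append(sp.csc_matrix(cols))
        cell_ids.extend(f"{ct.name}_c{c:04d}" for c in range(ct.n_cells))
        type_labels.extend([ct.name] * ct.n_cells)
        tissues.extend([ct.tissue] * ct.n_cells)

    matrix = ExpressionMatrix(
        genes=rates.index.to_numpy(dtype=object),
        cells=np.array(cell_ids, dtype=object),
        counts=sp.hstack(blocks, format="csc"),
    )
    annotation = make_annotation(
        matrix,
        cell_type=np.array(type_labels, dtype=object),
        tissue=np.array(tissues, dtype=object),
    )
    truth = SyntheticTruth(
        coupling=coupling,
        copula_r=copula_r,
        gene_rate_scores=pd.Series(z_rate, index=rates.index),
        age_label=rates["age_label"].copy(),
        library_size=pd.Series(np.array(libsizes), index=matrix.cells),
        cell_type=pd.Series(np.array(type_labels, dtype=object), index=matrix.cells),
    )
    return matrix, annotation, truth


def simulate_stage_series(
    design: SimulationDesign, rates: pd.DataFrame
) -> list[tuple[str, ExpressionMatrix, pd.DataFrame]]:
    """One matrix per developmental stage with stage-specific coupling.

    Each stage reuses the design's cell types with target_spearman replaced
    by the stage coupling. At stages flagged fetal, young-labeled genes get
    ``young_fetal_boost`` added to their latent log-mean (the young-gene
    fetal upregulation signal). Per-stage seeds are spawned from the design
    seed, so the whole series is deterministic.
    """
    if len(design.stages) < 2:
        raise ValueError("need at least 2 stages")
    young_mask = (rates["age_label"] == evo_rates.YOUNG).to_numpy()
    seeds = np.random.SeedSequence(design.seed).spawn(len(design.stages))
    series = []
    for stage, ss in zip(design.stages, seeds):
        stage_types = [
            replace(ct, target_spearman=stage.coupling) for ct in design.cell_types
        ]
        stage_design = replace(design, cell_types=stage_types, stages=[])
        shift = (
            design.young_fetal_boost * young_mask.astype(float)
            if stage.fetal and design.young_fetal_boost
            else None
        )
        matrix, ann, _ = simulate_expression(
            stage_design, rates, rng=np.random.default_rng(ss), extra_log_shift=shift
        )
        ann["stage"] = stage.label
        ann["stage_ordinal"] = stage.ordinal
        series.append((stage.label, matrix, ann))
    return series


def coupling_carrier_genes(rates: pd.DataFrame, frac: float = 0.25) -> list[str]:
    """Genes that carry most of a negative E-R coupling.

    Under a negative coupling, the slowest-evolving genes (lowest dN/dS)
    are the most highly expressed; removing the lowest ``frac`` of the
    dN/dS distribution restricts the rate range and weakens the observed
    anticorrelation (range restriction).
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    k = max(1, round(frac * len(rates)))
    order = rates["ratio"].to_numpy().argsort(kind="stable")
    return list(rates.index.to_numpy()[order[:k]])
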