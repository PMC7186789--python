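# Methods

## The statistic

For a cell *c* with counts *x₁…x_G*, let *D(c)* be the set of genes with
*x_g > 0* (the detected genes) that also have an evolutionary-rate record.
The per-cell E–R coefficient is the Spearman correlation over *D(c)*
between the counts and the genes' dN/dS (ρ_ratio; computed against dN in
parallel). Only detected genes enter: a rank correlation over the full gene
universe would be driven mostly by the zero pattern, i.e. by dropout, and
the zeros carry no usable expression ordering. Because Spearman is a rank
statistic, any per-cell scaling (library-size normalisation) or monotone
transform (log(1+x)) leaves ρ unchanged — so no normalisation is applied,
and log-scaled visualisations imply nothing about the computed value. Both
invariances are asserted by property tests.

ρ is the Pearson correlation of mid-ranks (ties receive average ranks).
Two-sided p-values use the t approximation with n − 2 df for n ≥ 10 and
exhaustive enumeration of orderings below that; small synthetic fixtures
sit exactly in the regime where the approximation is poor, which is why the
exact path exists. |ρ| = 1 with n ≥ 10 reports p = 0 (the t statistic
diverges).

## Evolutionary rates

dN and dS come from ortholog-pair tables (BioMart-export style TSV). A gene
with several ortholog pairs gets the arithmetic mean of its dN values and
of its dS values, and the ratio is formed *after* averaging —
mean(dN)/mean(dS), not the mean of per-pair ratios, which would weight
low-dS pairs erratically. Filtering follows collapsing: genes with dS = 0
(ratio undefined) or dN/dS > 2 (positive selection or alignment artifacts)
are discarded, and both removal counts are logged and attached to the
table. Genes absent from the rate table are silently excluded from every
correlation (with a logged count): the statistic is only defined over genes
with rates.

Gene age is a per-gene phylogenetic branch index (1 = oldest). A gene is
"young" when its branch is ≥ the threshold (default 8, lineage-specific),
"old" below, "unassigned" if absent from the age table.

## Depth correction

Detected-gene count confounds ρ: deeper cells detect more genes, suffer
less zero-truncation, and show stronger anticorrelation. The corrected
value is the residual of an OLS regression of ρ_ratio on detected-gene
count, fitted once per dataset with all cell types pooled — a per-type fit
would absorb exactly the between-type differences under study. Residuals
are exactly orthogonal to the covariate (asserted to 1e-10). If every cell
has the same depth (a degenerate synthetic case) the values are
mean-centred with a warning rather than failing.

In developmental series the default is likewise a single pooled fit across
all stages, but only the slope term is subtracted
(ρ − b·(detected − mean detected)), preserving each cell's level. Pure
within-stage residuals would centre every stage at zero and erase the
cross-stage signal the trend statistic measures; the `per_stage` mode that
does exactly that is kept for series whose stages come from incomparable
platforms, with the caveat that its stage medians are not trend-comparable.
The trend itself is the Spearman correlation of stage ordinal with the
stage median (configurably mean) of the adjusted values; stage order is
always taken from an explicit ordinal column, never parsed from labels. A
2-stage series yields a trend of ±1 by construction and is flagged
degenerate.

## Permutation null

The null for a subtype breaks the gene–rate pairing: the subtype's mean
expression vector (arithmetic mean per gene over the subtype's cells,
zeros included) has its gene assignment permuted uniformly without
replacement, preserving both marginals, and ρ is recomputed. Resampling
*with* replacement would distort the expression marginal. The empirical p
for the anticorrelation tail uses the add-one rule,
p = (1 + #{ρ_null ≤ ρ_obs}) / (1 + n_perm), so p > 0 always; with ≤ 8 genes
an exhaustive mode enumerates all n! orderings and returns the exact
fraction. Default n_perm is 10,000.

## Group comparisons

Comparisons between disjoint cell groups use the rank-sum (Mann–Whitney)
test — a signed-rank test is undefined for unpaired groups — with
Kruskal–Wallis for multi-group comparisons; the paired signed-rank form is
used only for the gene-set removal effect, where before/after values are
paired per cell. Cell types are ranked by increasing median corrected value
(most negative = most constrained first) with all one-sided pairwise
p-values reported. Upregulated genes in a target group require strict fold
change > threshold on means with a pseudocount of 1e-9 (division-by-zero
guard; distortion negligible at count scale) and a BH-adjusted one-tailed
rank-sum p ≤ α across cells. BH is used wherever an adjusted p is required.
Cells with significantly *positive* ρ are excluded from
`significant_profiles` by default, since the retained quantity is an
anticorrelation; the sign rule is configurable.

## Synthetic data

The generator's role is to provide ground truth with the same failure
modes as real data, not realistic transcriptome marginals.

- **Coupling.** The rate axis enters as the deterministic normal scores of
  the dN/dS ranks, z_rate. Each cell's latent log-expression is
  z = r·z_rate + √(1−r²)·ε with ε iid N(0,1) per gene *and cell*, and
  r = 2 sin(πρ_s/6) inverts the Gaussian-copula identity
  ρ_s = (6/π) asin(r/2). Because z_rate is a fixed grid, each cell's
  realized latent Spearman fluctuates independently around ρ_s, so
  type-level means concentrate tightly. Coupling is imposed on latent
  log-means, not counts: Poisson noise, zero-truncation and dropout
  attenuate the realized per-cell ρ exactly as sequencing depth does in
  real data, which is why recovery tests compare orderings and rates, not
  absolute values (except under the deep-library, no-dropout calibration
  condition, where attenuation is negligible).
- **Counts.** Per cell, expected counts are a library-size draw
  (log-normal around the type mean, σ = 0.25) times the softmax of
  σ_log·z (σ_log = 1.5, a typical scRNA-seq log-normal spread); counts are
  Poisson. Dropout zeroes an entry of mean μ with probability
  exp(−μ/λ) where λ = `dropout_strength` — decaying in the mean, no
  dropout at λ = 0, monotone more dropout as λ grows.
- **Rate tables.** dS is gamma-distributed and strictly positive, dN/dS is
  drawn on (0, 2], so ordinary rows always survive filtering; exact
  fractions of rows are forced to dS = 0 or ratio > 2, making filter
  counts deterministic.
- **Ages and stages.** Age labels are assigned independently of the rates
  (young fraction default 0.15), so young and old genes are exchangeable
  in expression unless a fetal boost is imposed; stages reuse the design's
  cell types with a stage-specific coupling, and fetal-flagged stages add
  `young_fetal_boost` (log-units) to young genes' latent means. Per-stage
  seeds are spawned from the design seed.

What the generator does *not* emulate: empirical count marginals, gene–gene
modules beyond the rate coupling, batch effects, doublets, UMI saturation.
Passing tests therefore demonstrate that the estimators recover imposed
orderings, trends and calibrations under realistic noise, depth and dropout
mechanisms — not that real tissues follow the generator's distributions.

## Evaluation scales

The built-in studies run at desk scale, chosen to keep each study in the
seconds-to-a-minute range while leaving comfortable statistical margins:
2,000-gene rate tables with 150–200 cells per type for calibration,
confound, ranking and removal studies; 500 genes × 200 subtypes × 1,000
permutation replicates for null calibration; 6 stages × 100 cells (1,500
genes) for trajectories; 5 stages × 60 cells (1,000 genes) for young/old
detection; 20 replicates wherever a rate is measured. Deep libraries
(2×10⁶) and zero dropout define the calibration condition; shallow
libraries (2,000 vs 6,000) define the depth-confound condition.

## Known limitations

- The depth correction is linear; strongly nonlinear ρ-vs-depth
  relationships (e.g. mixing platforms with orders-of-magnitude depth
  differences) leave structure in the residuals. Within a platform the
  relationship is near-linear.
- The permutation null treats genes as exchangeable; correlated gene
  modules shared between expression and rates would narrow the true null.
- Exhaustive Spearman p-values below n = 10 are exact but O(n!); the
  per-cell pipeline only hits this path for near-empty cells.
- Cross-species ortholog harmonisation, normalisation, clustering and
  cell-type assignment are out of scope: annotations and rate tables are
  inputs.
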