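# Methods

## Phenotype gating

Cells carry binary positivity calls produced upstream by image-analysis
software; no intensity thresholds are applied here. A gate is a rule
(required-positive markers, required-negative markers, priority); each cell
receives the highest-priority rule it satisfies, otherwise `other`, so
labels always partition the table. The shipped priorities are
tumor (CK+) > Treg (CD3+FoxP3+CD8−) > cytotoxic T (CD3+CD8+) >
helper T (CD3+CD8−) > FoxP3− T > PD1+ T > B (CD20+) > macrophage (CD68+) >
NK (CD56+). Placing Treg above cytotoxic T resolves the only biologically
plausible conflict deterministically; under a CD3/CD8-only panel (where
FoxP3 is never called) the T compartment reduces exactly to
cytotoxic ∪ helper = CD3+. By default every immune gate additionally
requires CK−, so cytokeratin-positive cells cannot enter immune phenotypes;
this is configurable. Two rules firing on the same cell at equal priority
is treated as a configuration error and raises.

The two staining panels come from different sections, so panel-specific
phenotypes are only ever combined per sample, never per cell.

## Quadrat colocalization (Morisita–Horn)

Each sample is tiled with non-overlapping squares of side 100 µm (the
field-standard neighborhood scale for cell colocalization; configurable).
The grid is anchored at the bounding-box minimum of all cells in the
sample, cells are binned by half-open intervals [k·s, (k+1)·s), and partial
edge squares are kept — dropping them would silently discard cells. With
per-square counts xᵢ, yᵢ and totals X, Y:

MH = 2 Σ xᵢyᵢ / ((Σ xᵢ²/X² + Σ yᵢ²/Y²) · X · Y).

MH is symmetric, bounded in [0, 1], equals 1 when the two count vectors are
proportional and 0 when no square holds both types. When either type is
absent the statistic is *missing*, not 0: zero would falsely assert
observed segregation. When a sample comprises several cores, statistics are
computed per core and averaged per sample.

## Nearest-neighbor proximity (G, SPS) and Ecoscore

G(r) is the empirical fraction of reference-type cells whose nearest
target-type cell (Euclidean distance; self excluded when the two types
coincide) lies within r. No edge correction is applied by default — cores
are small and uncorrected G is what the quadrat statistic is compared
against — but a border correction (discarding reference cells within r of
the bounding box) is available.

The Spatial Proximity Score summarizes the curve as its normalized area,

SPS = (1/r_max) ∫₀^{r_max} G(r) dr,

evaluated by the trapezoidal rule on a 1 µm radius grid with
r_max = 50 µm by default: 1 when every reference cell touches a target
cell, 0 when none is within r_max. This is an explicit, documented stand-in
definition: SPS (and the Ecoscore construction below) circulate in the
literature mainly through supplementary material, and deployments holding
an exact published formula should substitute it — both r_max and the
radius step are configuration keys.

The Ecoscore compares the mean SPS-to-tumor of anti-tumor classes
(default: cytotoxic T) against pro-tumor classes (default: Treg,
macrophage): anti-tumor if mean(anti) > mean(pro)·(1+margin), pro-tumor on
the reverse, indeterminate on ties or when either side is missing. The
class memberships and margin (default 0) are configurable.

## Signature scoring

Expression (log-scale, genes × samples) is per-gene mean-centered across
all samples jointly (centering within sample-type strata is possible by
subsetting first). A signature score is the unweighted mean of the centered
values of its genes present in the matrix; per-gene direction weights
(+1/−1) are supported for signed signatures. Genes absent from the matrix
are dropped with a logged warning; a fully absent signature scores as
missing. The mean-of-centered-genes rule is the convention for this
signature family; proprietary multi-gene indices (e.g. commercial 70-gene /
80-gene risk scores) are *not* recomputed — their precomputed values enter
the screen as ordinary covariate columns.

## Outcome association

Overall survival is time from metastatic diagnosis to death from any
cause, censored at last follow-up. Cox proportional-hazards fits use the
Efron tie approximation (lifelines); hazard ratios are per unit increase of
the variable as supplied — no internal rescaling — with a per-SD option
where the natural unit is unclear (e.g. sTILs %). The p-value is a
likelihood-ratio test: twice the log-partial-likelihood difference between
the models with and without the variable, χ² with 1 df, which is better
behaved than the Wald test at these sample sizes.

Response (rCR) is fitted by logistic regression with the analogous
deviance-based LR test. We fit a logistic, not linear, model for this
binary endpoint because odds ratios are the reported effect measure; a
linear probability model cannot produce them.

Median follow-up uses the reverse Kaplan–Meier estimator (censoring as the
event, deaths censored), returning infinity when the reversed curve never
crosses 0.5 ("not reached"). Tertile splits use the empirical 1/3 and 2/3
quantiles with ties to the lower group; group KM curves come with a
multivariate log-rank test. Primary-vs-metastasis contrasts report the
metastasis-minus-primary mean difference with Mann–Whitney U (unpaired) or
exact Wilcoxon signed-rank on pair differences (paired). Correlation maps
use pairwise-complete Spearman ρ with average-linkage clustering on 1 − ρ
and significance stars at 0.05 / 0.01 / 0.001.

The screen runner sweeps every (variable, endpoint, subgroup, covariate
set) cell, labels each with the dot-plot significance tier (raw LR p <
0.05 / 0.05–0.10 / ≥ 0.10), and applies Benjamini–Hochberg across the
*entire* family of tested cells. Adjustment covariates that are constant
inside a subgroup (rCR inside the rCR subgroup) are dropped for that cell.
Cells that cannot be estimated — zero events, constant variable, complete
separation — are flagged `estimable = False` with the reason, never
silently dropped, and excluded from the BH family.

## Synthetic data

The point-pattern generator is a two-type Thomas cluster process in a
600 µm × 600 µm window (a typical core size; free parameter): Poisson
parents at 10/mm², Poisson offspring counts (means 40 for the tumor-like
type, 15 for the immune-like type), Gaussian displacements (σ = 20 µm),
plus 20/mm² uniform background per type. A fraction f of the parent
intensity is shared between the types and the rest is private per type, so
each type's marginal distribution is the same Thomas process for every f
while cross-type colocalization rises monotonically from segregated (f = 0)
to colocalized (f = 1). Offspring outside the window are discarded — a
physical core boundary, not a torus. The Thomas process was chosen because
it is the standard tunable-colocalization generator with closed-form
intuition; any real-image features beyond clustering (holes, tissue folds,
segmentation errors, marker spillover) are *not* emulated, so green spatial
tests demonstrate correctness of the statistics, not robustness to imaging
artifacts.

Survival times follow a proportional-hazards model with Weibull baseline
(shape 1 = exponential by default, scale 0.02–0.05 events/month in tests)
on z-scored scores, with administrative censoring; response is Bernoulli
through a logistic link. Standardizing scores makes "per unit" equal "per
SD" inside simulations, which keeps generating coefficients comparable
across scores.

Every generator is a pure function of (config, seed); identical seeds give
byte-identical tables.

## Numerical choices and problem sizes

- MH is clipped to [0, 1] against floating-point overshoot; missing is NaN.
- SPS integrates on the stored radius grid, interpolating the endpoint when
  r_max falls between grid points; G(0) contributes 0 for distinct points.
- Calibration checks run 100 replicates at n = 300 (type-I error in
  [0.01, 0.10] at α = 0.05) and n = 500 (HR = 2 CI coverage ≥ 90%);
  colocalization monotonicity uses 50 seeded replicates per shared-parent
  fraction; the end-to-end pipeline check uses a 40-sample cohort. These
  sizes give stable Monte-Carlo estimates while keeping the default test
  run fast.
- The tiny-cohort Cox fit is validated against brute-force maximization of
  an independently coded Efron partial likelihood on a 1e-4-step grid.

## Limitations

- SPS/Ecoscore are stand-in definitions (above); results depend on r_max.
- No edge correction by default biases G slightly downward near borders;
  acceptable for colocalization *comparisons* within a study, less so for
  absolute density estimation.
- The screen treats samples as independent; paired primary/metastasis
  samples should be analyzed with the paired contrast, not pooled.
- Complete separation in small subgroups is reported, not penalized — no
  Firth correction is implemented.
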