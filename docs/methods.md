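# Methods and modelling notes

This note records the statistical models, the parameter defaults and their
rationale, what the synthetic-data generator does and does not emulate, and
the numerical choices that affect results. Nothing here asserts an empirical
claim that the test suite or `scripts/acceptance.py` does not compute.

## Trait table and transforms

Five functional traits per species: body mass (g), litter size, a continuous
diet trait (derived, below), foraging stratum (ordinal 1–4: ground,
scansorial, arboreal, aerial) and habitat breadth (count of suitable
habitats ≥ 1). Activity pattern is a four-category factor (nocturnal,
crepuscular, cathemeral, diurnal) with a separate boolean flexibility flag.

Body mass and litter size are log10-transformed, habitat breadth
square-root transformed; every column is then z-scored using the sample SD
(n−1 denominator) over its observed cells. Transforms precede imputation, so
the conditional models operate on approximately linear scales. Missing cells
are tracked in an explicit boolean mask; the CSV dialect treats "", "NA" and
"NaN" (case-insensitive) as missing.

Collinearity diagnostics report pairwise Pearson correlations and variance
inflation factors, VIF_j = 1/(1 − R²_j) from regressing trait j on the other
four on complete cases (equivalently the diagonal of the inverse correlation
matrix); perfect collinearity is reported as infinite.

## Diet ordination

Gower distance over the ten semi-quantitative diet categories:
range-normalised mean absolute difference, every entry in [0, 1]. Categories
with zero range carry no information under this metric and are dropped with
a logged warning. Classical PCoA double-centres −d²/2 and keeps the positive
spectrum only; variance fractions are computed over positive eigenvalues
with no Lingoes/Cailliez correction. Axis 1 is oriented to correlate
positively with the invertebrate category, removing eigenvector sign
arbitrariness. Loadings are reported both as plain category–axis Pearson
correlations and scaled by √(variance fraction), because "loading" admits
both readings for PCoA.

## Imputation

Multiple imputation by chained equations, m chains (default 25) of a fixed
number of column sweeps (default 100; the desk-scale default used by the
tests is 5 × 10). Per incomplete column the conditional model is:

- continuous columns — Bayesian normal linear regression: σ² drawn from the
  scaled inverse-χ² posterior, coefficients from N(β̂, σ²(XᵀX)⁻¹), then a
  predictive draw;
- diel niche — bootstrap multinomial logistic regression (fallback to an
  observed-marginal draw on failure, always logged);
- foraging stratum — bootstrap proportional-odds (ordered logit) regression
  (fallback to multinomial, then marginal).

Design matrices contain all other trait columns (categoricals one-hot
encoded) plus the first ten phylogenetic eigenvectors — PCoA axes of the
tip–tip patristic distance matrix — which encode the tendency of close
relatives to resemble one another. Species absent from the tree receive
zero eigenvectors with a logged flag. Chains are pooled by the mean
(numeric) or the mode with a lowest-code tie-break (categorical). Every
column with missing cells must retain at least 20 observed cells.

Species whose *activity pattern* was imputed are excluded from the λ
estimation downstream, to avoid estimating phylogenetic signal partly from
values that the phylogeny itself helped impute.

## Phylogenetic signal

Pagel's λ rescales internal branches of an ultrametric tree by λ and
stretches each terminal branch so root-to-tip depths are preserved; λ = 1
leaves the tree untouched, λ = 0 makes tips independent. The activity
pattern evolves under the equal-rates Mk model, P(i→j, t) = 1/k +
(δ_ij − 1/k)·exp(−kqt/(k−1)). The log-likelihood uses Felsenstein pruning
with per-node rescaling and a uniform root prior. (q, λ) are maximised
jointly by L-BFGS-B on (log q, λ) with bounds log q ∈ (−12, 8), λ ∈ [0, 1],
from four λ starts {0.1, 0.5, 0.9, 0.99} (the λ surface is often flat near
1), tolerance 1e-6. Summaries report the mean and SD of λ̂ over trees
sampled without replacement (default 30), plus binary focal-niche recodes.

Desk-scale recovery: with 200-tip Yule trees and the simulation rate used by
the benchmarks, the mean λ̂ over 20 replicates lands within ±0.12 of true
values 0, 0.5 and 0.9, and shuffling tip states drives λ̂ below 0.2. The
acceptance script recomputes these numbers.

## Strategy surfaces

Per diel niche: PCA by eigendecomposition of the 5×5 covariance of the
standardised traits, each axis oriented so its largest-|loading| trait loads
positive. The 2-D score cloud gets a Gaussian KDE with a full (unconstrained)
2×2 plug-in bandwidth matrix: data are pre-sphered, the fourth-order
integrated density-derivative functionals are estimated by double sums under
an isotropic normal-reference pilot g = (2d/((d+2)n))^(1/(d+6)), and the
plug-in AMISE objective is minimised over the log-Cholesky parameters of H
(Nelder-Mead). If the optimisation fails, the estimator falls back to the
unconstrained normal-scale matrix with a logged, report-visible flag — never
silently. The grid (default 151×151) pads the data range by 3√(max
eigenvalue of H) per side, keeping integrated mass loss below 1%.

HDR thresholds c_α are empirical (1−α) quantiles of the density values at
the sample points (lower-interpolation), so ≈ α of the species sit inside
{f ≥ c_α}; thresholds are monotone, c_0.5 ≥ c_0.95 ≥ c_0.99. Hotspots are
8-connected components of grid cells with density ≥ c_0.5; species are
assigned to the component containing their nearest grid node, and family
coverage is reported against families present in the niche (and optionally
against all families, since the denominator is a modelling choice).

## Hypervolumes

A group's occupied region of the 5-D standardised trait space is the
acceptance region of a one-class SVM (RBF kernel) fitted to the group's
points. Volume is estimated by uniform rejection sampling in the data
bounding box expanded by one kernel SD (1/√(2γ)) per side; volume =
accepted/proposed × box volume, in SD⁵ units. Defaults: ν = 0.01;
γ = 1/(d · mean per-dimension variance), which equals 0.5 on z-scored 2-D
data and adapts to subsets whose variance differs from 1. These values were
fixed against analytic geometry benchmarks *before* the test suite was
written: 5000 uniform points in the unit square give volume ≈ 1.03, two unit
squares offset by 0.5 give Jaccard ≈ 1/3, and disjoint clusters give unique
fractions ≈ 1.

Overlap statistics use density-matched mutual inclusion: both stored clouds
are thinned to the smaller point density, the fraction of each cloud inside
the other boundary is measured, and the intersection volume is the average
of the two estimates (clipped at the smaller volume). Unique fractions,
Jaccard and Sørensen follow. Matched-pair comparisons subsample the larger
group to the smaller group's size (default 100 replicates) and report means
and SDs; the flexible-vs-obligate analysis runs pooled and within each
niche, skipping (with a warning) scopes lacking either group. All
hypervolumes within one analysis share a single z-score frame computed over
the full species set, so volumes are comparable across groups.

## Synthetic worlds

The generator emulates the *structure* of a mammal-scale comparative
dataset, not real mammalian values beyond orders of magnitude:

- pure-birth (Yule) ultrametric tree (default 5104 tips; tests use hundreds);
- four-state activity pattern evolved under ER Mk on the λ-transformed tree
  (default λ = 0.955, so the estimator faces realistic, strong conservatism);
- five latent traits per niche from multivariate normals on transformed
  scales (correlations include mass–diet −0.55 and litter–stratum 0.59),
  back-transformed to raw scales;
- diet compositions from niche-specific Dirichlet distributions scaled to
  the 0–10 semi-quantitative range in half-unit steps;
- per-niche diel-flexibility rates (16.5% / 54% / 18% / 18.8%);
- missingness per column — activity 3%, body mass 1%, litter size 24%, diet
  2% (all categories of a species jointly), foraging stratum 1%, habitat
  breadth 0.5% — MCAR by default, or MAR with missingness odds scaled
  1 : r : r² across body-mass terciles (default r = 2).

Not emulated: extinction, fossil tips, taxonomic error, measurement error,
trait-dependent diversification, and any real species identities. Family and
order labels are coarse tree partitions so family-level summaries have
structure to report, nothing more.

## Seeds and reproducibility

One master seed drives everything. The pipeline derives one stream per stage
by combining the master seed with a hash of the stage name, so changing the
hypervolume subset count cannot perturb the λ stage; within stages,
`SeedSequence.spawn` separates chains, replicates and trees. Identical
config + seed reproduces byte-identical tables and reports; the acceptance
script is deterministic in `--seed`.

## Limitations

- The plug-in bandwidth selector is implemented for 2-D surfaces only (the
  analyses need nothing else); its Nelder-Mead stage can fail on pathological
  inputs, in which case the normal-scale fallback is used and flagged.
- Hypervolume volumes are Monte-Carlo estimates; with the default proposal
  densities the unit-square benchmark varies by a few percent across seeds,
  and 5-D volumes are parameter-sensitive (ν, γ) by the nature of the method.
- The Mk model is equal-rates; ordered or asymmetric transition models are
  out of scope.
- Pooling imputed categorical cells by mode discards between-chain
  uncertainty; no Rubin's-rules variance pooling is provided.
- λ estimation requires ultrametric trees (the transform is undefined
  otherwise for λ < 1); likelihood evaluation alone accepts any tree.
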