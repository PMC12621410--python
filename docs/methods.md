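# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic-cohort tests do and do not
establish about behaviour on real imaging-mass-cytometry (IMC) data.

## Data model and units

Cells are rows of a validated table with ROI-scoped identity
(`(roi_id, cell_id)` is the global key), continuous µm coordinates
(origin top-left, Euclidean metric) and one non-negative intensity column
per panel channel. At the ~1 µm resolution of IMC one pixel corresponds to
one micrometre, so the package stores µm only. On-disk interchange is plain
CSV (`cells.csv`, `cohort.csv`, `panel.csv`), UTF-8 with `.` decimals.
Molecular subtype labels normalise case-insensitively (ignoring hyphens and
underscores) onto {POLE, MSI-H, CNH, CNL}.

## Intensity transformation and batch alignment

Per channel, across the whole cohort: clip above the `clip_quantile`
quantile (default 0.999), compress with `asinh(x / cofactor)` and min-max
scale to [0, 1]. The cofactor defaults to 5, the mass-cytometry convention;
the transform is monotone per channel below the clip point.

Batch alignment is per-batch mean centring: per channel each batch's mean
is shifted onto the global mean, removing additive batch offsets exactly
and preserving within-batch rank order. This is an intentionally simple,
fully reproducible alternative to iterative embedding-based harmonisation:
it corrects location shifts only, not scale or nonlinear effects, which is
sufficient for the additive per-(batch, channel) shifts the simulator
generates and is transparent to audit. Batch defaults to patient (each
tissue chip is acquired separately) and is configurable.

## Phenotype clustering and annotation

Clustering is Leiden community detection (modularity, RBConfiguration) on a
k-nearest-neighbour graph of transformed lineage-marker space (k = 30,
seed 0, both logged). The paper-style workflow fixes the number of major
classes rather than a resolution, so `target_k` tunes the resolution by
bisection on a log scale to hit a requested community count; the package
makes no claim to reproduce any particular published partition. Two-stage
refinement (`recluster_subgroups`) isolates each major group and re-clusters
it on a refined marker set.

Cluster annotation is deterministic: each cluster's mean marker profile is
matched to the signature of maximal cosine similarity. Ties break to the
lexicographically first phenotype name with a flag; best similarity below
0.2 maps to `other`. The signature table is user-editable CSV; the bundled
default assigns weight 1 to each phenotype's defining lineage markers and a
baseline 0.1 elsewhere, with a uniform row for `other` so featureless
profiles annotate as such. Automating what is usually a manual,
heatmap-assisted step trades expert judgement for reproducibility; on real
panels the signature table must be curated per antibody panel.

## Regions

A patch is a connected component of marker-positive cells under single
linkage at ≤ 20 µm, kept when it has ≥ 20 members. Because single-linkage
components are maximal, two surviving same-class patches are by
construction > 20 µm apart — merging of adjacent same-class regions is
implicit, and merging across classes is deliberately not performed.
Positivity comes either from annotated lineage labels (the deterministic
default: pan-cytokeratin-positive epithelial cells, CD45 lineages,
collagen-driven fibroblasts) or from a marker gate at the cohort-wide 75th
percentile. Patches are expanded by point distance (every cell within 20 µm
of a member — about two cell diameters), not polygon dilation; overlaps
between classes resolve by the priority order epithelial > immune >
fibrotic with a flag, and uncovered cells are `none`. Composition contrasts
use two-sided rank-sum tests on per-(region, ROI) frequency vectors
(absent phenotypes count as frequency 0), Benjamini–Hochberg adjusted
within each (region, phenotype) family.

## Cellular neighbourhoods

Windows never cross ROI boundaries. The headline configuration is the 20
nearest neighbours per cell (ties at the boundary broken by ascending cell
id for determinism); a fixed-radius mode (e.g. 20 µm) is also provided, as
source descriptions of this analysis family vary between the two. The
centre cell is included in its own window so isolated cells yield one-hot
rows. Window frequency rows are clustered with mini-batch k-means
(default k = 10, batch size 1024, seed 0; k-means labels are reported
1-based as CN1..CNk). Prevalence per core (core = ROI) is normalised to
exactly 100 % (the float residual of the division is folded into the
largest entry), z-scored across all cores per CN — not within subtype
groups — and the enrichment matrix is the column z-score of per-CN mean
window frequencies. Group contrasts of prevalence are rank-sum tests,
BH-adjusted within each CN.

## Pairwise interaction / avoidance testing

Two cells interact at centroid distance ≤ 6 µm. The per-ROI statistic for
the ordered pair (A, B) is the mean number of B neighbours per A cell
(equivalently the directed A→B adjacency count divided by n_A; the
edge-count statistic is available via the same counts). Positions — and
hence the adjacency — stay fixed; labels are shuffled within the ROI
(n_perm = 1000 by default, seeded). One-sided p-values use the add-one
correction, so p ∈ (0, 1] and the smallest attainable value is
1/(n_perm + 1); calls are made at α = 0.01. Pairs whose from- or to-type is
absent from an ROI are listed as undefined rather than reported as zero.
Group contrasts use Welch t-tests on per-ROI statistics with
log₂((mean_a + ε)/(mean_b + ε)), ε = 0.01, a `shown` flag at p < 0.05 and a
|log₂FC| ranking among shown pairs. Aggregation is by mean statistic per
ROI before testing (rather than fraction-of-ROIs-significant), so the
contrast retains effect-size information.

## NMF programs

The composition matrix defaults to cell-type frequencies per ROI (columns
sum to 1); a marker-mean mode (per-ROI mean transformed intensity, low
signal rows removed) is also supported since composition and protein
abundance are both legitimate inputs to this factorisation. Fitting is
Lee–Seung multiplicative updates for the Frobenius objective with a 1e-12
guard in denominators, `nndsvda` or seeded random initialisation, stopping
at relative error change < 1e-6 or 2000 iterations. The error trace is
recorded per iteration and is non-increasing by the update's guarantee.
After convergence W columns are normalised to sum 1 with the scale absorbed
into H (a WD⁻¹·DH rescaling, which leaves WH unchanged).

Rank selection runs seeded random-init restarts per candidate k, co-clusters
samples by dominant program into a consensus matrix, and walks k upward
while the consensus stays stable, choosing the largest k before the first
drop (threshold 0.95, drop tolerance 0.002, ties to smaller k). The
stability statistic is the consensus **dispersion** coefficient
(mean of 4(C − ½)²): the more familiar cophenetic correlation is also
computed and reported, but on small, nearly noise-free consensus matrices
it saturates near 1 for every rank above the truth and cannot drive the
first-drop rule, whereas dispersion falls as soon as co-assignments become
ambiguous. Inputs with no stable rank (e.g. i.i.d. noise) are flagged and
the smallest candidate returned with a warning.

## Outcome models

Features per ROI: phenotype frequencies (T), ordered-pair interaction
statistics at 6 µm (T²), and mean transformed functional-marker intensity
per phenotype (T·F), plus one missingness indicator per phenotype (absent
phenotypes contribute zeros). Each repeat draws a stratified 70/30 split —
by patient by default, which is stricter than splitting by ROI and avoids
leakage between a patient's ROIs; ROI-level splitting is available by
configuration. The forest's candidate-variables-per-split is tuned per
repeat on the out-of-bag misclassification over the grid
{⌊√p⌋/2, ⌊√p⌋, 2⌊√p⌋}; 500 trees by default (tests and the pipeline use
smaller forests — the estimates stabilise well below that at these sample
sizes). Importance is mean decrease accuracy: the drop in validation
accuracy when one feature column is permuted (all p single-feature
permutations are evaluated in one stacked predict call). AUC is standard
for binary labels and macro one-vs-rest for the four-class subtype label;
both the across-repeat mean and the pooled-prediction AUC are reported
since either aggregation is defensible. Splits that lose a class are
redrawn (more than 10 % redraws aborts). All randomness derives from one
master seed. The top-k model keeps the k best features by mean decrease
accuracy (in original column order, so k ≥ p reproduces the full model
exactly) and re-runs the same protocol.

Survival uses the Kaplan–Meier product-limit estimator and log-rank test
(two-sample, or the multivariate generalisation for more groups) via
lifelines, with a median-split helper for feature-based grouping. A
degenerate contrast (no events, or identical groups) reports statistic 0,
p = 1.

## Synthetic cohorts

The generator emulates the study design the analyses assume: 4 subtypes ×
10 patients × 2 ROIs (80 ROIs), 1000 × 1000 µm ROIs, a 41-plex panel and 10
major phenotypes, with intensity parameters that default to ~10⁴ cells per
ROI. Niches are a Thomas-style cluster process — Poisson parents per niche,
Gaussian offspring (σ = 20 µm, giving ~40 µm-diameter multicellular
structures of the scale of vessels and small immune aggregates), phenotypes
drawn from the niche composition. Five archetypes are bundled: epithelial
nests, immune hubs, fibrotic tracts, vascular niches and mixed stroma,
with compositions distinct enough to be recoverable as neighbourhood
archetypes. Marker intensities are log-normal around phenotype signatures
(defining markers at log-mean 3, background 0, σ = 0.35), with optional
fine functional states (Treg, proliferating T, M1/M2 macrophages,
proliferating endothelium) shifting functional channels; per-(patient,
channel) additive shifts (σ = 0.4) model acquisition batches and truncate
at zero.

Attractions relocate a stated fraction of target-type cells to within a
placement radius (default 5 µm) of random source-type cells, preserving
marginal composition; a relocated cell's ground-truth niche follows it to
its anchor's niche, since that is where it now resides. Defaults plant a
constitutive endothelial→myeloid attraction (excess 0.5) and a
recurrence-linked CD90⁺→myeloid attraction whose per-patient excess is
drawn uniformly and feeds the outcome model. Outcomes: recurrence is
Bernoulli with a logistic model on standardised planted patient features
(frequency of the CD90⁺ phenotype and the realised recurrence-linked
excess, both with coefficient 1.5); progression-free survival is
exponential with hazard 0.02·exp(0.8·lp) per month, censored uniformly on
[0, 40] months (a 40-month follow-up horizon).

Scaled-down cohorts for tests and examples (`small_config`) keep the
cohort structure and niche geometry and reduce only offspring counts.
Tests and the acceptance script run at 500–1500 cells per ROI — problem
sizes chosen so each check completes in seconds to a few minutes while
leaving the spatial statistics well away from degeneracy.

**What the simulator does not emulate:** segmentation error and doublets,
marker spillover / isotope interference, spatial gradients within niches,
cell shape and size, non-additive batch effects, correlated marker noise,
and truly continuous phenotypes. Passing recovery tests therefore show the
algorithms are correct and well calibrated under the generative assumptions
they target — not that a real cohort's phenotypes or neighbourhoods will be
recovered at the same fidelity.

## Numerical and testing notes

- Permutation p-values compare integer adjacency counts, so ties are
  handled exactly; the add-one correction keeps p > 0. Null calibration of
  the one-sided tests is checked on label-randomised ROIs dense enough that
  the count statistic is not degenerate. Like any discrete permutation test
  with the add-one correction, the attained size sits slightly below the
  nominal α (measured ≈ 0.006–0.009 at α = 0.01 at tissue-like densities):
  the test is valid and mildly conservative, never anti-conservative.
- Null AUC checks for the repeated random-forest protocol use several
  hundred samples: with one fixed label-shuffled dataset, chance
  feature–label correlations are shared by both split halves and genuinely
  lift held-out AUC above 0.5 at small n — a property of the protocol, not
  a bug.
- kNN distance ties are broken by ascending cell id; patch membership is
  invariant to row order and rigid motion; increasing `min_cells` can only
  reduce the number of patches.
- Determinism contract: every stochastic routine takes a seed, the pipeline
  derives per-stage seeds from one master seed by hashing, and a full rerun
  with the same configuration reproduces every CSV byte for byte.
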