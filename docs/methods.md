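# Methods

This note documents the models, parameters and design choices behind
`cellniche`, and what the synthetic-data tests do and do not establish.

## Data model

A cohort is three tab-delimited tables (cells, spots, patients) with
spot-local cell coordinates in µm (origin at the disk center). The pipeline
is deliberately image-free: the tissue compartment is carried per cell and
QC/tumor areas per spot as scalars, replacing the pixel-wise segmentation
and alignment masks a full imaging pipeline would produce. This preserves
the density denominators (counts per mm² of tumor = carcinoma + stroma
area) but is a simplification: per-spot scalar areas cannot express
spatially heterogeneous QC failures.

Spot QC keeps aligned areas in [0.7, 3.0] mm². Spots below the floor carry
too little well-registered tissue; spots above the ceiling are typically
shattered into shards whose spatial statistics are distorted. Both bounds
are treated as inclusive — the nominal 1.5 mm core (π·0.75² ≈ 1.77 mm²)
sits comfortably inside the window, and a spot exactly at a bound passes.

## Phenotyping

The gating table is ordered and first-match, with a terminal catch-all, so
every marker-vector × compartment combination receives exactly one fine
class; the medium class and lineage are functions of the fine class. The
default table is a reconstruction, not a published artifact: it encodes
lineage precedence (compartment-gated CK > CD3 > CD20 > CD56 >
CD163/CD68), the lymphocyte states (GrB⁺ activated, PD-1⁺ without GrB
exhausted, FoxP3⁺ T cells regulatory), PD-L1 as a lineage-independent
immunosuppressive modifier, and TAM1 = CD68⁺CD163⁻ vs TAM2 = CD163⁺.
CK⁺ cells are carcinoma only outside the healthy compartment; in healthy
tissue they are normal epithelium (pneumocytes and ciliated cells share
cytokeratin expression). CD4⁺CD8⁺ and marker-negative CD3⁺ cells fall to a
generic T-cell class rather than inventing combination phenotypes of
unknown biological meaning. The resulting default has exactly 43 fine and
23 medium classes, but the membership of individual classes is this
package's reconstruction; the table is a TSV-round-trippable config so a
published supplementary definition can be substituted verbatim.

## Niche detection

For each cell we count marker-positive cells (a cell contributes to every
marker it carries, and to its own neighborhood) within 34 µm, inclusive.
The radius spans first- and second-order neighbors: it admits one adjacent
macrophage (up to ~30 µm diameter) around a central lymphocyte (~8 µm), in
line with the 30–40 µm interaction ranges used across spatial TME studies.
Counts are log1p-transformed — presence/absence matters more than exact
counts — and divided by the vector sum, yielding a point on the 12-marker
composition simplex; zero-mass neighborhoods map to the zero vector and are
assigned by the same nearest-centroid rule (no special class). Including
the index cell guarantees nonzero mass for every marker-positive cell.

Prototypes come from mini-batch k-means++ (k = 10 by default, batch 8000,
3 seeded restarts keeping the lowest inertia), fitted per subtype — LUAD
and LUSC are biologically distinct entities and pooling would blur
subtype-specific spatial patterns. Assignment is nearest centroid with ties
to the lowest niche id. Niche profiles carry the phenotype distribution and
marker proportions; a niche is "hot" when its lymphocyte-lineage (T+B+NK,
all states) fraction is ≥ 0.25 — macrophage-dominated niches therefore
classify cold, matching the conventional hot/cold grouping. The dominance
entropy test compares groups of spots on the mean Shannon entropy of their
niche proportion vectors via an independent-sample permutation test
(permuting spot group labels; equivalently their precomputed entropies).

Open point: neighborhood counts are per *marker* (12-dimensional), not per
phenotype class; a cell positive for several markers contributes to each.
This follows the marker-count formulation of the originating protocol; a
per-phenotype variant would change the feature space.

## Niche matching

Profiles are compared with the symmetric chi-squared distance on phenotype
distributions (nonnegative, zero iff equal, symmetric; it does not satisfy
the triangle inequality, which partial OT does not require). Each niche
carries uniform mass 1/k — niches are categorical prototypes, not
frequency-weighted. For every candidate pair count n = 0..k the exact
partial transport LP (HiGHS; no entropic regularization, hence
deterministic) moves mass n/k at minimal cost; costs are nondecreasing in
n. n* is the maximum discrete second difference of log(cost + 1e-12) over
n = 1..k−1 — the sharpest bend where cheap genuine matches give way to
forced ones; matched pairs are plan entries carrying at least half a niche
mass unit (1/2k). An all-zero distance matrix degenerates to n* = k at zero
cost.

## Survival modeling

Cohort selection keeps stage I–III, confirmed R0, no adjuvant therapy, and
≥ 3 months follow-up (earlier deaths are plausibly perioperative).
Propensity matching balances training and test centers on (UICC8,
follow-up, censoring) using logistic-regression logits and greedy nearest
matching without replacement — logistic regression is the simplest
calibrated choice for a three-variable origin classifier.

Features (k niche proportions + UICC8 stage as an integer covariate, with a
one-hot switch available) are Yeo-Johnson transformed and standardized on
training rows only — the abundances are right-skewed with heavy tails, and
the power transform adapts per feature where a fixed log1p would not.
mRMR for censored data scores relevance as the univariate Cox training
c-index (constant features score 0.5) and redundancy as the mean absolute
Pearson correlation with already-selected features; greedy selection with
ties broken by column order. The Cox model is ridge-penalized (lifelines,
L2) on spot rows: each spot is an instance carrying its patient's outcome.
Replicating outcomes onto spots violates row independence — accepted
deliberately, because it is exactly the late-fusion multiple-instance
design being modeled, with patient-grouped cross-validation (spots never
straddle folds) protecting the tuning. Default grids: max_k ∈ {3,5,8,10,11},
α ∈ {0.01, 0.1, 1, 10}, 5 inner folds; ties prefer smaller max_k, then
stronger regularization.

Patient risk is the maximum of spot risks ("hot-spot" rule: grading-like
diagnostics score the worst region, and underestimating risk is the costly
error when the decision is whether to give adjuvant therapy); mean pooling
is available. Tertiles RS1/RS2/RS3 are cut at the evaluated cohort's 1/3
and 2/3 quantiles with boundary ties going down; boundaries can be frozen
from a reference cohort for prospective use. Evaluation: Harrell's c-index
(ties 0.5), the relative improvement (c_model − 0.5)/(c_baseline − 0.5)
(the c-index is informative only above 0.5, so gains are expressed on that
range; undefined when the baseline is at or below chance), multi-group
log-rank on tertiles, a paired bootstrap (the same patient resample scores
both models in each replicate, which is the conservative paired design;
replicates without admissible pairs are redrawn) compared by two-sided
Mann-Whitney U, and the stage × risk-group restratification table with the
stage-1 upstaging fraction.

## Whole-section validation

Virtual 1.5 mm cores tile the bounding box of tumor-compartment cells with
a 750 µm stride (half-diameter overlap guarantees exhaustive coverage
wherever density suffices — no stride is canonical, this is the simplest
one with that property); cores with fewer than 100 tumor cells are dropped,
a cell-count proxy for the 0.7 mm² QC floor since virtual cores have no
raster areas. Each kept core is scored like a TMA spot (its own cells form
the neighborhood graph) and the section risk is the maximum core risk.
Heterogeneity uses the exact one-way decomposition: total spot-risk
variance = within-patient + between-patient components.

## Reporting

Stacked histograms are ordered by the first kernel principal component
(Gaussian kernel, length scale 1/d in the convention exp(−‖x−y‖²/2ℓ²),
i.e. γ = d²/2 — other parameterizations of "length scale one over the
number of features" exist; this one is documented and fixed). The PC sign
is pinned by score skewness, a content-based rule that makes the sorted
output invariant to shuffling input rows; an index-based fallback covers
perfectly symmetric scores. Heatmap ordering reuses the immune-state
linkage (Euclidean, single, after log1p + column z-scoring). The niche
atlas is a UMAP embedding with n_neighbors = 100, min_dist = 8, spread = 8
— min_dist far above the conventional (0, 1] range is passed through as
specified upstream; it scatters points so composition glyphs do not overlap.

## Synthetic cohorts: what they are and are not

No generative model exists for the real data; every distributional choice
in `cellniche.synthetic` is a stand-in that encodes the statistical
structure the analysis assumes. Cells follow a Neyman-Scott-style cluster
process (parent seeds uniform in the spot disk with intensity ∝ archetype
weight, isotropic Gaussian offsets with the prototype's σ, offsets
resampled to stay in the disk); marker calls are independent Bernoulli per
prototype; per-spot counts are Poisson with a mean-one log-normal
patient intensity (σ_log = 0.5), reproducing the right-skewed, heavy-tailed
counts of real cohorts. Survival is exponential under proportional hazards
(baseline 0.01/month at z = 0; the simplest PH-consistent choice —
adequacy here means parameter recovery, not hazard-shape realism), with
independent exponential censoring at rate c/(1−c)·λ so the expected
censored fraction is exactly the configured c (0.3 by default) for every
patient. Defaults: 4 spots of 1.5 mm per patient, ~350 cells per spot,
three planted prototypes (carcinoma CK-dominant, mixed lymphocyte,
macrophage; σ = 15 µm) and three archetype mixtures spanning
carcinoma-heavy to immune-rich, hazard loading β = −1 on the lymphocyte
niche and +0.5 per stage.

Passing tests on these cohorts establish that the pipeline recovers
planted spatial and survival structure under its own model assumptions
(ARI ≥ 0.9 for separated prototypes, calibrated null behavior, planted
hazard recovery). They do not establish performance on real tissue, where
marker calls are correlated within cells, compartments are spatially
contiguous rather than prototype-attached, cell counts and censoring are
not exponential-family clean, and the true niche structure is unknown.

## Numerical conventions and limitations

* Radius and QC comparisons are inclusive; niche and k-means seeds are
  explicit everywhere; all generator randomness derives from one seed.
* c-index pair conventions for exactly tied event times follow lifelines;
  the oracle-equivalence guarantee is stated for continuous (tie-free)
  times.
* Test problem sizes (e.g., 400/200-patient survival cohorts, 50
  replicates, 200 null repetitions, 300-cell oracle spots) were chosen as
  the smallest sizes at which the checked effects are well-resolved.
* The immune-state cluster count k and the TME thresholds are user
  parameters: no numeric criterion for them is canonical, so nothing is
  auto-selected.
* Multi-way (more than two niche sets) matching and raster-mask handling
  are out of scope.
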