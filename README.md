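# cellniche

Spatial cell-niche phenomics for multiplexed immunofluorescence (mIF) tissue
microarray (TMA) cohorts in non-small cell lung cancer.

Clinical risk stratification of resected NSCLC relies on UICC8 TNM staging,
which ignores the tumor microenvironment (TME). This package implements an
image-free analysis pipeline that starts from per-cell boolean calls for a
12-marker mIF panel (CK, CD3, CD4, CD8, CD20, CD56, CD68, CD163, FOXP3,
PD-1, PD-L1, Granzyme B) plus a tissue-compartment label, and produces:

* **Phenotypes** — a first-match gating table mapping each cell's marker
  vector and compartment to 43 fine / 23 medium phenotype classes
  (lineage precedence CK > CD3 > CD20 > CD56 > CD163/CD68; GrB = activated,
  PD-1-only = exhausted, PD-L1 = immunosuppressive, FoxP3 = regulatory).
* **Immune states** — single-linkage clustering of per-spot density
  profiles and a 2×2 TME typing (PD-L1 × TIL).
* **Cell niches** — for every cell, the marker-positive counts within its
  34 µm neighborhood, log1p-saturated and normalized to a composition
  vector; mini-batch k-means++ (batch 8000) defines k = 10 prototypical
  neighborhoods, each cell is assigned to its nearest prototype, and spots
  are summarized by niche proportions. Niche profiles are classified hot
  (lymphocyte-lineage fraction ≥ 0.25) or cold.
* **Niche matching** — independently derived niche sets (LUAD vs LUSC) are
  compared with the symmetric chi-squared distance
  `d(x, y) = Σᵢ (xᵢ − yᵢ)² / (xᵢ + yᵢ)` on their phenotype distributions
  and matched by exact partial optimal transport; the number of genuine
  pairs is selected at the elbow (maximum second difference) of the
  log-transport-cost curve.
* **Survival** — cohort selection (stage I–III, R0, no adjuvant therapy,
  ≥ 3 months follow-up), propensity matching across centers, Yeo-Johnson
  normalization, censored-data mRMR feature selection (relevance =
  univariate Cox c-index, redundancy = mean |Pearson r|), ridge Cox on spot
  rows, and max-pooled ("hot-spot") patient risks; evaluation by Harrell's
  c-index, the relative improvement over the clinical baseline
  `(c_model − 0.5) / (c_baseline − 0.5)`, risk tertiles RS1–RS3 with
  Kaplan-Meier / log-rank, paired bootstrap comparison, and a
  stage-vs-risk restratification table.
* **Whole-section validation** — virtual 1.5 mm cores tiled over a section,
  section risk = max core risk, TMA concordance and intra-/inter-tumoral
  risk variance decomposition.
* **Synthetic cohorts** — because comparable patient-level data is access
  restricted, a cluster-point-process generator plants niche prototypes,
  skewed cell counts and proportional-hazards survival with known ground
  truth; all tests run against it.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
import cellniche as cn

config = cn.SimulationConfig(
    n_patients_per_center_per_subtype=50,
    hazard_betas=np.array([0.0, -3.0, 0.0, 0.4]),  # protective lymphocyte niche + stage
    seed=1,
)
cohort = cn.generate_cohort(config)
cells, spots, patients = (cohort.dataset.cells, cohort.dataset.spots,
                          cohort.dataset.patients)

feats = cn.neighborhood_features_by_spot(cells)           # 34 um compositions
niche_model = cn.fit_niche_model(feats, k=3, seed=0)
cells = cells.assign(niche_id=cn.assign_niches(feats, niche_model))
print(adjusted_rand_score(cohort.cell_truth["prototype"], cells["niche_id"]))

_, props = cn.spot_niche_abundance(cells, k=3)            # spot niche proportions
rows = (props.reset_index()
        .merge(spots[["spot_id", "patient_id"]], on="spot_id")
        .merge(patients[["patient_id", "uicc8", "os_months", "event", "center"]],
               on="patient_id"))
train, test = rows[rows.center == "A"], rows[rows.center == "B"]
model = cn.fit_risk_model(train, ["niche_1", "niche_2", "niche_3", "uicc8"],
                          max_k=3, alpha=0.1)
risks = cn.predict_patient_risk(model, test)              # max over spots
```

Output (continuing with `concordance_index`, `relative_improvement`,
`stratify_tertiles` and `km_logrank` on the held-out center):

```
niche recovery ARI vs planted prototypes: 0.956
selected features: ['niche_1', 'uicc8', 'niche_3']
hold-out c-index: niche+stage model 0.584 vs UICC8 alone 0.547
relative improvement over UICC8: +78.9%
log-rank across risk tertiles: statistic 5.76, p = 0.0561
```

The niche model recovers the planted cluster structure almost perfectly and
beats the stage-only baseline on the held-out center; with 100 evaluation
patients the tertile separation is suggestive rather than conclusive, which
is the honest outcome at this cohort size. The percentage is the gain on the
informative part of the c-index scale (everything above the 0.5 chance
level), so modest absolute gains translate into large relative ones when the
baseline is close to chance.

A thin CLI wraps the common steps:

```sh
cellniche simulate --out cohort/ --seed 1 --n-patients 25
cellniche qc --data cohort/
cellniche phenotype --data cohort/ --out cells_phenotyped.tsv
cellniche niches --data cohort/ --k 10 --model-out niches.json
cellniche match --profiles-a luad.tsv --profiles-b lusc.tsv --out pairs.tsv
```

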