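# lungmorph

Nuclear morphometry and multimodal modelling for non-small-cell lung cancer
histology.

`lungmorph` is a reusable, tested implementation of a tabular
histology-plus-omics pipeline for the two major NSCLC subtypes, lung
adenocarcinoma (LUAD) and lung squamous cell carcinoma (LUSC). It goes from
H&E tile images and per-patient clinical/genetic tables to per-nucleus
morphometry features, merged per-nucleus factor tables, correlation-based
factor screening, and subtype / 1–3-year overall-survival classification with
a full metric report. A synthetic-cohort generator with plantable class
effects stands in for controlled-access cohort data, so every stage runs and
is verified at desk scale.

## What the pipeline computes

**Image preparation.** Slides (or any large RGB images) are cut into
fixed-size tiles on a row-major grid; tiles that are mostly unstained
near-white background are excluded; colour variation between slides is
removed by per-channel histogram matching to a reference image.

**Segmentation and quality filtering.** A small U-shaped encoder–decoder
(NumPy implementation, im2col convolutions, Adam) is trained on (tile, mask)
pairs and produces per-pixel foreground probabilities. Thresholded maps are
labelled into 8-connected nucleus instances, each with area *A*, perimeter
*P* (outer-boundary polygon arc length, diagonal steps √2) and compactness
*C = P²/A* (minimal, 4π, for a disc). Per image, Otsu's method — between-class
variance maximisation on the feature histogram — sets adaptive thresholds on
area and compactness; instances with *A* below the area threshold or *C*
above the compactness threshold are removed as fragments and ragged false
detections.

**The 20-feature nuclear vector.** Per kept nucleus: mean and population
variance of R, G, B inside the nucleus (6); area, perimeter, circularity
*4πA/P²*, compactness *P²/A*, eccentricity *√(a²−b²)/a* of the
moment-equivalent ellipse, and the seven Hu moment invariants of the binary
silhouette (12); mean and population variance of the diagonal-detail (cD)
subband of a single-level 2-D Haar wavelet transform of the masked grayscale
patch (2).

**Factor integration.** Clinical strings are encoded to small integers (sex,
race, TNM, stage); survival status at 1/2/3 years is a three-class label
(0 unknown / 1 death / 2 survival). GISTIC-style copy-number amplitudes *t*
discretise to 0 (*t* ≤ 0.1), 1 (0.1 < *t* ≤ 0.9), 2 (*t* > 0.9); MAF variant
classifications binarise to non-synonymous (1) vs synonymous (0) over a closed
vocabulary; mRNA values pass through. Everything joins on the patient
barcode; each patient is balanced to exactly 200 nucleus rows (random
subsampling above, random duplication below); patients split 60/20/20 into
train/validation/test, stratified by subtype. The subtype design matrix is
20 nuclear + 26 mRNA = 46 factors; the survival design uses all
20 + 7 + 15 + 27 + 26 = 95 factors.

**Screening and modelling.** Each factor is screened by Pearson correlation
with the task label (retained iff |r| > 0.05 and p < 0.05, p from the exact
t-statistic with n−2 degrees of freedom); the factor–factor correlation
matrix flags collinear pairs (|r| > 0.8). Classifier families — LightGBM,
XGBoost, random forest, AdaBoost, MLP, plus optional adapter slots for
tabular-attention and 1-D CNN models — are tuned over their published
candidate grids by validation accuracy, refit on train, and evaluated once on
test with accuracy, macro one-vs-rest precision/recall/F1, trapezoidal
ROC-AUC (equal to the Mann–Whitney rank statistic), confusion matrices and
fit durations.

## Worked example

```python
from lungmorph.synthetic import CohortSpec, generate_cohort, render_tile, \
    sample_feature_rows
from lungmorph.assemble import build_patient_table, assemble
from lungmorph.screening import screen_factors
from lungmorph.modeleval import default_spaces, run_experiment
from lungmorph.segment import binarize_and_label, filter_instances
from lungmorph.nucfeat import extract_features

spec = CohortSpec(n_patients_class1=60, n_patients_class2=60, seed=0,
                  class_effect={"area": 0.25, "expression": 1.0})
cohort = generate_cohort(spec)

# image arm: render one tile, segment, measure
res = render_tile(cohort[0], n_nuclei=12, seed=0, tile_size=128)
instances = binarize_and_label(res.mask.astype(float))
filt = filter_instances(instances)
print(f"{len(instances)} instances, {len(filt.kept)} kept "
      f"(area threshold {filt.area_threshold:.1f}, "
      f"compactness threshold {filt.compactness_threshold:.2f})")
features = extract_features(res.tile, instances,
                            patient_id=cohort[0].patient_id)
print(features[["Area", "Perimeter", "Circularity", "Eccentric"]]
      .head(3).round(3))

# tabular arm: planted-signal cohort, screen, model
patients = build_patient_table(p.to_raw() for p in cohort)
rows = sample_feature_rows(cohort, seed=0, rows_per_patient=60,
                           effects={"Area": 1.0, "Perimeter": 1.0})
dataset = assemble(rows, patients, task="subtype", target=60, seed=0)
print(f"{len(dataset.rows)} rows x {len(dataset.feature_columns)} factors")
report = screen_factors(dataset)
print(f"retained {len(report.retained)}/{len(report.results)} factors")
ev = run_experiment(dataset, families=("xgboost", "random_forest"),
                    spaces=default_spaces(strategy="random", budget=4, seed=0),
                    feature_subset=report.retained, seed=0)
for fam, m in ev.models.items():
    print(f"{fam}: accuracy={m.metrics.accuracy:.3f} AUC={m.roc.auc:.3f}")
```

prints

```
12 instances, 2 kept (area threshold 135.6, compactness threshold 12.49)
    Area  Perimeter  Circularity  Eccentric
0  194.0     49.213        1.007      0.615
1  104.0     35.556        1.034      0.644
2   77.0     30.971        1.009      0.672
7200 rows x 46 factors
retained 27/46 factors
xgboost: accuracy=0.917 AUC=0.902
random_forest: accuracy=0.876 AUC=0.904
```

The rendered nuclei are near-elliptical (circularity just above 1 reflects
the discrete-grid perimeter of small blobs); the adaptive quality filter
always splits each tile's population at its Otsu thresholds, here keeping the
two largest, roundest instances. In the tabular arm the planted 1-SD shift on
two shape factors plus a 1-SD expression shift on four genes is enough for
boosted trees to reach test AUC ≈ 0.9 on held-out patients.

A thin CLI mirrors the library:
`lungmorph simulate | tile | normalize | segment | build`.

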