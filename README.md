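# odyn

Slide-level analysis of oral epithelial dysplasia (OED) downstream of deep
segmentation: OED classification from segmentation masks and a weakly
supervised malignant-transformation risk score built from interpretable
nuclear features.

OED is a potentially malignant diagnosis of oral mucosal lesions; manual
WHO/binary grading predicts progression poorly and varies between
pathologists. This package implements the analysis layer of an
AI-based grading pipeline for pathologists and computational-pathology
researchers who already have per-slide **epithelium masks**, **dysplasia
masks** and **classed nuclear instance annotations** (e.g. from
HoVer-Net-style and Transformer-based segmentation models), plus a clinical
follow-up table. It does not perform segmentation itself.

## What it computes

**OED classification.** The dysplasia–epithelium ratio

&nbsp;&nbsp;&nbsp;&nbsp;*R*<sub>Epith</sub> = |dysplasia ∩ epithelium| / |epithelium|

is computed per slide from co-registered binary masks; a slide is called
dysplastic when *R*<sub>Epith</sub> ≥ *t*, with *t* chosen on a training
set to maximize the F1-score of the dysplastic class (candidates are the
midpoints between consecutive sorted ratios).

**Transformation risk (the ODYN-score).** Dysplastic regions are
tessellated into 512 × 512 patches (256 px overlap, 0.5 µm/px). Each patch
is summarized by 168 nuclear morphological and spatial features over four
nucleus classes — dysplastic epithelial, normal epithelial,
intra-epithelial lymphocytes (IEL) and peri-epithelial lymphocytes (PEL) —
covering counts/densities, shape moments (area, perimeter, circularity,
eccentricity, axis lengths, solidity, equivalent diameter),
nearest-neighbour and Delaunay-graph statistics, area fractions and
class-mixing indices. A 168-64-2 MLP (leaky ReLU, dropout 0.2) scores each
patch; it is trained with **iterative draw-and-rank sampling** (IDaRS:
each epoch every slide contributes its k = 5 patches ranked highest for
the slide's own label plus r = 45 random patches, batch size 256) under a
**symmetric cross-entropy** loss (cross-entropy plus reverse cross-entropy
with clamped log 0) with Adam. The slide-level ODYN-score is the mean of
the top 50% of patch scores.

**Evaluation protocol.** Patient-grouped, outcome-stratified 5-fold
cross-validation repeated 3 times (15 models; 90/10 inner split selects
the checkpoint), external scoring by ensembling all 15 models,
AUROC/AUPRC, Kaplan-Meier curves with log-rank tests (conservative
combined p = 2 × median over repeats), Harrell's C-index, multivariate Cox
models (Efron ties, right-censoring at 96 months), and the top-ten-tile
nuclear count / area-ratio comparison between correctly predicted
transforming and non-transforming slides (Shapiro-Wilk gate, two-tailed
Mann-Whitney U with rank-biserial effect sizes, Benjamini-Hochberg FDR).

A **synthetic cohort generator** (`odyn.synthetic`) emulates all inputs —
mucosa-like epithelium bands, contiguous dysplastic sub-bands, elliptical
nuclei with per-class morphology, and exponential time-to-transformation —
with a single `nuclear_effect` dial controlling how strongly transforming
slides differ. Every stage of the package is testable against it.

## Worked example

```python
from odyn.synthetic import SynthConfig, generate_cohort
from odyn.pipeline import classify_cohort, run_synthetic_pipeline
from odyn.scoring import CVPlan
from odyn.mlp import TrainConfig

cfg = SynthConfig(n_patients=30, n_controls=10, nuclear_effect=1.0, seed=5)
cohort, bundle = generate_cohort(cfg)

labels = {r.slide_id: int(r.who_grade is not None) for r in cohort}
table, threshold = classify_cohort(bundle, labels)
print(f"R_epith threshold: {threshold.threshold:.3f}  "
      f"training F1: {threshold.training_f1:.2f}")

feats, cv, ev = run_synthetic_pipeline(
    cohort, bundle, CVPlan(seed=5), TrainConfig(epochs=30, seed=5))
print(f"out-of-fold AUROC (pooled): {ev.auroc_pooled:.3f}")
print(f"C-index (mean over repeats): {ev.c_index_mean:.3f}")
print(f"conservative log-rank p: {ev.conservative_p:.4f}")
```

Output:

```
R_epith threshold: 0.154  training F1: 1.00
out-of-fold AUROC (pooled): 1.000
C-index (mean over repeats): 0.774
conservative log-rank p: 0.0071
```

The threshold separates the 10 control slides (R_epith = 0) from the 30
dysplastic ones perfectly (F1 = 1.0). With a 1-SD nuclear effect, the
cross-validated ODYN-score separates transforming from non-transforming
slides (AUROC 1.0 on this small cohort), ranks shorter
transformation-free survival higher (C = 0.77), and splits the
Kaplan-Meier curves of its high/low risk groups (p ≈ 0.007).

The same stages are available as a CLI:

```bash
odyn synth --out cohort/ --seed 5
odyn fit-threshold --cohort cohort/cohort.csv --masks cohort/ --out thr.json
odyn features --cohort cohort/cohort.csv --masks cohort/ --nuclei cohort/ --out feat/
odyn score-train --features feat/ --cohort cohort/cohort.csv --out run/
odyn evaluate --scores run/oof_scores.csv --cohort cohort/cohort.csv --out report/
```

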