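# Methods

This note documents the models and procedures implemented in `odyn`, the
choices made where a published protocol leaves details open, what the
synthetic generator does and does not emulate, and known limitations.

## OED classification by the dysplasia–epithelium ratio

Inputs are two co-registered binary masks per slide (any nonzero pixel is
positive; mismatched shapes raise before any computation). The ratio

R_epith = |dysplasia ∩ epithelium| / |epithelium|

uses the *intersected* numerator: dysplasia pixels outside the epithelium
mask (segmentation disagreement) do not count, which guarantees
R_epith ≤ 1. Slides with zero epithelium pixels are flagged
"no epithelium" and excluded from classification with a logged count —
they are never silently assigned 0.

Threshold selection sweeps the midpoints between consecutive sorted unique
training ratios plus {0, 1} and keeps the candidate maximizing the F1 of
the dysplastic class; ties break toward the smaller threshold, and
classification uses the inclusive rule R_epith ≥ t so the fitted threshold
itself classifies as dysplastic. Training AUROC is reported alongside.

## Patch tessellation

Scoring patches are 512 × 512 px with 256 px overlap at 0.5 µm/px
(`make_patch_grid` also supports the 184 px / 1.0 µm/px geometry used for
segmentation training elsewhere). Masks are rescaled to the target
resolution with nearest-neighbour interpolation (labels stay categorical).
Patches are half-open windows [x, x+512) × [y, y+512); when the regular
stride grid would leave an uncovered margin the final row/column origin is
shifted back so the last patch ends exactly at the region boundary —
shift-to-fit preserves the stated patch size without fabricating tissue.
Regions smaller than one patch yield a single zero-padded patch with a
logged warning.

Risk scoring uses tissue in the dysplastic regions alone: a patch enters
scoring when its dysplastic-pixel fraction is ≥ `min_coverage`
(default 0.5; no published value exists for this cut, so it is
config-exposed). Slides with no qualifying patch are flagged and excluded
from scoring, never scored as empty.

## Nuclear compartments and the 168-feature vector

'Other'-class nuclei are split by the epithelium pixel under their
centroid into intra-epithelial (IEL) and peri-epithelial (PEL)
lymphocytes; centroid-in-mask is used rather than polygon-overlap
fractions because it is unambiguous and cheap. Morphometrics are computed
from the contour polygon: area (µm²), perimeter (µm), circularity 4πA/P²,
eccentricity and major/minor axis lengths of the ellipse matching the
polygon's exact second central moments (shoelace forms, the same
normalization scikit-image uses for raster regions), solidity, and
equivalent diameter. Self-intersecting polygons are repaired by their
convex hull with a logged count.

The default registry emits exactly 168 features per patch:

* 4 classes × (count, density per mm², mean + SD of 8 morphometrics) = 72
* 4 classes × (within-class NN-distance mean/SD/min, Delaunay degree
  mean/SD, incident Delaunay edge length mean/SD/min, nuclear area
  fraction) = 36
* 12 ordered class pairs × cross-class NN-distance mean/SD/min = 36
* 6 unordered pairs × (Delaunay cross-edge fraction, kNN mixing index,
  k = 5) = 12
* 12 global features (total count/density, 4 class shares, overall NN
  stats, Delaunay degree mean/SD, edge-length mean).

A nucleus belongs to a patch iff its centroid lies in the half-open
window, so counts partition exactly on a non-overlapping grid; on the
overlapping scoring grid a nucleus may appear in several patches, which
matches the patch-independence assumption of the weakly supervised
learner. Statistics over empty sets are imputed 0 — the MLP input must be
finite, and the companion count feature keeps imputed zeros
distinguishable. The registry (names, class list, block structure) is
serialized to JSON and is data, not code: an alternative feature list of
the same shape can be slotted in without code changes.

## The scoring model

The patch scorer is a 168-64-2 MLP with leaky ReLU (slope 0.01) and
dropout 0.2 after the hidden layer, implemented directly in numpy with an
explicit backward pass and Adam — at this size a framework adds nothing,
and an explicit implementation makes single-CPU bit-reproducibility
trivial. Features are z-scored with moments fitted on the training slides
only; constant features pass through centred.

The loss is symmetric cross-entropy: α·CE + β·RCE, where RCE swaps
prediction and one-hot label and the resulting log 0 is clamped to a
finite constant A, giving RCE = −(1 − p_y)·A per sample. Defaults
α = β = 1, A = −4 follow the loss's originating convention; β = 0 reduces
exactly to cross-entropy (asserted to 1e-12 in tests). The analytic
gradient of both terms is verified against finite differences.

Training uses iterative draw-and-rank sampling: per epoch each slide
contributes its k = 5 patches currently ranked highest by the probability
of the slide's own label (the standard ranking rule for this sampler)
plus r = 45 uniform random patches; the epoch-0 ranking is uniform
random; slides with ≤ k + r patches contribute everything without
replacement. Minibatches of 256 are optimized with Adam at learning rate
1e-3 for 50 epochs by default (30 in the desk-scale reference runs below
— the cohorts are small and converge early). When a validation split is
supplied, the parameters of the epoch with the best validation slide
AUROC are kept; the published protocol holds out 10% of training data
without stating its purpose, and checkpoint selection is the natural use.

The slide-level ODYN-score is the mean of the ⌈n/2⌉ highest patch scores
(odd counts round up: never empty, deterministic). Risk groups for
survival analyses dichotomize at 0.5 by default; no published cutoff
exists, and the value is config-exposed.

## Cross-validation and ensembling

Patients — not slides — are assigned to 5 outcome-stratified folds
(scikit-learn's grouped stratified splitter), repeated 3 times with
distinct derived seeds, giving 15 models and one out-of-fold score per
slide per repeat; the mean over repeats is the slide's reported score.
External cohorts are scored by averaging the 15 models' slide scores.
A single root seed fixes fold assignment, the inner 90/10 patient split,
sampling, initialization and therefore every emitted score; reruns are
bit-identical.

## Evaluation statistics

AUROC uses the rank (Mann-Whitney) formulation with midrank ties; AUPRC
uses step-wise precision-recall integration. Mask-level F1/recall/
precision are pixel counts over co-registered masks; for all-negative
control slides a single specificity TN/(TN+FP) is reported instead, since
one false-positive pixel would zero out F1.

Mann-Whitney U counts pairs with x > y plus half-ties; the rank-biserial
effect size is r_rb = 2U/(n_x n_y) − 1. The two-tailed p-value is exact
when n_x·n_y ≤ 400 — computed by a subset-sum dynamic program over
doubled midranks, i.e. the exact permutation null over group assignments,
which handles ties and is equivalent to full enumeration — and otherwise
a normal approximation with tie and continuity corrections. Spearman's ρ
is computed on midranks with a permutation p-value
(1 + #{|ρ*| ≥ |ρ|}) / (n_perm + 1). Shapiro-Wilk (scipy) gates normality;
Benjamini-Hochberg FDR (statsmodels) adjusts within each measure family
with input order preserved.

Survival analyses right-censor at 96 months before any fit: later events
become censored at the horizon. Kaplan-Meier curves, log-rank tests,
Harrell's C (score ties count ½) and multivariate Cox models delegate to
lifelines; Cox uses Efron tie handling because month-resolution times tie
often. The conservative combined p across CV repeats is
min(1, 2 × median of per-repeat log-rank p). Survival analyses run at
slide level by default (one slide per patient in the reference cohorts);
categorical covariates are one-hot encoded with the first level dropped.
WHO-grade comparisons support both stratifications: G1 (mild vs
moderate/severe) and G2 (mild/moderate vs severe).

The top-tile feature analysis takes the ten highest-scoring patches of
each correctly predicted slide (true positives vs true negatives under
the same dichotomization as the KM risk groups) and compares per-patch
counts of the four nucleus classes and the patch's partition into other
tissue / dysplastic epithelium / normal epithelium, via the
Shapiro-Wilk-gated Mann-Whitney pipeline above.

## The synthetic generator

Each slide is a smoothed epithelial band (sinusoidal centre-line and
thickness, ~50% of a 1536² canvas at 0.5 µm/px) with the dysplastic
region a contiguous sub-band occupying a per-slide fraction of the band
thickness drawn from U(0.3, 0.7) — the subset invariant
dysplasia ⊆ epithelium holds by construction. Nuclei are 16-vertex
ellipse polygons with per-class lognormal areas (means 52/42/18 µm² for
dysplastic epithelial / normal epithelial / other; CVs 0.25/0.15/0.12)
placed with non-overlapping centroids (greedy 8 px minimum spacing shared
across classes) at densities of 2400 (epithelial), 300 (intra-epithelial
other) and 350 (stromal other) per mm². These densities are deliberately
~2× sparser than real oral mucosa to keep generated cohorts small; the
geometry, not the absolute density, carries the signal.

`nuclear_effect` is a standardized effect size applied only to
transforming slides: the dysplastic-nucleus area mean shifts up by that
many within-class SDs, its CV inflates by 30% per unit effect
(pleomorphism), and stromal 'other' density rises 50% per unit effect.
Event times for transforming patients are truncated-exponential within a
120-month administrative horizon with rate (ln 2 / 60) · exp(effect), so
larger effects also shorten time-to-event; non-transforming patients are
censored at the horizon, or earlier with probability `censor_rate`.
Transformation is assigned to exactly round(n · fraction) patients by a
sorted uniform draw; all slides of a patient share the outcome. A single
integer seed drives per-slide substreams
(SeedSequence spawn keys), so regenerating one slide is independent of
generation order. The default per-outcome dysplasia-fraction ranges are
identical, so at `nuclear_effect = 0` the outcome-conditional feature
distributions are exactly exchangeable — a clean null.

What the generator does **not** emulate: real nuclear texture and
staining, spatially structured dysplasia (fields, drop-shaped rete
ridges), grade-dependent architecture, scanner effects, annotation noise,
or multi-lesion slides. Passing tests therefore demonstrate that the
pipeline recovers a known signal of the stated form and size — not
clinical performance on real slides.

## Reference problem sizes

The reference runs (tests and `scripts/acceptance.py`) use 60-patient
cohorts (plus 20 controls for classification), 30 training epochs, and
two independent zero-effect cohorts whose pooled AUROCs are averaged for
the chance-level calibration; Cox recovery uses n = 500 with true
log HR = 0.7. These sizes give stable estimates while keeping a full run
in minutes on one CPU.

## Known limitations

* The 168-feature registry reconstructs the stated feature *family*
  (morphological + spatial over the four nucleus classes, totalling 168);
  name-level fidelity to any particular published list is not claimed,
  and the registry is replaceable data.
* The top-tile analysis conditioned on *correctly predicted* slides is
  subject to selection bias: even at the exact null, models fit noise
  aligned with the dominant between-slide variance direction (here the
  per-slide dysplasia fraction), so the selected TP/TN groups can differ
  significantly in dysplasia-geometry measures; per-patch testing
  additionally treats correlated tiles of one slide as independent. The
  test suite documents this behaviour rather than hiding it: the
  zero-effect FDR check is expected to fail under these study conditions.
* Epochs, learning rate and the checkpoint criterion are not externally
  specified; the defaults above are the package's own and config-exposed.
* Survival models assume proportional hazards and are run without
  diagnostics beyond convergence checks; no competing-risks handling.
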