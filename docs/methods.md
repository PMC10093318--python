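# Methods

This note documents the models and procedures `urisedclass` implements,
the defaults and why, the synthetic benchmark's scope, and the numerical
choices a maintainer would need to know.

## The pipeline

Urine-sediment particle crops are classified by fusing two complementary
per-image representations:

```
images ──► uniform LBP (2891) ──► mRMR k=500 ─┐
                                              ├─► fuse (1000) ─► classifier ─► metrics
images ──► dense features (1000) ─► mRMR k=500 ┘
```

The texture descriptor captures micro-structure (granularity, edges,
periodicity); the dense block captures coarser, multi-scale structure.
Selection before fusion keeps the fused dimension fixed at 1000 and
removes redundant histogram bins.

## Uniform LBP

For each interior pixel with value `x_c`, the 8 neighbours `x_i` at angle
`2πi/8` counter-clockwise from east (radius 1, nearest 8-connected
sampling by default) produce the code `Σ_i [x_i ⊵ x_c]·2^i`.

* **Tie rule.** `⊵` is `>=` by default (`geq_is_one`), the standard
  convention: it makes constant regions well-defined (all-ones code).
  `gt_is_one` is available for sensitivity checks.
* **Uniform mapping.** Codes with at most two circular 0↔1 transitions
  get individual bins — `P(P−1)+2 = 58` of them for `P = 8` — and every
  other code shares one catch-all bin, giving 59 bins.  (For `P ≤ 3` every
  pattern is uniform and the catch-all bin is empty but still allocated.)
* **Descriptor geometry.** Border policy is "valid": the code map is
  `(H−2R)×(W−2R)`.  It is partitioned into a 7×7 grid with cell
  boundaries at `round(k·H′/7)`, and per-cell 59-bin histograms are
  concatenated row-major: `59 × 49 = 2891` features.  This is the unique
  standard uniform-LBP configuration with that dimension.
* **Normalization.** Default is raw counts (mass = number of coded
  pixels); `per_cell_fraction` divides each cell's histogram by its mass.
* **Invariances.** The descriptor is exactly invariant to any strictly
  increasing intensity remapping, and the code map to additive shifts.
  It is *not* rotation-invariant (bit order encodes orientation), which
  is intentional: orientation is a class cue here.
* The bit ordering (east = bit 0, counter-clockwise) changes code values
  but not the information content of uniform-bin histograms; it is fixed
  and documented so code maps are comparable across runs.

## Dense features: the filter-bank surrogate

The pipeline's second block has the shape of a pretrained CNN's final
fully-connected layer (1000 units, 224×224 input).  Pretrained weights
cannot be assumed in an offline environment, so the built-in backend is a
deterministic surrogate that preserves the structural contract — dense,
fixed-length, image-dependent, seed-reproducible:

1. resize to 224×224 (bilinear; intensities scaled to [0, 1]);
2. box-blur at 3 scales (2, 4, 8 px); at each scale take oriented odd
   (`f(x+d) − f(x−d)`) and even (`f(x+d) + f(x−d) − 2f(x)`) differences
   along 4 directions — band-pass filters that annihilate constants;
3. pool response magnitudes over a 4×4 grid, plus 16 local-mean (DC)
   cells: 3·4·2·16 + 16 = 400 raw responses;
4. project to `output_dim` with a seed-fixed Gaussian random matrix
   (`N(0, 1/400)` entries).

The surrogate makes no fidelity claim to any particular network; an
actual pretrained extractor can be plugged in via `register_backend` and
is used identically downstream.  Shifts use periodic wrap; the artefacts
this introduces at image borders are identical across images and carry no
class information.

## mRMR

Greedy forward selection.  Relevance of feature `f` is `I(f; y)` (plug-in
mutual information in bits, after per-feature equal-width discretization
into `bins` levels) for MID/MIQ, or the one-way ANOVA F statistic for
FCD/FCQ.  Redundancy against the selected set `S` is the mean pairwise
`I(f; s)` (MID/MIQ) or mean `|Pearson r(f, s)|` (FCD/FCQ).  Scores:
`relevance − redundancy` (MID/FCD) or `relevance / redundancy` (MIQ/FCQ).

* **Defaults.** `criterion="MID"`, `bins=10`, `k=500` per block.
* **Discretization.** `floor(bins·(x−min)/(max−min))` clipped to
  `[0, bins−1]`; constant features map to all zeros (and have zero MI
  with everything).
* **Degenerate F.** Zero within-class variance with non-zero between
  yields `+inf` (logged); such a feature is picked first.
* **Quotient floor.** Mean redundancy is clamped at `1e-12` before
  division, so the second pick is defined even when the first selected
  feature is independent of everything.
* **Tie-break.** Scores within `1e-9` (relative) of the step maximum are
  treated as tied and the lowest feature index wins.  The tolerance
  matters: two exact copies of the same signal have mathematically equal
  MI whose float values differ by summation order, and a bitwise argmax
  would make the selection depend on implementation details.
* **Complexity.** Relevance is computed once; redundancy is a running
  mean updated with one pass against the newest selected feature.  Joint
  histograms for a whole block are accumulated by a one-hot matrix
  product, chunked over features to bound memory; results are identical
  to the naive per-pair double loop (tested against it).

## Classifiers and evaluation

Six classical classifiers with fixed, point-and-click-style defaults
(scikit-learn implementations):

| kind | estimator | defaults |
|---|---|---|
| `fine_tree` | DecisionTree | Gini, ≤100 splits (`max_leaf_nodes=101`) |
| `linear_discriminant` | LDA | `lsqr` solver, shrinkage `1e-6` |
| `gaussian_naive_bayes` | GaussianNB | variance floor `1e-9` |
| `svm` | SVC | linear kernel, C=1, one-vs-one, standardized inputs |
| `knn` | KNeighbors | k=5, Euclidean, standardized inputs |
| `ensemble_bagged_trees` | Bagging | 30 bootstrapped trees |

Standardization (train-fold mean/sd) applies to the distance- and
margin-based classifiers (SVM, KNN) inside the fitted pipeline, so no
evaluation data leaks into the scaler.  LDA uses convex shrinkage of the
pooled covariance (`1e-6`), the closest regulariser sklearn's non-SVD
solver exposes to a small additive ridge.

Evaluation is stratified: holdout (per-class train count
`floor(f·n_c + 0.5)`, remainder to test) or k-fold CV (default 5 folds)
whose pooled out-of-fold confusion matrix spans every sample.  All
randomness flows from explicit seeds; per-stage seeds derive from the
global seed by SHA-256, so adding a stage never perturbs another.

**Selection placement.**  The pipeline's default runs mRMR on the full
matrix *before* CV, matching the common (and optimistic) practice in the
benchmark literature this pipeline mirrors.  This leaks label information
into the evaluation: on pure-noise data it lifts 8-class pooled accuracy
from ~12.5% to ~20%.  A nested mode (`nested=true` in the config,
`train_eval_nested` in the API) re-runs selection inside each training
fold and is the statistically sound choice; the separability probe always
uses it, since its chance-level control is meaningless otherwise.

## Metrics

Per class: recall (= sensitivity), precision, specificity, and their
exact complements FNR/FDR/FPR; F1 is the harmonic mean of precision and
recall; overall accuracy is `100·trace/total`.  Computation is exact; the
benchmark-layout renderer *truncates* to two decimals (30/70 → 42.85),
matching how such tables are conventionally printed, while
accuracy-comparison summaries round to one decimal (7280/8509 → 85.6).
In the benchmark layout the first column ("accuracy") is per-class recall
and the second ("sensitivity") is precision; the library's own tables use
the unambiguous names.  Classes with no true samples (or never predicted)
yield NA with a warning rather than a silent zero.

## Synthetic benchmark

`synthgen` emulates what the pipeline needs from real data — small
grayscale crops, 8 classes, heavy imbalance (1224/1842/240/432/2279/1734/
688/70; max:min = 2279:70), per-class texture signal — without claiming
visual realism.  Each class pairs a shape archetype with a texture:

| class | shapes | texture |
|---|---|---|
| bacteria | many small rods | grating 0.45 cyc/px, horizontal |
| crystal | polygons | checkerboard 0.25 cyc/px |
| cylinder | elongated cast | grating 0.12 cyc/px, vertical |
| epithelial | large polygon | faint grating 0.055 cyc/px |
| erythrocyte | rings | concentric rings 0.20 cyc/px |
| leukocyte | ovals | granular speckle |
| yeast | ovals | grating 0.30 cyc/px, oblique |
| others | irregular blobs | per-image random 3-grating mixtures |

Design principles: grating frequencies are spread by ≥1.5× and waveform
families differ, so classes are texture-separable *by construction*;
"others" combines the smallest count with per-image randomized mixture
textures (a family no named class uses), making it the hardest class —
the qualitative failure mode rare heterogeneous classes show in practice
— without colliding with the named classes.  Shapes cover a large
fraction of the frame so most descriptor cells see class texture rather
than background.  Per-image generators are seeded by
`(seed, class_index, image_index)`: byte-identical output independent of
generation order.

What a green synthetic run does **not** establish: performance on real
microscopy (staining, focus, illumination, segmentation artefacts,
inter-class visual similarity are all absent), the adequacy of the
surrogate relative to a pretrained CNN, or any specific accuracy number
on the public 8-class benchmark the composition mirrors.  The synthetic
probes establish that the machinery is sound: distinct-texture data is
classified far above chance (≥90% pooled CV accuracy at 50 images/class)
and identical-texture data falls to chance (12.5% ± 3 SE) when selection
is nested.

## Numerical and degenerate-input choices

* Grayscale conversion: BT.601 luminance (0.299R + 0.587G + 0.114B),
  rounded half-up; `first_channel` available.
* Images must be ≥3×3 (one LBP neighbourhood); code maps must be at least
  grid-sized; violations are fatal with the required minimum in the
  message.
* Feature matrices reject NaN/inf at construction; fusion validates
  sample-ID and label alignment row by row and names the first offending
  row.
* Corrupt image files are skipped with a warning; empty datasets, unknown
  labels, singleton classes (for splitting), and classes smaller than the
  fold count are fatal.
* Holdout split counts use round-half-up per class; with 8509 samples in
  the benchmark composition an 80/20 split yields 1702 test images
  (protocols reporting 1696 are within the per-class rounding ambiguity).
* CSV persistence uses `%.10g` floats; determinism tests compare bytes.

## Known limitations

* The surrogate's random projection makes individual dense features
  uninterpretable (by design; only the block's information content
  matters downstream).
* mRMR's MI estimates use a fixed equal-width discretization; heavily
  skewed features may want quantile bins (not implemented).
* `train_eval_nested` covers CV only; nested holdout would be a trivial
  extension but has no consumer here.
* The six classifier configurations are fixed defaults, not tuned; the
  harness deliberately excludes hyper-parameter search.
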