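# Methods

## The phantom and what it emulates

Each synthetic dataset mimics a temporal-mean T2*-weighted functional
acquisition of the cervical cord: 128×44 in-plane voxels of 1×1 mm and
25 axial slices of 3 mm (slice index increasing superior → inferior).
Per slice, the cord is an ellipse (default semi-axes ≈ 3.7 mm
anterior–posterior × 5.7 mm left–right, near published C7 cord
dimensions) whose center drifts smoothly along the cord; gray matter is
a four-lobed "butterfly" of scaled ellipses (two dorsal, two ventral,
plus a commissural bridge), intersected with the cord so GM ∪ WM
partitions the cord exactly. Intensities are per-tissue, per-slice
means (CSF outside the cord, WM/GM inside) plus independent Gaussian
noise; all generators are pure functions of spec + seed.

Default study conditions follow the design this pipeline analyses:
21 datasets, 8 simulated raters plus a perfect reference, a
superior→inferior decline of CSF signal (base profile 170 → 75 against
WM 100 / GM 120) with a dataset-level offset drawn in [−45, +35], so
many inferior slices show Adjacent:SC < 1 — the contrast-breakdown
pathology seen in real acquisitions — and per-slice noise s.d. of
roughly 3–10 (dataset base 3–7, slice factor 0.7–1.4).

The phantom deliberately omits MR physics (susceptibility, flow,
EPI distortion), physiological noise structure, and time-series
generation; activation maps are simulated z-maps, not GLM fits. Tests
passing on phantoms therefore validate the *analysis chain* — metric
definitions, inference calibration, propagation mechanisms — not the
behaviour of any particular scanner or preprocessing stack.

## The rater model

A simulated rater applies, per axial slice and in order: (1) a signed
morphological bias (|k| dilations or erosions with the 8-connected
3×3 element — a consistently generous or tight contourer); (2) a random
in-plane jitter translation (s.d. in mm, rounded to voxels); (3)
independent membership flips within the boundary band (slice-wise
Chebyshev distance ≤ 1 of the mask edge) with probability `flip_rate`.
All parameters zero reproduces the reference exactly; erosion that
empties a slice leaves a single centroid voxel with a logged warning.

No quantitative model of human contouring error exists for this
setting, so the default ladder (flip rates 0.02–0.22, jitter 0–0.5 mm,
two raters with ±1-voxel bias) was chosen once so that study-wide mean
DSC spans roughly 0.65–0.97, the plausible range between novice and
expert raters; the biased-but-consistent rater (F) reproduces the
qualitatively interesting case of low DSC with good downstream
stability. Slice difficulty is coupled to constructed image quality:
a slice's flip rate is scaled up where the Adjacent:SC ratio is low and
the adjacent CV high (standardised within dataset, gain 0.6), and a
dataset's overall flip rate scales with its mean contrast. This
coupling is the mechanism that downstream inference is expected to
detect; with the coupling disabled the correlations are null.

## Registration error and activation maps

Real registration is mask-weighted, so its error is modelled as the
per-slice centroid offset (in mm, rounded to voxels) between the rater
mask and the reference, applied to the image as a nearest-neighbour
in-plane translation while atlas masks stay fixed — keeping masks
binary and all metrics exactly computable. GM:WM contrast is then read
from the shifted image: aligned data give the constructed GM/WM ratio
(1.2 by default), and any tested shift mixes tissue classes and lowers
it. A rater's participant-level z-map is the reference activation
pattern carried through that rater's shifts plus Gaussian analysis
noise (s.d. 0.5) for pipeline differences downstream of registration;
group-level maps use a fixed-effects combination (Σ z_d / √D).

## Metric and inference conventions

* "2-voxel dilation" is two iterations of one-voxel 8-connected
  dilation, in-plane only (matching the 1×1×3 mm anisotropy); both the
  count and the per-slice DSC aggregation are configurable.
* Logit uses ε-clamping with ε = 10⁻⁶ so perfect-agreement cells stay
  usable in linear models; Fisher's z clamps |r| at 1 − 10⁻⁷.
* CV uses the sample (n−1) standard deviation, as does the rater s.d.
  σ_xi in the standardized comparison (8 raters by default).
* The per-dataset DSC response for ANOVA is the mean of slicewise logit
  DSC over included slices (the most superior and inferior slice are
  trimmed, n_trim = 1); the DSC analysis excludes the reference's own
  rows (8 × 21 cells, residual df 140), the GM:WM analysis includes the
  reference as a ninth rater (9 × 21 cells, residual df 160).
* The ANOVA is additive (no interaction) on one observation per cell,
  fitted via OLS with type-II sums of squares (equivalent to the
  balanced decomposition here); η² = SS_factor / SS_total. A constant
  response is reported as the degenerate case with η² = 0.
* The max-T permutation test draws independent within-pair slice
  permutations from one seeded generator; p-values use the add-one
  convention (1 + #{null ≥ |obs|}) / (B + 1), so the smallest
  attainable p is 1/(B+1). A pair with degenerate ranks — observed or
  permuted — contributes Fisher z = 0 rather than being dropped,
  keeping the pooled statistic's dimension constant across replicates
  (dropping would break exchangeability). Spearman uses average ranks
  for ties and requires ≥ 3 complete pairs.
* The hemicord center column is the single column at the rounded
  (half-up) left–right center of mass of the cord per slice. Half-up
  rounding makes the partition mirror-consistent except when a slice's
  centroid falls exactly between two columns, where no single-column
  choice can be; ties round up. Spatial correlation is Pearson on
  unthresholded z-values (Spearman available); thresholding uses strict
  Z > 2.3.
* Report heatmaps order raters and datasets by ascending marginal mean
  logit DSC; margin CIs are normal-approximation, mean ± 1.96·SE.

## Reproducibility and problem sizes

Every stage is deterministic given the run configuration: per-rater and
per-dataset seeds are spawned from one master seed via `SeedSequence`
spawn keys, so adding a rater never changes anyone else's data, and two
runs from one configuration are byte-identical in all tabular outputs.

The validation suite exercises the permutation test at the study's own
scale (8 raters × 21 datasets × 23 retained slices). Family-wise error
is estimated from 500 independent null table replicates at 1,000
permutations each (the vectorised rank engine makes this a ~1-minute
computation); power uses 200 replicates with a Spearman-0.5 dependence
injected through a Gaussian copula (Pearson r = 2·sin(π·0.5/6)).
Calibration replicates simulate the metric tables directly rather than
rendering 500 full image studies, since the test's operating
characteristics depend on the tables alone. The default full pipeline
run (image rendering included) takes a few seconds.

## Known limitations

* Misregistration is integer-voxel translation; rotations, scaling and
  non-linear warps are not modelled, so GM:WM degradation is a lower
  bound on real mixing effects.
* The difficulty coupling makes CV and Adjacent:SC strongly (inversely)
  related by construction; real data decouple them more.
* The rater ladder's variance split between rater and dataset factors
  is a design choice, not an estimate: with the default wide ladder the
  rater factor dominates the ANOVA, whereas real studies can show the
  reverse ordering.
* Group-level activation combination is fixed-effects only; mixed
  effects, cluster correction and TFCE are out of scope.
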