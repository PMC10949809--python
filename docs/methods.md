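# Methods

## Scientific problem

In memory-clinic populations with subjective cognitive decline (SCD) or mild
cognitive impairment (MCI), two prognostic questions drive management and
trial enrolment: will this patient receive an Alzheimer's-dementia diagnosis
within four years, and how fast will global cognition (MMSE) decline? The
package implements a controlled comparison of four model families for these
two outcomes — clinical data alone, clinical + hippocampal volume,
clinical + 68 regional gray-matter volumes, and a whole-brain multi-task 3D
CNN — under a shared double cross-validation design, so that differences in
measured performance reflect the predictors, not the evaluation protocol.

## Outcomes

**Progression.** A subject progresses if an AD-dementia diagnosis occurs at
any visit within the closed interval [0, 4] years from baseline
(`progression_label`). The synthetic pipeline derives the label directly
from the generator's group membership; the timeline rule exists for
real-data mode.

**MMSE slope.** Ordinary least squares of MMSE on visit time, fitted per
subject from all follow-up points with time ≤ 4 years (baseline included as
the t = 0 point), reported in points/year. At least two distinct visit
times are required; identical times raise a degenerate-design error.

## Synthetic cohort generator

The generator is the package's canonical input source and encodes the study
conditions:

* **Composition:** n = 332, 32.8% early-AD (progressors); a Bernoulli draw
  per subject by default, or the exact 223/109 split with `exact_counts`.
* **Group marginals** (mean ± SD; truncated Gaussians, resample on
  violation): age 70.2 ± 5.5 vs 72.1 ± 4.7 years (bounds [60, 80]),
  education 12.0 ± 3.7 vs 11.8 ± 3.5 years, baseline MMSE 28.2 ± 1.7 vs
  27.1 ± 1.7 (bounds [24, 30], the inclusion rule), ADAS delayed recall
  4.2 ± 2.4 vs 6.7 ± 2.1 errors (≥ 0), hippocampal volume 3339 ± 480 vs
  2927 ± 415 mm³, ICV 1136 ± 153 vs 1114 ± 107 cm³, female fraction
  0.475 vs 0.468. APOE ε4 counts are Binomial(2, p) with p = 0.2 / 0.5 so
  the group means match 0.4 / 1.0 (and the implied SDs, 0.57 / 0.71, sit
  close to the reported 0.6 / 0.7).
* **Longitudinal model:** annual visits {0..4} years. A true slope per
  subject is drawn from N(−0.2, 0.4²) (stable) or N(−1.5, 0.8²)
  (progressors) points/year; observed MMSE = baseline + slope·t + N(0, 1²),
  clipped to [0, 30]. Slope distributions and the 1-point test–retest noise
  are not published quantities; they were fixed once at values typical of
  memory-clinic cohorts (stable patients near-flat, progressors losing
  1–2 points/year) and all tests run under them.
* **Volumes:** the MRI (default 40³, native-space convention) is smoothed
  white noise plus a central bright sphere whose voxel count scales
  linearly with the subject's hippocampal volume; `mri_hippo_signal=False`
  removes the sphere, leaving the MRI purely uninformative. The JD map
  (default 32³, template-space convention) is a near-unit background —
  1.0 plus Gaussian registration-scale noise (SD 0.02), mirroring the
  residual variation real deformation maps carry everywhere — except a
  planted sphere (center (16,16,16), radius 6) whose value is exactly the
  subject's hippocampal volume divided by the stable-group mean: values
  < 1 encode contraction, proportional to the planted signal. The
  background noise matters beyond realism: with an exactly constant
  background the network gets no gradient pressure to null its background
  weights, which later corrupts occlusion maps. Grids are deliberately
  mismatched so the pipeline must crop MRIs and zero-pad JDs.
* **Regional volumes:** 68 regions with deterministic per-region baseline
  means (1.5–12 cm³, SD 12%); a 16-region "AD-signature" subset is shifted
  −0.4 SD in progressors. Features are group-conditionally independent —
  only the group label couples them to outcome — because only marginals are
  published.

Every draw descends from the config seed; volumes use per-subject
substreams, so cohorts and volumes are bitwise reproducible in any order.
(Stream tags are distinct nonzero integers: NumPy absorbs trailing zero
entropy words, so `default_rng([s, 0])` would collide with
`default_rng(s)`.)

**What the generator does not emulate:** anatomical structure, scanner
noise and site effects, correlated feature blocks (e.g. age–atrophy
coupling within group), missing visits, diagnosis-timeline dynamics, or
deformation-field physics behind real Jacobian determinants. Tests passing
on this generator therefore demonstrate that the *pipeline* recovers planted
statistical structure under realistic marginals and class overlap — not
clinical-grade performance on real MRI.

## Double cross-validation

Outer layer: subjects are partitioned into five near-equal test folds
({67, 67, 66, 66, 66} at n = 332), class-stratified by largest-remainder
apportionment. A candidate partition is accepted only if, for every fold,
dev-vs-test balance tests pass at α = 0.05 on diagnosis ratio, age,
education, APOE count (Welch t-test) and sex (Fisher's exact); otherwise
the whole plan is redrawn (up to `max_attempts`, default 10,000 — in
practice a few draws suffice because the ~25 tests are independent-ish null
tests). Rejection sampling guarantees the recorded constraint report
p-values are all ≥ α by construction.

Inner layer: each outer fold's development set is split into ten folds with
per-class largest-remainder counts (class proportions within one subject),
otherwise uniformly at random. Iterating the plan yields the 50 train /
validation / test triples; train and validation partition the development
set, so no test subject ever contributes to any training-set statistic.

## Preprocessing

* Feature tables: z-score with training-fold mean and population SD
  (ddof = 0 — fixed so exact-value tests are well-defined).
* CNN clinical inputs: min-max to [0, 1] on the training fold; held-out
  values extrapolate unclipped.
* MRI volumes: `v / (0.5 · gmax) − 1` into [−1, 1]. The reference maximum
  `gmax` is taken over the *training* volumes by default; a
  `global_max_scope="all"` option reproduces the variant that pools the
  entire image set, which is convenient but lets one extreme test voxel
  influence training inputs.
* JD volumes: passed through unscaled.
* Shape conformance: centered crop / symmetric zero-pad with odd remainders
  on the trailing side; crop∘pad on matched shapes is the identity.

## Multi-task network

Each image branch applies a strided 3×3×3 convolution (1→4 channels,
stride 2), a depthwise-separable convolution (depthwise 3³ stride 2 +
pointwise 1³ to 8 channels), batch normalization after each convolution
block, a 1³ channel reduction to 4, 2³ average pooling (when the grid
allows), and a dense embedding with per-position weights. The dense readout
is deliberately spatially specific: it is what allows block occlusion to
attribute performance to locations. Branch embeddings and the clinical
vector concatenate into a 16-unit fused layer feeding three single-unit
heads: progression (sigmoid + class-weighted binary cross-entropy; class
weight n/(2n_c)), MMSE slope (linear + MSE) and hippocampal volume
(linear + MSE). Regression targets are z-scored on the training fold so the
auxiliary weights operate on a comparable scale; predictions are mapped
back to native units.

Training: 50 epochs of Adam (lr 10⁻³, ×0.3 at epochs 20 and 40), batch 4,
loss `L = w1·L1 + w2·L2 + w3·L3` with `w = (1, 0.025, 0.025)` for the
progression-primary model (the slope-primary variant swaps the unit weight
onto L2). Regularization on the small-cohort regime: decoupled weight decay
10⁻², dropout 0.7 on the flattened position features, and proximal L1
(10⁻¹) on weight matrices, which pushes weights of uninformative positions
toward exact zero — both a guard against memorizing noise volumes and a
prerequisite for clean occlusion maps. Auxiliary-weight selection is a validation grid
search over {0, 0.025, 0.050, 0.075, 0.1}, ties to the smaller value. The
hippocampal-volume head doubles as an anatomical anchor: on synthetic data
its target is exactly the quantity encoded by the planted JD sphere, which
stabilizes what the imaging branches learn.

All layers (grouped/separable 3D convolutions, batch norm, dropout, dense,
Adam with milestone schedule) are implemented directly on NumPy with
explicit backpropagation (`mciprog.nn`); gradients are verified against
central finite differences in the test suite. Everything is deterministic
given the config seed, including batch order and dropout masks.

The parameter count is reported at build time and must stay under a config
ceiling (default 50,000; the default 32³ build uses ~3,800 parameters) — a
parameter-efficiency contract for the ~250-subject training folds.

Modality ablation retrains the same architecture with the MRI branch, the
JD branch, or neither zeroed out. By default the clinical vector is zeroed
as well, isolating the imaging contribution: with clinical covariates
included, their shared signal dominates both single-modality models and the
contrast between imaging modalities becomes unmeasurable at desk scale. An
`include_clinical=True` option restores the full-covariate variant.

## Occlusion mapping

Cubic blocks (default 8³, stride 4, plus trailing-edge positions) are set
to zero in both image branches at the same location; the model's
performance on a fixed reference set (five progressors + five stable
subjects) is recomputed, and the drop relative to the unoccluded baseline
is added to every voxel the block covers, averaging overlaps.

The choice of the performance functional is load-bearing. Zero-filling a
block of a JD map fabricates extreme atrophy there for *every* subject, a
large off-manifold perturbation that is shared across subjects wherever the
occluded content carries no subject-specific signal. Cross-entropy and
probability metrics register this shared shift as a plateau of spurious
drops; rank-based AUC cancels it but is blind to partial occlusion of a
spatially redundant signal (any un-occluded remnant preserves the
ranking). The default metric is therefore the *class separation of the
logits* — mean progression logit of progressors minus that of
non-progressors — which cancels subject-shared shifts at the score level
while shrinking in proportion to genuine signal attenuation. AUC,
class-weighted cross-entropy and true-class-probability metrics remain
available (the per-subject ones are required for single-class reference
sets). Maps average over folds and subject sets voxelwise.

Occlusion should target a model whose decisions demonstrably depend on the
image — for a clinical + imaging network the clinical pathway can dominate,
leaving image maps noise-bound; the image-only ablation model is the clean
readout. A model trained with a modality ablated must also be evaluated
with those inputs zeroed: its batch-norm statistics for a silenced branch
are degenerate, so feeding real data through that branch at evaluation time
saturates the network.

## Evaluation layer

* AUC by the rank formula (ties one half) — identical to trapezoidal ROC
  integration and verified against exhaustive pair counting.
* MCC with probabilistic scores thresholded at 0.5 (the minimal-assumption
  choice; a validation-Youden option exists) and the zero-marginal → 0
  convention.
* R² = 1 − SS_res/SS_tot on predictions; negative values are meaningful and
  preserved.
* Pairwise model comparison: two-sided Mann-Whitney U over the 50
  fold-level metric values per model; exact enumeration when both samples
  are ≤ 8 without ties, normal approximation with tie correction otherwise;
  significance at p < 0.05. Fold-level values reuse overlapping training
  data, so the test is calibrated only under the fold-design convention it
  mirrors; it is reported as such.
* 95% CIs: percentile bootstrap (default 1000 resamples) over subjects of
  the pooled test sets, using each subject's inner-fold-mean score;
  undefined resamples (single class drawn) are redrawn.

## Problem sizes and numerical choices

Desk-scale defaults — 32³ network inputs (40³ MRIs cropped), 50-epoch
training runs, and smoke-scale experiment configurations (n ≈ 60–160,
2 outer × 3 inner folds, 8³ volumes, 3–10 epochs) — were chosen so the full
suite and the acceptance script run comfortably on a single CPU while every
planted signal remains recoverable; full-resolution settings are
config-only. Other fixed choices: float64 arithmetic throughout the
network; sigmoid computed in the numerically stable split form;
cross-entropy clamped at 10⁻¹²; bootstrap reps ≥ 100 enforced; batch-norm
ε = 10⁻⁵; all tie-breaks deterministic (stable sorts, first-index argmax).

## Known limitations

The CNN is a compact CPU implementation: no GPU kernels, no data
augmentation, no early stopping (epoch count is fixed by design). The
generator's group-conditional independence means multivariate structure
beyond group membership is absent, so model rankings on synthetic data need
not transfer to real cohorts. Occlusion with zero fill takes JD inputs off
their physical manifold (a JD of 0 is an extreme deformation); the
rank-based metric mitigates but does not remove this. The Mann-Whitney
model comparison inherits the fold-dependence caveat above.
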