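# Methods

`gmconnsurv` implements a whole-brain prognostic pipeline for survival
prediction from structural MRI: single-subject gray-matter covariance
networks are summarized into regional graph-theory predictors, fed into
ridge-penalized Cox proportional-hazards models under 10-fold
cross-validation, and compared against clinical and volumetric feature
designs by censoring-aware integrated time-dependent AUC. This note
documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic cohorts do and do not
establish about real data.

## Single-subject gray-matter covariance networks

**Nodes.** A segmented, spatially normalized gray-matter probability map
is tiled into non-overlapping 3×3×3-voxel cubes. A cube becomes a network
node when at least `min_mask_fraction` (default 0.5) of its 27 voxels lie
in the gray-matter mask; out-of-mask voxels contribute value 0. Each node
is assigned to the atlas region holding the majority of its in-mask
voxels, ties broken toward the lower label so the assignment is
deterministic and order-independent.

**Edges.** The similarity of two nodes is the Pearson correlation of
their 27-element intensity vectors. Optionally the correlation can be
maximized over the 48 axis-aligned rotations/reflections of the second
cube (`maximize_over_rotations`), as in similarity-based network
extraction; the default is the plain correlation.

**Threshold.** The binarization threshold is estimated per subject
against a permutation "random network" null: each node's value vector is
independently permuted (destroying inter-node covariance, preserving
marginals; 20 permutations by default) and correlations are recomputed.
The returned threshold is the smallest value t on a 400-point grid for
which

    E[# null correlations > t] / (# observed correlations > t) ≤ α,

a false-discovery-rate bound with default α = 0.05. For data with no real
covariance the observed tail matches the null tail at every t, no
threshold attains the bound, and the estimator raises an advisory error —
this is the correct behavior of a discovery-rate criterion, not a
failure mode.

**Connectivity repair.** The binarized graph must have no isolated node.
Under the default `relax` policy the threshold is lowered in fixed 0.01
decrements until every node has at least one edge, and the relaxed value
is recorded as `threshold_used`; the `error` policy raises instead.

**Local efficiency.** For node i with neighbor set N (k = |N|), local
efficiency is 0 when k < 2 and otherwise the mean of 1/d(j, h) over
ordered neighbor pairs, where d is the shortest-path length within the
subgraph induced by N and 1/∞ = 0. The implementation peels off
distance-d pair counts by iterated boolean reachability (one matrix
product per additional hop), which is algebraically identical to
breadth-first search for every pair; tests verify exact agreement with a
brute-force BFS oracle and with networkx. This matters because
FDR-thresholded cube networks are large (≈1200 nodes, mean degree ≈100
in the synthetic cohorts) and per-node BFS dominates runtime otherwise.

**Predictors.** Nodal efficiencies are averaged (unweighted arithmetic
mean) within each of the atlas regions, giving a fixed-length vector
regardless of each subject's network size. With the standard 90-region
cortical/subcortical parcellation the predictor vector is the 90 regional
efficiencies plus total gray-matter volume (ml), network size (node
count) and mean degree — 93 predictors. Regional gray-matter volumes
(voxel values × voxel volume, summed per region) form the 90-column
volumetric design used as a post-hoc comparator.

## Survival modeling

**Ridge Cox.** The Breslow partial log-likelihood (common risk-set
denominator at tied event times) is maximized with an L2 penalty,
l(β) − (λ/2)‖β‖², by Newton–Raphson with step-halving; the objective is
monotonically non-decreasing across iterations and convergence requires
the penalized-gradient max-norm ≤ 1e-7 (max 100 iterations; a
non-converged fit is returned flagged, never silently). There is no
intercept — it is absorbed into the baseline hazard. Features are
z-scored with statistics from the fitting (training) data only; the
stored transform is applied to held-out subjects. Standardization is the
default because milliliter volumes and ages would otherwise dominate 0/1
clinical codes under a single λ. The default λ = 1.0 on standardized
features is a stability choice for p ≈ 100, n ≈ 300 and is exposed in
configuration; no inner-loop tuning is performed by default.

**Cross-validation.** Subjects are shuffled once per seed and split into
k = 10 folds (sizes differing by at most one). Each fold's model —
including its standardization — is fit strictly on the other nine folds,
and held-out linear risk scores x·β are emitted. Fold partitions are
shared across feature designs so per-fold metrics are paired.

**Per-fold coefficient export.** Wald standard errors from the penalized
observed information give per-fold p-values and unstandardized
coefficients, plus across-fold means. Under a ridge penalty these
p-values are approximate and intended for descriptive ranking of
predictors, not formal inference.

## Evaluation

**Time-dependent AUC.** At horizon t, cases are subjects with an observed
event by t and controls are subjects still at risk after t. Censoring is
handled by inverse-probability-of-censoring weights w = 1/Ĝ(y⁻), with Ĝ
the Kaplan–Meier estimator of the censoring distribution (event
indicators inverted) fit on the fold's *training* subjects, so no
test-label information enters the weights. The evaluation grid is the
test fold's distinct event times, keeping only horizons with at least one
case and one control. Tied risk scores count ½.

**Integrated AUC.** AUC(t) is averaged against the Kaplan–Meier
increments of the event-time distribution: with grid t_1 < … < t_m and
t_0 = 0, the weight of t_k is Ŝ(t_{k−1}) − Ŝ(t_k) from the training-fold
event-time KM, normalized to 1. On a grid that coincides with the KM step
times this is exactly the discrete density Ŝ(t⁻) − Ŝ(t); accumulating
interval mass keeps the weights well-defined when the density is
estimated on an independent sample (test folds of ~30–50 subjects give
degenerate step functions, which is why the training-fold KM is used).

**Model comparison.** Designs are compared by paired t-tests on the k
per-fold iAUC values (paired, because fold partitions are shared), with a
Bonferroni multiplier equal to the number of model pairs. Degenerate
cases are explicit: identical AUC vectors give p = 1; zero-variance
nonzero differences give an infinite statistic and p = 0.

## Synthetic cohorts

Real cohorts of segmented patient MRIs cannot be redistributed, so the
package ships a generator whose outputs exercise every pipeline stage
with known ground truth.

**Atlas.** Contiguous rectangular blocks in a lattice (90 by default) in
a (36, 42, 36) volume with a 3-voxel background margin; each region
contains at least one full cube. Anatomical shape is irrelevant to the
computations under test — only the node→region map matters.

**Gray matter.** Values live on the [0, 1] probability scale of tissue
segmentation with base mean 0.6. Each subject has `latent_dim` = 5
standard-normal factor scores f. Region r receives a mean offset
(L f)_r, where the default loading matrix L assigns each region one
dominant factor (round-robin, random sign, magnitude 0.2), plus iid
voxel noise (SD 0.08).

A mean offset alone is invisible to the network construction: Pearson
correlation centers each cube's 27-vector, so a region-constant shift
cancels exactly. To give the *network* a planted signal, each factor also
owns a fixed zero-mean within-cube texture template, painted tile-aligned
with the cube grid at amplitude 0.07·max(0.1, 1 + 2·(L f)_r) in region r.
Co-loaded regions therefore share a texture and correlate; independent
regions do not; and a subject's regional signal modulates how strongly
their cubes correlate, so network density and local efficiency rise and
fall monotonically with the same factors that drive the hazard. Setting
`texture_amp = 0` recovers the pure offset-plus-noise volume (used in
noise-free-limit tests). Regional mean intensity is unaffected by the
texture (templates are zero-mean), so volumetry sees exactly the offset
model.

**Outcomes.** Event times follow a Weibull proportional-hazards model
with linear predictor f·β, default β = 0.8·(+1, −1, +1, −1, +1), shape
1.2 and scale 180 months (baseline median ≈ 133 months, the order of
magnitude of long-surviving glioma cohorts). Censoring is independent
exponential with its rate calibrated by bisection so the realized
censored fraction hits the 0.30 target. Times are reported in months
throughout.

**Clinical table.** Standard neuro-oncology coding (location 1–4,
laterality, multifocality, grade 2–4, histology 1–3, resection 1–3, age,
sex), drawn *independently of the latent factors* — so in synthetic
cohorts the clinical designs are uninformative by construction and serve
as the pure-noise comparator.

**What the generator does not emulate.** No tumors or lesions, no
scanner artifacts, no registration error, no anatomical covariance
topology, no dependence of clinical covariates on outcome, and no
radiomic feature distributions (radiomic designs are accepted only as
precomputed tables). Passing tests therefore demonstrate that the
machinery recovers a planted network→hazard signal and behaves correctly
at its contracts — not that real gliomas are predictable at any
particular accuracy.

## Problem sizes and determinism

The shipped tests run cohorts of 120 subjects with a 12-region atlas for
unit-level checks, and 300–500 subjects with the full 90-region atlas for
end-to-end discrimination; the acceptance script uses a 305-subject
cohort. These sizes keep a full run in the minutes range on a single
CPU while leaving the discrimination signal far above fold noise. Every
stochastic component (atlas, volumes, outcomes, fold splits, permutation
nulls) draws from a generator seeded by the run seed, and two runs with
identical configuration produce byte-identical output CSVs.

Known numerical edge cases: constant-valued cubes have undefined
correlation and are dropped (or raise, per configuration); thresholds
relax only down to 0 before raising; a Cox fit with all subjects
censored raises; cohort-level chance correlations put a single null
cohort's mean iAUC within roughly ±0.1 of 0.5 at n = 300, which is why
chance-level checks average independent cohorts.
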