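# gmconnsurv

Whole-brain prognostic modeling from structural MRI: build each
subject's **gray-matter covariance connectome** from a segmented
T1-weighted gray-matter map, summarize it into regional graph-theory
predictors, and evaluate how well those predictors forecast overall
survival against clinical and volumetric baselines.

The package is aimed at neuro-oncology imaging researchers who have
per-subject segmented, spatially normalized gray-matter probability
volumes (e.g. from a VBM pipeline), an atlas parcellation, and a
survival table — and who want a reproducible, leakage-free harness for
comparing prognostic feature sets. Because patient MRI cohorts usually
cannot be shared, the package also ships a synthetic-cohort generator
with planted covariance and a known proportional-hazards outcome, so the
entire pipeline is testable at desk scale.

## What it computes

**Connectome features.** The gray-matter volume is tiled into 3×3×3-voxel
cube nodes; edges are Pearson correlations of cube intensity vectors
exceeding a per-subject permutation-FDR threshold (connectivity repaired
so no node is isolated). For each node the local efficiency

E_loc(i) = (1 / k_i(k_i−1)) · Σ_{j≠h ∈ N_i} 1 / d_{jh}

is computed, with d the shortest-path length inside the subgraph induced
by the neighbors N_i. Nodal values are averaged within each of the 90
atlas regions and concatenated with total gray-matter volume, network
size and mean degree: **93 predictors** per subject. Regional gray-matter
volumes (90 columns) form a volumetric comparator design; clinical
designs use 5 presurgical or all 8 coded covariates.

**Survival model.** A Cox proportional-hazards model with ridge penalty,
maximizing the Breslow partial log-likelihood l(β) − (λ/2)‖β‖² by
Newton–Raphson with step-halving, fit under 10-fold cross-validation
with fold-local standardization (no test-subject leakage anywhere).

**Evaluation.** Held-out risk scores are scored by the cumulative/dynamic
time-dependent AUC with inverse-probability-of-censoring weights
1/Ĝ(y⁻), integrated over the event-time distribution's Kaplan–Meier
density into a single iAUC per fold; designs are compared with paired
t-tests and Bonferroni correction.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from gmconnsurv.pipeline import RunConfig, run_analysis

config = RunConfig(
    mode="synthetic",
    designs=("clinical", "connectome", "gm_volumes"),
    seed=11,
    cohort={"n_subjects": 120},
)
result = run_analysis(config, write=False)
print(result.fold_auc.mean(axis=1).round(3))
print(round(result.km_median_months, 1))
```

Output:

```
model
clinical      0.607
connectome    0.751
gm_volumes    0.876
dtype: float64
105.0
```

The synthetic cohort plants a latent-factor signal in both the
gray-matter covariance structure and the hazard, while the clinical
table is generated independently of the outcome. Accordingly the
connectome and regional-volume designs discriminate survival well above
chance (mean cross-validated iAUC 0.75 and 0.88 over 10 folds), the
clinical design hovers near chance, and the cohort's Kaplan–Meier median
survival is 105.0 months. `result.comparisons` holds the paired,
Bonferroni-corrected tests between the designs, and
`result.coefficient_tables` the per-fold coefficients and approximate
Wald p-values.

The same run is available from the shell:

```bash
gmconnsurv run --config config.yaml   # mode, designs, cohort, seed, output_dir
gmconnsurv simulate --n-subjects 50 --out cohort/   # write NIfTI + CSV cohort
gmconnsurv features --manifest cohort/manifest.csv --atlas cohort/atlas.nii \
    --clinical cohort/clinical.csv --survival cohort/survival.csv --out feats/
```

Real data enter through `mode: real` with a manifest CSV linking subject
ids to NIfTI gray-matter maps, an atlas volume, and clinical/survival
CSVs; precomputed feature tables (e.g. radiomics) can be attached as
additional designs via `external_tables`.

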