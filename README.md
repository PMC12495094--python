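# fcprog

Cross-validated prognostic modelling of longitudinal clinical outcomes from
functional-coupling (FC) matrices, with honest permutation inference — plus a
seeded synthetic-cohort generator that makes the entire pipeline testable
end to end without patient data.

## Who this is for

Researchers asking whether resting-state FC measured at the start of
treatment (or its early change) predicts how a patient's symptoms and
functioning evolve over the following months, and who want the full
methodological apparatus — repeated-split cross-validation, permutation
nulls, familywise-error control — rather than a single optimistic fit.
Everything operates on parcellated time series or precomputed FC matrices
as plain delimited text; volumetric image processing is out of scope.

## The methods

Each subject-visit is summarised as a symmetric region-by-region matrix of
Pearson correlations between regional activity time series; models consume
its strict upper triangle `x` (87,571 edges at 419 regions). A coupling
change matrix is the follow-up minus the baseline matrix. Clinical change is
the proportional score `(y2 − y1) / y1` of a bounded scale (0–100
functioning, 24-item symptoms), with slope and positive-symptom-subscale
variants.

Three predictors are implemented:

- **CPM** (connectome-based predictive modelling): inside each training set,
  keep edges whose correlation with the outcome has the required sign and a
  two-sided p < α (exact t transform, `t = r·√((n−2)/(1−r²))`); sum the kept
  edges into one summary score; fit a one-variable least-squares line.
- **KRR** (kernel ridge regression): predict each test outcome as a
  regularized weighted mean of training outcomes, with weights from the
  between-subject Pearson-similarity kernel; the ℓ₂ strength λ is tuned by
  an inner 4-fold cross-validation loop over a log-spaced grid.
- **Meta-matching** (proxy-feature stacking): a bank of models trained on
  large synthetic source cohorts maps each subject's FC vector to proxy
  phenotypes (two families per phenotype — linear ridge and ridge on a fixed
  random nonlinear expansion; extra phenotypes stack on base-proxy rows);
  a final KRR on the proxy rows predicts the clinical target. At the
  canonical 67 base + 162 extra phenotypes this yields 458 proxies.

Every model cell of the factorial grid (algorithm × outcome measure ×
timepoint × predictor × feature sign; 16 CPM + 8 KRR + 4 meta-matching
models) is scored by `r_mean`: the mean over 100 random splits of 4-fold
cross-validation of the Pearson correlation between pooled out-of-fold
predictions and observed outcomes. Significance comes from re-running the
whole pipeline on outcome shuffles (1000 permutations; 100/50/20 splits per
permutation for CPM/KRR/meta-matching), and familywise error across the
models sharing an algorithm is controlled by the Westfall–Young max-statistic
method: `p_FWE` compares each observed `r_mean` against the per-permutation
maximum across the grid.

The synthetic generator plants a sparse edge effect with a calibrated effect
size: the noiseless predictor is `w·x` over `n_causal_edges` edges and the
targets satisfy `corr²(target, w·x) ≈ effect_r2`, so recovery is decidable.

## Worked example

```python
import fcprog
from fcprog.evaluation import SplitScheme

config = fcprog.CohortConfig(
    n_subjects=48, n_regions=20, n_timepoints=60,
    effect_r2=0.5, n_causal_edges=5, attrition_fraction=0.25, seed=7,
)
cohort = fcprog.generate_cohort(config)
study = fcprog.PredictionStudy.from_cohort(cohort)
results = study.fit(
    algorithms=("cpm", "krr"),
    scheme=SplitScheme(n_splits=20, base_seed=0),
    n_perm=99, perm_splits={"cpm": 20, "krr": 10}, perm_seed=1234,
)
print(results.summary())
```

prints (abridged):

```
Prognostic model evaluation (20 splits of 4-fold CV, 99 permutations)
==============================================================================
algorithm     measure  timepoint   predictor     sign  n r_mean     p p_fwe
      cpm functioning          6 baseline_fc positive 48  0.384 0.000 0.071
      cpm functioning         12 baseline_fc positive 48  0.442 0.000 0.030
      cpm    symptoms          6 baseline_fc negative 48  0.553 0.000 0.000
      cpm    symptoms          6    delta_fc positive 36 -0.221 0.869 1.000
      krr    symptoms          6 baseline_fc      n/a 48  0.399 0.000 0.020
      krr    symptoms         12 baseline_fc      n/a 48  0.465 0.000 0.000
      ...
```

Reading it: half the variance of this cohort's outcome change is planted on
five baseline-FC edges, so baseline-FC cells detect it (`r_mean` ≈ 0.4–0.55,
surviving familywise correction), the symptom cells through negative edge
weights (symptoms improve when the latent signal is high), while the
delta-FC cells — where nothing was planted — hover around zero with
`p_FWE` ≈ 1. `n` drops from 48 to 36 in delta-FC cells because subjects
without a follow-up scan never enter those models; nothing is imputed.

A command-line interface mirrors the library
(`fcprog simulate / evaluate / permtest / report`):

```bash
fcprog simulate --n-subjects 48 --n-regions 20 --n-timepoints 60 \
    --effect-r2 0.5 --seed 7 --out cohort/
fcprog permtest --cohort cohort/ --algorithms cpm,krr \
    --n-splits 20 --n-perm 99 --seed 0 --out results/
```

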