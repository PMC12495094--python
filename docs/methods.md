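# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the tests demonstrate.

## Outcome targets

Clinical scales are bounded: functioning on 0–100, symptoms as a 24-item
inventory with 7-point items (total 24–168; higher is worse). The primary
target is the proportional change `(y2 − y1)/y1` between baseline and a
6- or 12-month visit; it is scale-invariant and undefined at `y1 = 0`
(such subjects are dropped, as is any subject missing a required visit —
no imputation anywhere). Exploratory targets: the least-squares slope of
score on time over all available visits (two points suffice), and the
proportional change of the 4-item positive-symptom sum (unusual thought
content, conceptual disorganization, hallucinatory behavior, grandiosity).
Whether a positive-symptom analysis should use raw or proportional change
is genuinely open; proportional change was chosen for consistency with the
primary target.

## Predictors

**FC features.** Entry (i, j) of a subject's FC matrix is the Pearson
correlation of regional time series i and j; the feature vector is the
row-major strict upper triangle, one fixed order everywhere. Coupling
change (ΔFC) is follow-up minus baseline; only subjects with both scans
enter ΔFC models. Raw correlations are used by default — a Fisher-z flag
exists (`use_fisher_z`) but is off, preferring the plainest feature
definition; no per-edge standardization is applied, for the same reason.
A region with zero temporal variance is a hard error naming the region: it
signals a degenerate scan that should have been excluded upstream.

**CPM.** Selection keeps edge e iff `corr(x_e, y)` has the requested sign
*and* its two-sided p-value is below α (default .05; .001 exposed for the
stricter variant). The two conditions are deliberately separate — a
two-sided p with a sign gate, not a one-sided test; the distinction only
matters at α near 1, but it makes the positive and negative selections
provably disjoint. Internally the p-threshold is converted once to an
equivalent |r| threshold (the t transform is monotone), which the tests
verify against a per-edge `pearsonr` loop. Empty selection or constant
summary scores degrade to predicting the training mean, keeping every
split defined. CPM contains no randomness.

**KRR.** Correlation kernel between subjects' feature vectors; dual
weights solve `(K + λI)α = y − ȳ` with the mean re-added at prediction
(the kernel has no intercept). λ is chosen from `{0} ∪ 16 points
log-spaced on [1e−3, 1e4]` by inner 4-fold CV maximizing the mean
inner-fold Pearson correlation — the same metric as the outer evaluation;
ties break to the smallest λ for determinism. A λ whose regularized kernel
is numerically singular on an inner fold (minimum eigenvalue + λ below
1e−10) is skipped with a warning rather than aborting; if the finally
chosen λ is singular on a training fold the fold falls back to the
training mean. All solves go through one eigendecomposition of the
training kernel, so evaluating the whole grid — and whole batches of
permuted targets — costs a few matrix products; the tests pin this route
against a plain dense solve at 1e−8.

**Meta-matching.** The bank has two layers (base models on raw FC, extra
models stacked on base-proxy rows) and two families per phenotype: linear
ridge, and ridge on a fixed seeded random tanh expansion. The expansion is
a deliberately simple deterministic stand-in for the deep-network family
of published pretrained stacks; it preserves the two-family, two-layer
architecture and the proxy-dimension law `n_families · (n_base + n_extra)`
(458 at the canonical 67 + 162 configuration) while remaining trainable in
seconds. Zero-variance phenotypes are excluded with a warning and the
dimension adjusted. The final predictor is the same KRR applied to proxy
rows, baseline FC only — no pretrained model exists for longitudinal FC
change. Proxy columns constant on the training subjects are dropped before
the kernel (a constant row breaks a correlation kernel).

## Evaluation and inference

One split = one random partition into 4 folds (sizes differ by ≤ 1, no
stratification); each fold is predicted from the other three, and one
Pearson r is computed between the pooled out-of-fold predictions and the
observed targets. Pooling (rather than averaging per-fold r's) uses every
subject exactly once per split and is the convention adopted here.
`r_mean` averages over `n_splits` splits (100 in the main configuration).
Constant pooled predictions score 0 with a warning.

Permutation inference shuffles the targets among subjects with a fixed
seed and re-runs the entire pipeline — selection and λ tuning included —
per permutation, with per-algorithm split budgets (100 CPM / 50 KRR / 20
meta-matching) reflecting their relative costs. The p-value is the
proportion of null `r_mean` values ≥ the observed one: ties count against
the observed value; the `(k+1)/(n+1)` estimator is available via
`plus_one=True`. Westfall–Young familywise correction takes, at each
permutation, the maximum null `r_mean` across all models sharing an
algorithm; each model's `p_FWE` is the proportion of those maxima ≥ its
observed `r_mean`, so `p_FWE ≥ p` holds by construction. Bonferroni is
deliberately not offered as a default alternative.

Two implementation choices matter for reproducibility and cost:

- *Seeding.* Split s draws its fold allocation from
  `default_rng([base_seed, s])` and its inner-CV allocations from
  `default_rng([base_seed, s, 1])`; permutation indices come from an
  independent stream seeded by `perm_seed`. The permutation stream must be
  independent of the stream that generated the data — seeding both from
  the same integer makes the shuffles a deterministic function of the
  data and measurably distorts the null (this was observed and fixed
  during development; the validation experiments now offset the
  permutation seed).
- *Batching.* At a given split, all permuted target columns share that
  split's fold allocation, so a permutation run is a handful of matrix
  products (CPM selection thresholds and line fits, and the KRR
  eigendecomposition, vectorize across target columns). Shuffled targets
  are exchangeable conditional on the allocation, so the permutation
  p-value remains exact; a 1000-cohort simulation in the acceptance
  machinery confirms the familywise error rate sits at the nominal 5%.
  The cost is that allocations are shared across permutations within a
  split rather than redrawn per (permutation, split) pair.

## Synthetic cohorts

The generator emulates the data structure of a small longitudinal
first-episode-psychosis trial: ~49 analysable subjects, baseline scans for
everyone, a 3-month follow-up missing completely at random for ~27%
(yielding the 35–37-subject ΔFC subsamples typical of such cohorts), 1:1
randomization to a placebo-labelled arm, and both scales at months 0, 6
and 12.

**Time series.** Each scan is drawn from a subject-specific low-rank
factor model: regional loadings = shared network backbone + subject
deviation + white observation noise. Subject deviations are structured as
a few shared *variation modes* with subject-specific coefficients plus a
weak idiosyncratic term (defaults: 3 modes, strength 0.5, idiosyncratic sd
0.1). The mode structure mirrors the well-replicated finding that
individual differences in FC concentrate along a few major axes; it is
also load-bearing for the validation: with isotropic high-dimensional
subject noise the similarity kernel has a nearly flat spectrum and no
kernel method can detect any noisy target at n ≈ 48. Follow-up scans add
a per-subject loading drift (sd 0.2), so ΔFC has realistic
between-subject variance without a planted effect.

**Planted effect.** `n_causal_edges` edges (default 5) get unit positive
weight `w`; the latent signal is `w·x` over realized baseline FC vectors.
Standardized targets mix the latent and Gaussian noise as
`√(effect_r2)·s + √(1−effect_r2)·ε`, so the squared correlation between
target and noiseless predictor is calibrated to `effect_r2` (verified by
Monte Carlo). Functioning loads positively on the latent and symptoms
negatively; the noise pair is correlated −0.3 across scales (symptom and
functioning change are related but distinct). Proportional-change means
anchor at +20%/+22% (functioning, 6/12 months) and −25%/−23% (symptoms),
with sds 0.25 and 0.15.

**Scores.** Baselines anchor at scale midpoints (50 and 96) and follow-ups
are derived as `y1·(1 + target)`, so the proportional-change formula
reproduces the planted target exactly; targets are clipped to keep scores
inside scale bounds (±0.98 functioning, ±0.74 symptoms — a > 3 sd event,
logged when it occurs). Item-level symptom scores are a seeded Dirichlet
allocation of the total onto 24 items water-filled into [1, 7]; they are
continuous, sum exactly to the total, and exist so the positive-symptom
pathway is exercised — no item-level effect is planted.

**Source cohorts for transfer.** Large source cohorts (default 2000
subjects, 5 base + 10 extra phenotypes) share a population structure with
the target cohort via a separate structure seed, but use many variation
modes (15, strength 0.25) and dense Gaussian phenotype readouts: such
readouts are estimable from thousands of subjects yet not from ~40, which
is precisely the regime where proxy stacking helps. With three dominant
modes a 40-subject kernel model learns any mode-aligned construct
directly and transfer shows no advantage — a useful reminder that
meta-matching buys nothing when the in-sample problem is easy or when the
target is unrelated to every source phenotype.

**What the generator does not emulate.** Scanner artifacts, head motion,
hemodynamics, site effects, non-Gaussian outcome distributions, informative
(non-random) attrition, and any coupling between ΔFC and outcomes. Passing
tests therefore demonstrate the statistical machinery — calibration, error
control, recovery under the stated generative family — not that real FC
cohorts carry recoverable prognostic signal.

## Desk-scale validation conditions

The acceptance experiments run at 20 regions (190 edges), 60 time points,
48 subjects, 5 causal edges, 99 permutations × 10 splits; null calibration
uses 200 cohorts, signal recovery 50, transfer 50 seeds at target n = 40.
These sizes were fixed once from an a-priori power analysis of the
generative family and keep the full run within minutes on one CPU. At
these conditions: permutation p uniform (KS), type-I ≈ 5%, familywise rate
≈ 5%, CPM/KRR mean `r_mean` ≈ 0.45/0.39 at `effect_r2 = 0.5` with ≥ 90%
rejection, ~60% causal-edge recovery, and a transfer gain of ≈ +0.3 for
correlated targets vs ≈ −0.2 for independent ones — numbers recomputed,
not asserted, by `scripts/acceptance.py` and `tests/test_acceptance.py`.

## Known limitations

- The nonlinear proxy family is a random-feature ridge, not a trained deep
  network; absolute proxy accuracies are not comparable to published
  pretrained stacks, only the architecture and dimension law are.
- The λ grid is this package's choice; the referenced KRR implementations
  defer their grids to supplements and may differ.
- Permutation nulls share fold allocations across permutations within a
  split (see above); the p-value is exact but the null `r_mean` variance
  decomposition differs slightly from a fully re-drawn design.
- Bounded-scale clipping very slightly attenuates the planted effect for
  extreme draws (< 0.5% of subjects at default settings).
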