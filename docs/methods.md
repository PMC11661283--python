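# Methods

## Survival model

All per-modality models are Cox proportional-hazards risk models: the hazard
of patient i is a shared baseline hazard times `exp(r_i)`, and each model
outputs the log-partial hazard `r_i` directly. Because every modality's model
is trained on the same cohort, the baseline hazards coincide and raw risk
scores are summed across modalities at fusion time without per-modality
standardization (a `standardize=True` switch exists on `fuse` for
scale-sensitive settings but is off by default; the weighted sum of raw
log-partial hazards is the declared contract). Follow-up is in months;
events are death (OS) or recurrence/progression (DFS); right censoring only —
no interval censoring, competing risks, or date arithmetic.

## Tabular preprocessing

Fit on the training fold only, replayed verbatim elsewhere; all fitted state
is a JSON-serializable spec. Choices where the procedure is underdetermined:

- Missingness filter drops a feature only when its missing fraction is
  *strictly* above `max_missing_frac` (default 0.20).
- z-scoring uses the sample standard deviation (ddof=1, configurable);
  zero-variance training columns are dropped.
- One-hot coding uses k−1 indicators with the modal training level as
  reference, avoiding exact collinearity in Cox fits; unseen test levels map
  to all-zero indicator rows.
- Spearman deduplication runs greedily in the table's column order (a column
  is dropped iff |ρ| with an already-kept column exceeds 0.8, absolute by
  default since anticorrelated duplicates are equally redundant) and is
  applied after one-hot coding so the matrix is fully numeric.

## Cox fitting

Screening and forward selection need thousands of small fits, so the package
carries a vectorized Newton–Raphson solver for the Efron-corrected partial
likelihood (reverse cumulative sums + segment sums, backtracking line
search). A mild L2 penalty (default 1e-6) stabilizes near-collinear omics
features; fits that fail to converge — including zero-variance covariates —
are treated as uninformative (scored C-index 0.5) rather than aborting a
scan. The solver is cross-checked against lifelines' `CoxPHFitter` in the
test suite on data with and without tied event times.

Forward selection uses 10 random 80/20 sub-partitions of the training fold;
"validation performance" is the arithmetic mean of sub-validation C-indexes.
Candidates are accepted only on strict improvement; ties between candidates
break toward the higher screening rank, making the whole procedure
deterministic under its seed. The final model is refit on the full training
fold, and the best mean validation C-index becomes the modality's fusion
weight input `p_m`.

## Deep MIL risk model

Patch embeddings are projected to `proj_dim` (default 256), passed through
ReLU and dropout (0.25), mixed by multi-head self-attention with a residual
connection, mean-pooled, and mapped to a scalar risk. Attention uses the
Nyström approximation when the bag has at least `n_landmarks` patches
(landmarks are contiguous-segment means; the m×m landmark kernel is inverted
with a Newton–Schulz-type iteration); smaller bags fall back to exact
attention. Defaults: 8 heads, `n_landmarks = 256`, `pinv_iterations = 18` —
the iteration count is chosen so the approximation error at landmarks =
tokens stays far below 1e-3 even for poorly conditioned landmark kernels
(at 6 iterations a kernel with condition number ~4e4 still shows errors of
order 1e-2). The scalar normalization in the pseudo-inverse initialization
is locally constant in the parameters and is treated as such during
backpropagation.

A partial-likelihood loss is undefined for a single patient, so training
scores bags one at a time (subsampling 4096 patches without replacement from
larger bags) and accumulates risks over `accumulation_size` patients
(default 32) before each loss evaluation and Adam update; event-free
accumulation batches are skipped. An event-stratified 20% validation split
of the training fold drives a reduce-on-plateau schedule (lr ×0.1 after 5
epochs without validation-loss improvement, from lr = 1e-3); the final
model's validation C-index is the deep modality's `p_m`. Gradients come from
a minimal reverse-mode autodiff engine inside the package
(`mmsurv.autodiff`), verified against central finite differences; training
is bit-reproducible on CPU under its seed.

## Slide preprocessing

Segmentation: downsample (default 1/32), RGB→HSV, threshold the saturation
channel (Otsu by default; uniform-saturation images fall back to a fixed
0.05 cut so blank backgrounds stay empty), median blur (kernel 7) and
morphological closing (kernel 9) at mask scale. Patching keeps grid-aligned,
non-overlapping 512×512 level-0 tiles with tissue coverage ≥ 0.5. Encoders
are pluggable callables (224×224×3 → d); the bundled `ToyStatEncoder`
(per-channel mean/sd/8-bin histogram through a fixed seeded projection) is
deterministic and colour/texture-sensitive but carries no histology
semantics — it exists so the pipeline is testable without pretrained
weights, which are deliberately out of scope.

## Evaluation

Harrell's C with risk ties scored 0.5 and tied event times not comparable;
percentile bootstrap (B = 1000) over patients for the CI, with
no-comparable-pair replicates redrawn; Welch's unpaired t-test compares two
models' replicate distributions. Median-risk stratification sends ties at
the median to the low-risk group. Horizon labels at 12/36/60 months:
positive if the event occurred by the horizon, excluded if censored before
it, negative otherwise. AUROC uses midranks; its variance, CI and the paired
two-model test follow DeLong's structural-components method. Test-fold
predictions from the 5 folds are pooled into one vector per model before any
metric is computed. All p-values are two-sided.

## Synthetic cohorts

The generator emulates the *structure* of a multimodal renal-carcinoma
cohort, not omics biology: standard-normal features with an equicorrelated
nuisance block (ρ = 0.3) and independent informative columns; event times by
inverse sampling from an exponential-baseline proportional-hazards model
(Weibull optional); independent exponential censoring whose rate is
calibrated by bisection — jointly with an administrative follow-up horizon
(default 150 months) — to hit a target censoring fraction; a DFS endpoint
coupled to OS by a Beta(2,1) time-contraction for event patients (so
recurrence precedes death) plus a 25% chance of recurrence before censoring
otherwise; and embedding bags that mix background and signature Gaussian
clusters with signature fraction `sigmoid(2·risk)`. Defaults mirror the
target cohort scale: 226 patients with heavily censored OS (~83%) and more
frequent DFS events.

Passing tests on these cohorts demonstrates recovery of planted
proportional-hazards signal under censoring, not robustness to real-world
messiness (batch effects, non-proportional hazards, informative censoring,
stain variation); those are explicitly untested.

## Problem sizes in the test suite and acceptance run

Fixtures are sized for a single CPU: coefficient recovery uses n = 1000 over
10 seeds; forward-selection recovery 50 features at n = 500 over 10 seeds;
deep-model training 200 patients × 50–200 patches at d = 32 for 30 epochs
(projection width 64 in tests — the mechanism is identical at 256, only
slower); the end-to-end acceptance run uses 240 patients with a 48-wide
projection and 30 epochs. In the bag-recovery fixture the planted bag effect
is set to 2 standard deviations so that the ground-truth risk itself reaches
a concordance of ~0.84 — leaving measurable headroom for the recovery bound
being tested.

## Known limitations

- Fusion assumes comparable risk scales across models; a deep model with a
  drifting output scale can dominate or vanish in the raw weighted sum.
- The univariate screen and forward selection inherit the instability of
  validation-based selection at high dimension; selected omics feature sets
  vary across folds by design.
- The deep model has no positional information and treats bags as sets;
  spatial patch context is not modelled.
- `n_landmarks` defaults to 256 while typical test bags are smaller, so the
  exact-attention path is the one usually exercised end-to-end; the Nyström
  path is validated directly against an exact-attention oracle.
- No learned (stacked) fusion; weighting is a fixed function of validation
  performance.
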