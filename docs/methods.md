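# Methods

`metgp` implements a three-stage analysis of multi-environment testcross
trials (METs) feeding into genomic prediction, together with a synthetic
MET generator that supplies ground truth for every stage. This note
records the models, the numerical choices, and what the synthetic data do
and do not establish.

## Stage one: spatial analysis per location-year

Plot yields of one location-year are modelled as

    Y_hijkv = (GT)_hv + S_i + R_ij + B_ijk [+ W_ijo + V_ijq] + e_hijkv

with fixed genotype-by-tester cell means `(GT)_hv` and random trials `S`,
replicates in trials `R`, blocks in replicates `B`, and optionally rows
`W` and columns `V` in replicates. A *physical* trial is the combination
of a genotype subset and a tester: where a location evaluates the same
subset under both testers, those are two separate field trials with their
own replicates, blocks and coordinates. Nine candidate models share the
fixed part and differ in the random terms and the plot-error covariance:

| id | rows/columns | error structure |
|----|--------------|-----------------|
| M1 | –  | independent |
| M2 | yes | independent |
| M3 | –  | AR(1) within block |
| M4 | –  | linear variance within block + nugget |
| M5 | –  | AR(1)×AR(1) within replicate |
| M6 | yes | AR(1)×AR(1) within replicate |
| M7 | –  | M3 + nugget |
| M8 | –  | M5 + nugget |
| M9 | yes | M6 + nugget |

Distances are integer plot-index differences (unit spacing, no physical
plot dimensions). The AR(1) correlation is ρ^d; the two-dimensional form
is the separable product ρ_row^dr · ρ_col^dc, assembled over the observed
plots only, so non-rectangular layouts come out right by construction.
The linear-variance (LV) covariance is σ²_lv (1 − d/d_max) within a
block, with d_max the block extent, plus a mandatory nugget; the exact LV
parameterization used by other software is not standardized, so this
normalized-decay form is fixed here deliberately. A two-dimensional
LV×LV model is out of scope. One error structure is shared by all trials
of a location-year.

Fitting is by REML: the restricted log-likelihood
−½[log|V| + log|XᵀV⁻¹X| + yᵀPy] is maximized over transformed parameters
(log variances, atanh correlations bounded at |ρ| ≤ 0.999) with
multistart L-BFGS-B (default three deterministic starts, relative
tolerance 1e−8) and a bounded Nelder–Mead polish when a line search
stalls near a correlation boundary — spatial likelihoods are prone to
that, and robustness has to be engineered rather than assumed.
Non-convergence and an indefinite Hessian are reported as flags on the
fit, never as silent failures or exceptions; flagged models are ineligible
to be "best" in model selection. Boundary parameters (a variance pinned
at effectively zero) are excluded from the Hessian check, since a
one-sided optimum has no interior curvature.

Models are compared by AIC = −2·logREML + 2q with q the number of
variance parameters only; the fixed part is identical across M1–M9, which
is the condition for comparing REML fits by information criteria at all.

Adjusted means are the BLUEs of the genotype-by-tester cells,
(XᵀV̂⁻¹X)⁻XᵀV̂⁻¹y, with their full covariance matrix. Cell-means coding
makes every observed cell estimable; genotypes evaluated under different
testers are linked through locations that grow both testers.

## Stage two: integration across locations, testers, years

Stage-one means enter a weighted mixed model whose residual variance is
*fixed*, not estimated: `var(e_hsv) = 1/w_hsv` with Smith weights
`w = diag(vcov⁻¹)` from stage one. Fixing the scale (no free residual
multiplier) is what identifies the three-way interaction component, which
is otherwise confounded with the residual. Singular covariance matrices
fall back to the Moore–Penrose pseudo-inverse with a warning.

Year-wise model (Approach 1): genotype and tester fixed; location and
every interaction containing it random; genotype-by-tester random so that
means are estimable across testers. Genotype BLUEs are averaged over
tester levels. The weights this stage forwards to prediction are again
Smith weights from the BLUE covariance — not inverse squared SEs — because
the shared part of the uncertainty (e.g. the location main effect common
to every mean) cancels between genotypes and must not inflate the fixed
error variances of the prediction model.

Year adjustment:

* **1a** — year enters the prediction stage as a fixed effect.
* **1b** — the simple (unweighted) mean of all genotype means of a year
  is subtracted; corrected means average exactly zero within each year.
  Rationale: with hundreds of entries per year, the sample mean estimates
  the year effect better than one check can.
* **2** — one across-years model with fixed year-by-tester cells (the
  year main effect is absorbed by them and is dropped), all interactions
  containing year or location random, and residual variances fixed at the
  squared stage-one SEs. Years must share at least one check; a
  disconnected year set is a hard error. Only SEs, not a full covariance
  matrix, are forwarded from this route — mirroring the method's own
  practice for the across-years model — which is a known weakness: shared
  uncertainty components inflate the fixed error variances of the
  prediction stage under Approach 2.

Heritability per year uses the ad hoc form h² = σ²_g/(σ²_g + v̄_Δ/2),
where v̄_Δ is the mean variance of a difference of two genotype BLUEs
taken over all pairs, and σ²_g comes from a genotype-random refit of the
year-wise model (a genotype-fixed fit has no genetic variance component,
so a refit is the only way to obtain one). √h² is a rough upper bound
for predictive ability. Repeatability per location is
R = σ²_GT/(σ²_GT + σ²_R + σ²_B + σ²_e) from a baseline refit with the
genotype-by-tester term random; the trial variance is excluded from the
denominator because trials differ in genotype sets, not in repeated
measurements of the same group.

## Stage three: genomic prediction

RR-BLUP: y = Xβ + Zu + e with u ~ N(0, σ²_u I_p) over the raw {−1,0,1}
marker codes (no centering or scaling — the intercept absorbs the mean),
and e ~ N(0, R) with R diagonal and fixed from the stage-two weights.
Estimation uses the equivalent kernel form var(y) = σ² Γ + R with
Γ = ZZᵀ/p (the rescaling Z* = Z/√p leaves Zu invariant after rescaling
σ²_u), which reduces REML to a single variance parameter optimized on the
whitened eigenbasis of Γ. Marker effects are back-solved as
û = σ̂² ZᵀV⁻¹(y − Xβ̂)/p, so the marker-space and kernel-space GEBVs are
identical by construction (verified to 1e−8 in the tests, not assumed).
GEBVs for new genotypes are Z_new û in the same code space as training.

Cross-validation: k-fold, t repetitions (default 5×5). WC sampling
partitions genotypes uniformly; AC sampling assigns whole crosses to
folds by a seeded randomized greedy rule (shuffled crosses go to the
currently smallest fold), so no full-sib family is ever split. Fold plans
are deterministic in the master seed and identical across the model
datasets being compared. Predictive ability is the Pearson correlation
between predicted GEBVs and observations, computed once per repetition
over the concatenated validation folds (the pooling level is not
prescribed anywhere authoritative; per-repetition pooling uses every
validation case exactly once), and is deliberately *not* divided by √h².
Under Approach 1a the observations are corrected by the training-fit year
effects before correlating, so the markers are not credited for
predicting the year. Bias is the OLS slope of observed on predicted
(1 = unbiased); a slope above 1 means over-shrunk predictions, and with
very small training sets, where σ̂²_u can hit the boundary, the slope is
unstable — it is reported per repetition rather than summarized away.

Variance decompositions: (i) genotype/cross — second-stage means are
modelled as genotype + cross + error, all random; with a single record
per genotype the genotype and error variances are confounded (their sum
and the cross variance remain identified) and the result carries a flag.
The cross share is σ²_C over the three-component total. (ii) polygenic —
the kernel model is extended by a second genotype-level random effect
with a supplied covariance (identity by default; a pedigree or kinship
matrix can be passed instead — the right choice is genuinely open and
therefore exposed), and the marker-captured share is
σ²_marker/(σ²_marker + σ²_polygenic).

## Model selection

Per location-year, models are ranked by ΔAIC (argmin) or by ρ-GP-CV
(argmax) computed with a common fold seed across models. Exact ties count
for every tied model in the best-fit tally; where a single winner is
needed (the Mix datasets), ties break toward the simpler model. Rows
where every ability is negative are excluded from counting — a more
negative correlation is not a better model, both mean "no prediction" —
but such locations fall back to the baseline model's means in the Mix
datasets. Mix1 assembles, per location, the means of the best-AIC model;
Mix2 those of the best-ρ model, each with a provenance map.

Final abilities are compared by all-pairs paired t-tests with the CV
repetition as the block, α = 5%, no multiplicity correction (by design),
summarized by an insert-absorb compact letter display. Degenerate paired
differences (zero variance) are declared significant iff the constant
difference is non-zero.

The published summary tables of the motivating study ship as CSV
resources, including the printed best-model markers and the
non-convergence/non-PD annotations. Counting from the printed values
alone reproduces the published AIC counts; the ability table ties at its
printed three-decimal precision, so the recorded markers (which carry the
source's fourth-decimal ordering) take precedence when present.

## The synthetic generator

The generator emulates the structure of a hybrid rye testcross program:
full-sib families from pairs of parents drawn at Hardy–Weinberg
proportions (population MAF uniform on a configurable range), offspring
sampled per locus; unlinked loci — no LD, which is the main respect in
which the panel is idealized. Marker effects are iid normal, scaled so
that var(GEBV)/(var(GEBV) + plot error variance) equals a target
plot-level heritability. Trials are α-designs with two replicates,
blocks nested in replicates and laid out two blocks per field row (so
rows span blocks and row effects are separable from block effects);
checks are grown in every trial (twice per trial, once per replicate) and
a configurable number of checks is shared between consecutive years —
exactly one by default, reproducing the weak-connectivity setting that
motivates the three year-adjustment approaches. One bridge location per
year grows all trials under both testers, which is what makes tester
effects estimable. Plot errors are a draw from
v_spatial·AR1(ρ_row)⊗AR1(ρ_col) + v_nugget·I per replicate grid.
Non-rectangular layouts arise by deleting a fraction of border plots, and
uneven final blocks give two block sizes within a trial.

Default structural counts mirror the motivating program (two genotyped
years, eleven locations, three trial series of ~107 entries, 349 crosses
totalling ~1610 genotypes, four checks per year, 11285 markers); variance
components and tester-effect spreads are not reported there and are set
to values typical for cereal yield trials (block/rep/row/column variances
a fraction of the spatial variance, plot-level h² = 0.35). Tests and the
acceptance script run deliberately smaller instances — fewer crosses,
hundreds of markers, 2–3 locations — chosen so each check still has the
statistical power it needs; the problem size used is reported alongside
every acceptance quantity.

What passing tests show: the estimators recover the parameters of data
generated under their own assumptions (unlinked loci, separable AR(1)
errors, normally distributed effects), and the qualitative contrasts of
the motivating study — row/column models out-fitting the baseline,
within-cross CV beating across-cross CV — reproduce under those
assumptions. They do not show robustness to LD structure, non-normal
effect distributions, or trend patterns outside the separable AR(1)
family.

## Numerical choices and degenerate inputs

* Variances live on [e⁻¹⁴, e¹⁴]; a component at the lower bound is an
  effective zero (boundary estimate), not a failure.
* V is Cholesky-factorized with a relative jitter of 1e−9·mean(diag V),
  escalated only for boundary fits (|ρ| → 1 without nugget).
* Rank-deficient fixed designs are handled by pseudo-inverse throughout;
  estimable functions (genotype means averaged over tester or
  year-by-tester levels) are formed explicitly.
* Zero-variance inputs: predictive ability and bias on constant vectors
  are NaN with a warning; a monomorphic-only marker matrix is a hard QC
  error; heritability with σ̂²_g = 0 is 0 with a warning.
* MAF treats the heterozygote as one copy of each allele; a marker at
  exactly the MAF or missingness threshold is kept (strict inequalities
  drop).

## Known limitations

* No linkage disequilibrium in the simulator; AC-sampling contrasts are
  therefore driven purely by family structure, not by shared haplotypes.
* Approach 2 forwards only SEs (not a covariance matrix) to prediction,
  so its fixed error variances overstate the exchangeable part of the
  uncertainty; at small scale this can push σ̂²_u toward zero.
* The LV parameterization is one defensible choice among several.
* Single-stage (plot-level) analysis across all environments is out of
  scope; the stage-wise route with Smith weights is the method implemented.
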